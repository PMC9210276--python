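"""Homology retrieval: translated search, genome masking, EST evidence.

Three stand-ins for the standard web/CLI tools of repeat annotation, all
built on the same seed-and-extend core:

* ``translated_search`` — a tBLASTn-like scan of a protein query against the
  six reading frames of a genome (BLOSUM62 4-mer neighbourhood seeds,
  ungapped X-drop extension), returning the top hits with flanking context;
* ``mask_genome`` — a RepeatMasker-like screen of a genome with a consensus
  library, emitting one gapped alignment record per genomic copy (the
  ``-a`` analog consumed by the landscape stage) plus per-family coverage;
* ``match_ests`` — local alignment of EST reads against family consensuses
  filtered by identity and match length, giving per-family transcription
  evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._align import (Segment, make_nt_aligner, protein_extend,
                     protein_seed_matches, scan_pair, stitch_segments)
from ._seq import revcomp, translate


@dataclass
class CopyHit:
    """One translated-search hit, forward-strand genome coordinates."""

    query: str
    genome_start: int
    genome_end: int
    strand: str
    frame: int
    score: int
    flank_start: int = 0
    flank_end: int = 0
    flanked_sequence: str = ""


@dataclass
class CopyAlignment:
    """One masked genomic copy aligned to its family consensus.

    ``copy_row``/``cons_row`` are equal-length gapped rows, both written in
    the consensus 5'->3' orientation (reverse-strand copies are flipped), so
    CpG positions can be read off the consensus row directly.
    """

    family: str
    genome_start: int
    genome_end: int
    strand: str
    cons_start: int
    cons_end: int
    copy_row: str
    cons_row: str
    score: float
    copy_id: str = ""

    @property
    def aligned_bp(self) -> int:
        return self.genome_end - self.genome_start

    @property
    def identity(self) -> float:
        pairs = [(a, b) for a, b in zip(self.copy_row, self.cons_row)
                 if a != "-" and b != "-"]
        if not pairs:
            return 0.0
        return sum(a == b for a, b in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# translated search


def translated_search(query_protein: str, genome: str, query_name: str = "query",
                      top_n: int = 10, flank_bp: int = 3000, *,
                      seed_word: int = 4, seed_threshold: int = 13,
                      min_score: int = 60) -> list[CopyHit]:
    """Scan all six reading frames of ``genome`` for the protein query.

    Returns the ``top_n`` best-scoring ungapped hits, each with ``flank_bp``
    of upstream/downstream nucleotide context (clipped at the ends).
    """
    n = len(genome)
    raw: list[CopyHit] = []
    for strand, seq in (("+", genome), ("-", revcomp(genome))):
        for frame in range(3):
            prot = translate(seq[frame:])
            if len(prot) < seed_word:
                continue
            best_at: dict[int, tuple[int, int, int]] = {}
            for qpos, tpos in protein_seed_matches(
                    query_protein, prot, word=seed_word,
                    threshold=seed_threshold):
                qs, qe, ts, score = protein_extend(query_protein, prot,
                                                   qpos, tpos, word=seed_word)
                key = ts - qs  # diagonal: one hit per diagonal
                if key not in best_at or score > best_at[key][2]:
                    best_at[key] = (ts, ts + (qe - qs), score)
            for ts, te, score in best_at.values():
                if score < min_score:
                    continue
                nt_s, nt_e = frame + 3 * ts, frame + 3 * te
                if strand == "+":
                    gs, ge = nt_s, nt_e
                else:
                    gs, ge = n - nt_e, n - nt_s
                raw.append(CopyHit(query_name, gs, ge, strand, frame, score))
    # collapse hits covering the same locus, best first
    raw.sort(key=lambda h: -h.score)
    kept: list[CopyHit] = []
    for hit in raw:
        if any(min(hit.genome_end, k.genome_end)
               - max(hit.genome_start, k.genome_start) > 0 for k in kept):
            continue
        kept.append(hit)
        if len(kept) == top_n:
            break
    for hit in kept:
        hit.flank_start = max(0, hit.genome_start - flank_bp)
        hit.flank_end = min(n, hit.genome_end + flank_bp)
        hit.flanked_sequence = genome[hit.flank_start:hit.flank_end]
    return kept


# ---------------------------------------------------------------------------
# genome masking


def _chain(segments: list[Segment], max_gap: int = 500) -> list[list[Segment]]:
    """Group collinear, non-overlapping segments into copy candidates."""
    chains: list[list[Segment]] = []
    for seg in sorted(segments, key=lambda g: (g.qs, g.ss)):
        for chain in chains:
            last = chain[-1]
            if (seg.qs >= last.qe and seg.ss >= last.se
                    and seg.qs - last.qe <= max_gap
                    and abs((seg.ss - seg.qs) - (last.ss - last.qs)) <= 100):
                chain.append(seg)
                break
        else:
            chains.append([seg])
    return chains


def _score_rows(row_a: str, row_b: str) -> float:
    """Alignment score with the masker's nucleotide scoring scheme."""
    score = 0.0
    in_gap = False
    for a, b in zip(row_a, row_b):
        if a == "-" or b == "-":
            score += -0.5 if in_gap else -4.0
            in_gap = True
        else:
            in_gap = False
            score += 1.0 if a == b else -1.5
    return score


def mask_genome(library: list[tuple[str, str]], genome: str, *,
                seed_word: int = 11, min_segment: int = 30,
                max_mismatch_frac: float = 0.30, min_hit_bp: int = 100,
                ) -> tuple[list[CopyAlignment], pd.DataFrame]:
    """Screen ``genome`` with every consensus in ``library``.

    Seeds on exact 11-mers, merges and chains collinear segments, stitches
    them into gapped per-copy alignments, and resolves overlapping hits from
    different families by score (ties to the earlier library entry).
    Returns the accepted records plus a per-family summary with masked bp
    and percentage of the genome.
    """
    n = len(genome)
    candidates: list[CopyAlignment] = []
    for order, (family, cons) in enumerate(library):
        for strand in "+-":
            subject = cons if strand == "+" else revcomp(cons)
            segs = scan_pair(genome, subject, k=seed_word,
                             min_length=min_segment,
                             max_mismatch_frac=max_mismatch_frac,
                             max_gap=60)
            for chain in _chain(segs):
                rows = stitch_segments(genome, subject, chain)
                if rows is None:
                    continue
                g_row, s_row = rows
                gs, ge = chain[0].qs, chain[-1].qe
                ss, se = chain[0].ss, chain[-1].se
                if ge - gs < min_hit_bp:
                    continue
                if strand == "+":
                    cs, ce = ss, se
                    copy_row, cons_row = g_row, s_row
                else:
                    cs, ce = len(cons) - se, len(cons) - ss
                    copy_row, cons_row = revcomp(g_row), revcomp(s_row)
                candidates.append(CopyAlignment(
                    family, gs, ge, strand, cs, ce, copy_row, cons_row,
                    _score_rows(g_row, s_row) - 1e-6 * order))
    # winner-takes-all overlap resolution on the genome axis
    candidates.sort(key=lambda c: -c.score)
    accepted: list[CopyAlignment] = []
    for cand in candidates:
        overlap = sum(
            max(0, min(cand.genome_end, a.genome_end)
                - max(cand.genome_start, a.genome_start))
            for a in accepted)
        if overlap > 0.2 * cand.aligned_bp:
            continue
        accepted.append(cand)
    accepted.sort(key=lambda c: c.genome_start)
    for i, rec in enumerate(accepted, start=1):
        rec.copy_id = f"hit{i:04d}"

    rows = []
    for family in dict(library):
        recs = [r for r in accepted if r.family == family]
        bp = sum(r.aligned_bp for r in recs)
        rows.append({"family": family, "n_copies": len(recs), "masked_bp": bp,
                     "masked_pct": 100.0 * bp / n if n else 0.0})
    summary = pd.DataFrame(rows, columns=["family", "n_copies", "masked_bp",
                                          "masked_pct"])
    return accepted, summary


# ---------------------------------------------------------------------------
# EST evidence


@dataclass
class EstMatch:
    est_id: str
    family: str
    identity: float
    match_len: int
    strand: str = "+"


def match_ests(ests: list[tuple[str, str]], consensuses: list[tuple[str, str]],
               min_identity: float = 0.85, min_match_len: int = 100, *,
               prefilter_word: int = 11) -> tuple[list[EstMatch], pd.DataFrame]:
    """Local-align every EST against every consensus and keep pairs passing
    both filters (identity and aligned length strictly above the cutoffs).

    Returns the matches plus a per-family table with a ``has_transcript``
    flag.
    """
    aligner = make_nt_aligner("local")
    matches: list[EstMatch] = []
    for fam, cons in consensuses:
        cons_words = {cons[i:i + prefilter_word]
                      for i in range(len(cons) - prefilter_word + 1)}
        for est_id, est in ests:
            for strand in "+-":
                seq = est if strand == "+" else revcomp(est)
                if not any(seq[i:i + prefilter_word] in cons_words
                           for i in range(0, len(seq) - prefilter_word + 1, 4)):
                    continue
                aln = aligner.align(seq, cons)
                if len(aln) == 0:
                    continue
                a, b = str(aln[0][0]), str(aln[0][1])
                ncols = len(a)
                ident = (sum(x == y and x != "-" for x, y in zip(a, b)) / ncols
                         if ncols else 0.0)
                if ncols > min_match_len and ident > min_identity:
                    matches.append(EstMatch(est_id, fam, ident, ncols, strand))
                    break
    by_family = {fam: sorted({m.est_id for m in matches if m.family == fam})
                 for fam, _ in consensuses}
    table = pd.DataFrame(
        [{"family": fam, "n_ests": len(ids), "has_transcript": bool(ids)}
         for fam, ids in by_family.items()],
        columns=["family", "n_ests", "has_transcript"])
    return matches, table
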