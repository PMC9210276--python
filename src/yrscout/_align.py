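"""Seed-and-extend alignment primitives.

BLAST-flavoured machinery shared by the self-similarity scanner and the
homology search: exact k-mer seeding grouped by diagonal, ungapped X-drop
extension, and stitching of collinear segments into gapped alignments (gap
filling via Biopython's pairwise aligner on the short inter-segment pieces).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import seq_to_codes

BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: amino-acid alphabet index used for vectorised BLOSUM lookups
_AA = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = np.full(256, _AA.index("X"), dtype=np.int64)
for _i, _c in enumerate(_AA):
    _AA_INDEX[ord(_c)] = _i
_B62 = np.array([[BLOSUM62[a][b] for b in _AA] for a in _AA], dtype=np.int64)


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """All start positions of every k-mer."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i:i + k]].append(i)
    return index


@dataclass
class Segment:
    """An ungapped aligned segment: query[qs:qe] vs subject[ss:ss+(qe-qs)]."""

    qs: int
    qe: int
    ss: int
    identity: float

    @property
    def se(self) -> int:
        return self.ss + (self.qe - self.qs)

    @property
    def length(self) -> int:
        return self.qe - self.qs


def _extend_trim(q: np.ndarray, s: np.ndarray, qs: int, qe: int, d: int,
                 max_mismatch_frac: float, xdrop: int = 12) -> Segment | None:
    """Extend an exact-ish core outward with X-drop, then trim mismatched ends.

    ``d`` is the diagonal (subject pos - query pos). Scoring +1/-2 so that the
    extension stops quickly in unrelated sequence.
    """
    n, m = len(q), len(s)
    # left extension
    score = best = 0
    best_i = qs
    i = qs - 1
    while i >= 0 and i + d >= 0:
        score += 1 if q[i] == s[i + d] else -2
        if score > best:
            best, best_i = score, i
        if best - score > xdrop:
            break
        i -= 1
    qs = best_i
    # right extension
    score = best = 0
    best_j = qe
    j = qe
    while j < n and j + d < m:
        score += 1 if q[j] == s[j + d] else -2
        if score > best:
            best, best_j = score, j + 1
        if best - score > xdrop:
            break
        j += 1
    qe = best_j
    eq = q[qs:qe] == s[qs + d:qe + d]
    nz = np.flatnonzero(eq)
    if nz.size == 0:
        return None
    # longest window starting/ending on a match whose mismatch fraction
    # stays within bounds (two-pointer over the match mask)
    mism = np.concatenate([[0], np.cumsum(~eq)])
    best_len, best_lo = 0, 0
    lo = 0
    for hi in range(1, eq.size + 1):
        if not eq[hi - 1]:
            continue
        while lo < hi and (not eq[lo] or
                           mism[hi] - mism[lo] > max_mismatch_frac * (hi - lo)):
            lo += 1
        if hi - lo > best_len:
            best_len, best_lo = hi - lo, lo
    if best_len == 0:
        return None
    qs2, qe2 = qs + best_lo, qs + best_lo + best_len
    identity = float(eq[best_lo:best_lo + best_len].mean())
    return Segment(qs2, qe2, qs2 + d, identity)


def scan_pair(query: str, subject: str, *, k: int = 11, min_length: int = 50,
              max_mismatch_frac: float = 0.2, max_gap: int = 40,
              exclude_diagonal: bool = False,
              positive_diagonals_only: bool = False) -> list[Segment]:
    """All ungapped matches >= min_length between query and subject.

    Exact k-mer seeds are grouped by diagonal, collinear seeds closer than
    ``max_gap`` are merged into cores, and each core is X-drop extended.
    """
    if min(len(query), len(subject)) < k:
        return []
    q = seq_to_codes(query)
    s = seq_to_codes(subject)
    index = kmer_index(subject, k)
    by_diag: dict[int, list[int]] = defaultdict(list)
    for i in range(len(query) - k + 1):
        for j in index.get(query[i:i + k], ()):
            d = j - i
            if exclude_diagonal and d == 0:
                continue
            if positive_diagonals_only and d <= 0:
                continue
            by_diag[d].append(i)
    out: list[Segment] = []
    seen: set[tuple[int, int, int]] = set()
    for d, starts in by_diag.items():
        starts.sort()
        run_start = prev = starts[0]
        runs = []
        for i in starts[1:]:
            if i - prev > max_gap:
                runs.append((run_start, prev + k))
                run_start = i
            prev = i
        runs.append((run_start, prev + k))
        for qs, qe in runs:
            seg = _extend_trim(q, s, qs, qe, d, max_mismatch_frac)
            if seg is None or seg.length < min_length:
                continue
            key = (seg.qs, seg.qe, seg.ss)
            if key not in seen:
                seen.add(key)
                out.append(seg)
    out.sort(key=lambda g: (g.qs, g.ss))
    return out


# ---------------------------------------------------------------------------
# gapped stitching (for the genome masker)


def make_nt_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.5
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -0.5
    return aligner


def stitch_segments(query: str, subject: str, segments: list[Segment],
                    max_fill: int = 400) -> tuple[str, str] | None:
    """Join collinear ungapped segments into one gapped alignment.

    Segments must be sorted and mutually consistent (increasing in both
    coordinates).  Gaps between consecutive segments are filled by global
    alignment when both sides are short enough, else by a double-gap join.
    Returns (query_row, subject_row) or None when nothing to stitch.
    """
    if not segments:
        return None
    aligner = make_nt_aligner("global")
    rows_q: list[str] = []
    rows_s: list[str] = []
    cur = segments[0]
    rows_q.append(query[cur.qs:cur.qe])
    rows_s.append(subject[cur.ss:cur.se])
    for seg in segments[1:]:
        gap_q = query[cur.qe:seg.qs]
        gap_s = subject[cur.se:seg.ss]
        if gap_q and gap_s and max(len(gap_q), len(gap_s)) <= max_fill:
            aln = aligner.align(gap_q, gap_s)[0]
            a, b = str(aln[0]), str(aln[1])
            rows_q.append(a)
            rows_s.append(b)
        else:
            rows_q.append(gap_q + "-" * len(gap_s))
            rows_s.append("-" * len(gap_q) + gap_s)
        rows_q.append(query[seg.qs:seg.qe])
        rows_s.append(subject[seg.ss:seg.se])
        cur = seg
    return "".join(rows_q), "".join(rows_s)


# ---------------------------------------------------------------------------
# protein seeding (for the translated search)


def protein_seed_matches(query: str, target: str, *, word: int = 4,
                         threshold: int = 13) -> list[tuple[int, int]]:
    """(query_pos, target_pos) pairs whose aligned ``word``-mers score >=
    ``threshold`` under BLOSUM62 — the classic BLASTP neighbourhood seeding."""
    nq, nt = len(query), len(target)
    if nq < word or nt < word:
        return []
    qi = _AA_INDEX[np.frombuffer(query.encode("ascii"), dtype=np.uint8)]
    ti = _AA_INDEX[np.frombuffer(target.encode("ascii"), dtype=np.uint8)]
    n_t = nt - word + 1
    pairs: list[tuple[int, int]] = []
    t_cols = [ti[off:off + n_t] for off in range(word)]
    for i in range(nq - word + 1):
        scores = _B62[qi[i], t_cols[0]].copy()
        for off in range(1, word):
            scores += _B62[qi[i + off], t_cols[off]]
        for j in np.flatnonzero(scores >= threshold):
            pairs.append((i, int(j)))
    return pairs


def protein_extend(query: str, target: str, qpos: int, tpos: int, word: int = 4,
                   xdrop: int = 20) -> tuple[int, int, int, int]:
    """Ungapped BLOSUM62 X-drop extension of a protein seed.

    Returns (q_start, q_end, t_start, score).
    """
    qi = _AA_INDEX[np.frombuffer(query.encode("ascii"), dtype=np.uint8)]
    ti = _AA_INDEX[np.frombuffer(target.encode("ascii"), dtype=np.uint8)]
    d = tpos - qpos
    core = sum(int(_B62[qi[qpos + o], ti[tpos + o]]) for o in range(word))
    score = best = 0
    best_i = qpos
    i = qpos - 1
    while i >= 0 and i + d >= 0:
        score += int(_B62[qi[i], ti[i + d]])
        if score > best:
            best, best_i = score, i
        if best - score > xdrop:
            break
        i -= 1
    left = best
    score = best = 0
    best_j = qpos + word
    j = qpos + word
    while j < len(query) and j + d < len(target):
        score += int(_B62[qi[j], ti[j + d]])
        if score > best:
            best, best_j = score, j + 1
        if best - score > xdrop:
            break
        j += 1
    return best_i, best_j, best_i + d, left + core + best
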