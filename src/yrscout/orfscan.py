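"""ORF finding and conserved-domain-marker scanning.

ORFs are ATG-initiated, stop-terminated stretches of at least 75 nt (stop
codon included in the length, the common ORFfinder convention — a flag flips
this) over all six reading frames.  Domain detection replaces an online
conserved-domain search with ungapped BLOSUM62 sliding-window scoring of the
packaged 30-aa marker peptides; the score threshold is calibrated per marker
as mean + 5 SD of a null distribution of random-window scores.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from ._align import _AA_INDEX, _B62
from ._seq import STOP_CODONS, revcomp, translate
from .markers import MARKERS

#: amino-acid background used for the null score distribution (uniform over
#: the 20 standard residues — the generator's filler codons are near-uniform)
_AA20 = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class DomainHit:
    label: str
    score: float
    protein_interval: tuple[int, int]


@dataclass
class OrfAnnotation:
    """One ORF in forward-strand, 0-based half-open nucleotide coordinates."""

    start: int
    end: int
    strand: str
    frame: int
    protein: str
    domain_hits: list[DomainHit] = field(default_factory=list)

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def _scan_strand(seq: str, min_orf_nt: int, include_stop: bool,
                 ) -> list[tuple[int, int, int, str]]:
    """(start, end, frame, protein) tuples on the given strand's own coords."""
    n = len(seq)
    out = []
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    end = pos + 3 if include_stop else pos
                    if end - start >= min_orf_nt:
                        prot = translate(seq[start:pos])
                        out.append((start, end, frame, prot))
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
        if start is not None:  # runs into the sequence end, no stop
            end = n - (n - frame) % 3
            if end - start >= min_orf_nt:
                out.append((start, end, frame, translate(seq[start:end])))
    return out


def find_orfs(seq: str, min_orf_nt: int = 75, both_strands: bool = True,
              include_stop: bool = True) -> list[OrfAnnotation]:
    """All maximal ATG-to-stop ORFs of at least ``min_orf_nt`` nucleotides.

    "Maximal" means the 5'-most ATG of each stop-to-stop segment.  Non-ACGT
    characters never form a start or a sense codon, so ORFs spanning them are
    simply not reported.  Reverse-strand ORFs carry forward-strand
    coordinates and strand '-'.
    """
    n = len(seq)
    orfs = [OrfAnnotation(s, e, "+", f, p)
            for s, e, f, p in _scan_strand(seq, min_orf_nt, include_stop)]
    if both_strands:
        rc = revcomp(seq)
        for s, e, f, p in _scan_strand(rc, min_orf_nt, include_stop):
            orfs.append(OrfAnnotation(n - e, n - s, "-", f, p))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def detect_overlaps(orfs: list[OrfAnnotation],
                    ) -> list[tuple[OrfAnnotation, OrfAnnotation, int]]:
    """All pairs of ORFs whose forward-strand intervals overlap, with the
    overlap length in nucleotides."""
    out = []
    for i, a in enumerate(orfs):
        for b in orfs[i + 1:]:
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov > 0:
                out.append((a, b, ov))
    return out


def _window_scores(protein: str, marker: str) -> np.ndarray:
    """BLOSUM62 sum of the marker against every window of the protein."""
    p = _AA_INDEX[np.frombuffer(protein.encode("ascii"), dtype=np.uint8)]
    m = _AA_INDEX[np.frombuffer(marker.encode("ascii"), dtype=np.uint8)]
    k = len(marker)
    nwin = len(protein) - k + 1
    if nwin <= 0:
        return np.empty(0)
    scores = np.zeros(nwin, dtype=np.int64)
    for off in range(k):
        scores += _B62[m[off], p[off:off + nwin]]
    return scores


@functools.lru_cache(maxsize=None)
def null_score_threshold(marker: str, n_windows: int = 1000,
                         n_sd: float = 5.0, seed: int = 20211118) -> float:
    """Score cutoff = mean + ``n_sd`` SD over random 30-aa windows."""
    rng = np.random.default_rng(seed)
    aa = rng.choice(list(_AA20), size=n_windows * len(marker))
    prot = "".join(aa)
    scores = _window_scores(prot, marker)
    return float(scores.mean() + n_sd * scores.std())


def scan_domains(protein: str, marker_library: dict[str, str] | None = None,
                 min_score: float | None = None) -> list[DomainHit]:
    """Best-scoring hit of each marker peptide above its threshold."""
    lib = MARKERS if marker_library is None else marker_library
    hits = []
    for label, marker in lib.items():
        scores = _window_scores(protein, marker)
        if scores.size == 0:
            continue
        cutoff = (null_score_threshold(marker) if min_score is None
                  else min_score)
        best = int(scores.argmax())
        if scores[best] >= cutoff:
            hits.append(DomainHit(label, float(scores[best]),
                                  (best, best + len(marker))))
    hits.sort(key=lambda h: h.protein_interval)
    return hits


def annotate_orfs(seq: str, min_orf_nt: int = 75, both_strands: bool = True,
                  ) -> list[OrfAnnotation]:
    """find_orfs + scan_domains on every ORF's protein."""
    orfs = find_orfs(seq, min_orf_nt=min_orf_nt, both_strands=both_strands)
    for orf in orfs:
        orf.domain_hits = scan_domains(orf.protein)
    return orfs


def domains_found(orfs: list[OrfAnnotation]) -> set[str]:
    """Union of marker labels hit across a set of ORFs."""
    return {h.label for o in orfs for h in o.domain_hits}


def domain_order(orfs: list[OrfAnnotation]) -> list[str]:
    """Marker labels in 5'->3' genomic order of their hits (plus-strand ORFs).

    Positions are the ORF start plus three times the protein offset.
    """
    placed = []
    for o in orfs:
        if o.strand != "+":
            continue
        for h in o.domain_hits:
            placed.append((o.start + 3 * h.protein_interval[0], h.label))
    placed.sort()
    return [label for _pos, label in placed]
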