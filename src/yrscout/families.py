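"""Family grouping and consensus building.

Copies are grouped into families by single-linkage clustering of pairwise
divergence at the 80% threshold: sequence pairs more than 80% divergent are
"different families".  Divergence is measured on a global (affine-gap)
alignment as 1 - matches / alignment columns, gap columns included — the
way divergence reads off a multiple alignment where non-homologous stretches
sit against gaps.  With this convention two unrelated sequences measure as
almost entirely divergent (the aligner refuses to match them except by
chance), so the 80% cutoff separates genuinely different families while
copies of one family, even heavily decayed ones, stay well below it.

Consensus sequences are 50% majority-rule over a center-star multiple
alignment (ties emit IUPAC ambiguity codes; gap-majority columns are
dropped).
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

#: IUPAC ambiguity code for each base set
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def make_divergence_aligner() -> Align.PairwiseAligner:
    """Global aligner tuned so unrelated sequence gaps out rather than
    force-matching: mismatches cost more than gapping both sides."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -0.15
    return aligner


def pairwise_divergence(seq_a: str, seq_b: str,
                        aligner: Align.PairwiseAligner | None = None,
                        exclude_gap_columns: bool = False) -> float:
    """1 - identity of the global alignment of two sequences.

    By default identity is matches over *all* alignment columns (see module
    docstring); ``exclude_gap_columns=True`` restricts the denominator to
    columns where both sequences have a residue.
    """
    if seq_a == seq_b:
        return 0.0
    if not seq_a or not seq_b:
        return 1.0
    if aligner is None:
        aligner = make_divergence_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(a, b))
    if exclude_gap_columns:
        ncols = sum(x != "-" and y != "-" for x, y in zip(a, b))
    else:
        ncols = len(a)
    return 1.0 - matches / ncols if ncols else 1.0


def divergence_matrix(seqs: list[str],
                      aligner: Align.PairwiseAligner | None = None,
                      ) -> np.ndarray:
    """Symmetric pairwise divergence matrix with zero diagonal."""
    n = len(seqs)
    mat = np.zeros((n, n))
    if aligner is None:
        aligner = make_divergence_aligner()
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_divergence(seqs[i], seqs[j],
                                                        aligner)
    return mat


def cluster_families(matrix: np.ndarray, threshold: float = 0.80,
                     linkage: str = "single") -> list[int]:
    """Partition by divergence: pairs at <= threshold share a family.

    Single linkage = connected components of the <=threshold graph (the
    default, matching how chains of similar variants get one family name);
    ``linkage='complete'`` instead requires every within-cluster pair to
    pass, via agglomeration.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T):
        raise ValueError("divergence matrix must be square and symmetric")
    if linkage == "single":
        adj = csr_matrix(matrix <= threshold)
        _n_comp, labels = connected_components(adj, directed=False)
        return list(labels)
    if linkage != "complete":
        raise ValueError(f"unknown linkage {linkage!r}")
    clusters: list[set[int]] = [{i} for i in range(n)]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if all(matrix[a, b] <= threshold
                       for a in clusters[i] for b in clusters[j]):
                    clusters[i] |= clusters.pop(j)
                    merged = True
                    break
            if merged:
                break
    labels = [0] * n
    for lab, members in enumerate(clusters):
        for m in members:
            labels[m] = lab
    return labels


# ---------------------------------------------------------------------------
# multiple alignment + consensus


def center_star_msa(seqs: list[str],
                    aligner: Align.PairwiseAligner | None = None,
                    ) -> list[str]:
    """Progressive center-star multiple alignment.

    The center is the sequence minimising summed divergence to the rest;
    every other sequence is globally aligned to it and the pairwise
    alignments are merged on the center's coordinates ("once a gap, always
    a gap").
    """
    if not seqs:
        return []
    if len(seqs) == 1:
        return [seqs[0]]
    if aligner is None:
        aligner = make_divergence_aligner()
    mat = divergence_matrix(seqs, aligner)
    center = int(np.argmin(mat.sum(axis=0)))
    c_seq = seqs[center]
    m = len(c_seq)
    # per-sequence alignment to the center, parsed into insertion profiles:
    # ins[p] = residues of the sequence inserted before center position p
    parsed: list[tuple[list[str], list[str]] | None] = [None] * len(seqs)
    master_ins = [0] * (m + 1)
    for idx, seq in enumerate(seqs):
        if idx == center:
            continue
        aln = aligner.align(c_seq, seq)[0]
        c_row, s_row = str(aln[0]), str(aln[1])
        inserts = [""] * (m + 1)
        aligned_to = [""] * m  # the sequence char (or -) at center position p
        p = 0
        for cc, sc in zip(c_row, s_row):
            if cc == "-":
                inserts[p] += sc
            else:
                aligned_to[p] = sc
                p += 1
        parsed[idx] = (inserts, aligned_to)
        for p in range(m + 1):
            master_ins[p] = max(master_ins[p], len(inserts[p]))

    def _build(inserts: list[str], aligned_to: list[str]) -> str:
        parts = []
        for p in range(m):
            parts.append(inserts[p].ljust(master_ins[p], "-"))
            parts.append(aligned_to[p])
        parts.append(inserts[m].ljust(master_ins[m], "-"))
        return "".join(parts)

    rows = []
    for idx in range(len(seqs)):
        if idx == center:
            rows.append(_build([""] * (m + 1), list(c_seq)))
        else:
            inserts, aligned_to = parsed[idx]
            rows.append(_build(inserts, aligned_to))
    assert len({len(r) for r in rows}) == 1
    return rows


def majority_consensus(rows: list[str], threshold: float = 0.50,
                       ambiguity_floor: float = 0.25) -> str:
    """Majority-rule consensus of equal-length aligned rows.

    Per column: drop it when gaps hold the majority; emit the most frequent
    residue when its frequency (over non-gap residues) reaches ``threshold``
    and is a strict plurality; otherwise emit the IUPAC code of all residues
    above ``ambiguity_floor``.
    """
    if not rows:
        return ""
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise ValueError("consensus input rows must be equal length")
    n = len(rows)
    out = []
    for col in range(ncols):
        column = [r[col] for r in rows]
        gaps = column.count("-")
        if gaps * 2 > n:
            continue
        residues = [c for c in column if c != "-"]
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: -kv[1])
        top_char, top = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else 0
        if top / len(residues) >= threshold and top > second:
            out.append(top_char)
        else:
            above = frozenset(c for c, k in counts.items()
                              if k / len(residues) > ambiguity_floor)
            out.append(_IUPAC.get(above or frozenset(counts), "N"))
    return "".join(out)


def build_family_consensus(seqs: list[str], threshold: float = 0.50) -> str:
    """Center-star MSA followed by 50% majority consensus."""
    return majority_consensus(center_star_msa(seqs), threshold)


def filter_rt_coverage(items: list[tuple[str, str]], min_coverage: float = 0.70,
                       ref_length: int | None = None) -> list[tuple[str, str]]:
    """Keep (name, sequence-or-aligned-row) entries covering at least
    ``min_coverage`` of the reference (boundary inclusive).

    Coverage is non-gap residues over ``ref_length`` when given, else over
    the row's column count (for rows out of a multiple alignment).
    """
    kept = []
    for name, row in items:
        residues = len(row) - row.count("-")
        denom = ref_length if ref_length else len(row)
        if denom and residues / denom >= min_coverage:
            kept.append((name, row))
    return kept
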