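"""Kimura divergence, CpG adjustment, age dating and repeat landscapes.

Each masked copy is compared with its family consensus on their gapped
alignment: transition (P) and transversion (Q) fractions over ungapped
columns give the Kimura 2-parameter distance

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)).

CpG adjustment follows the RepeatMasker utility convention: a transition at
an alignment position where the consensus carries a CpG dinucleotide counts
1/10 of a transition (two transitions at the same CpG count as one full
transition), compensating for the ~10x hypermutability of methylated CpG
sites.  Ages come from T = K / r with r = 3.1e-9 substitutions/site/year,
the average substitution rate of the two Xenopus genomes.  The landscape is
the classic histogram of genome proportion per divergence bin (width 0.01 on
K), whose peaks mark amplification waves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import TRANSITION
from .homology import CopyAlignment

#: substitutions per site per year
DEFAULT_RATE = 3.1e-9
DEFAULT_CPG_WEIGHT = 0.1
DEFAULT_BIN_WIDTH = 0.01


@dataclass
class DivergenceRecord:
    copy_id: str
    family: str
    superfamily: str
    aligned_bp: int
    P: float
    Q: float
    K: float | None          # None when the distance is saturated
    age_years: float | None
    saturated: bool = False


def _k2p_formula(P: float, Q: float) -> tuple[float | None, bool]:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None, True
    return -0.5 * math.log(w1 * math.sqrt(w2)), False


def _paired_columns(copy_row: str, cons_row: str) -> list[tuple[str, str]]:
    if len(copy_row) != len(cons_row):
        raise ValueError("alignment rows must be equal length")
    return [(a.upper(), b.upper()) for a, b in zip(copy_row, cons_row)
            if a != "-" and b != "-"]


def kimura2p(copy_row: str, cons_row: str) -> tuple[float, float, float | None]:
    """(P, Q, K) of a gapped pairwise alignment; K is None when saturated."""
    pairs = _paired_columns(copy_row, cons_row)
    if not pairs:
        return 0.0, 0.0, None
    ts = sum(a != b and TRANSITION.get(b) == a for a, b in pairs)
    tv = sum(a != b and TRANSITION.get(b) != a for a, b in pairs)
    P, Q = ts / len(pairs), tv / len(pairs)
    K, _sat = _k2p_formula(P, Q)
    return P, Q, K


def cpg_adjusted_kimura(copy_row: str, cons_row: str,
                        cpg_weight: float = DEFAULT_CPG_WEIGHT,
                        ) -> tuple[float, float, float | None]:
    """(P_adjusted, Q, K) down-weighting transitions at consensus CpG sites.

    CpG sites are read off the consensus row as written (ignoring gap
    columns when testing adjacency).  One transition at a CpG contributes
    ``cpg_weight`` of a transition; both positions mutated contribute one
    full transition between them.  With no CpG in the consensus this equals
    :func:`kimura2p` exactly.
    """
    pairs = _paired_columns(copy_row, cons_row)
    if not pairs:
        return 0.0, 0.0, None
    n = len(pairs)
    is_ts = [a != b and TRANSITION.get(b) == a for a, b in pairs]
    is_tv = [a != b and TRANSITION.get(b) != a for a, b in pairs]
    cons = [b for _a, b in pairs]
    in_cpg = [False] * n
    cpg_pairs = []
    for i in range(n - 1):
        if cons[i] == "C" and cons[i + 1] == "G":
            in_cpg[i] = in_cpg[i + 1] = True
            cpg_pairs.append((i, i + 1))
    ts_adj = float(sum(t for t, c in zip(is_ts, in_cpg) if not c))
    for i, j in cpg_pairs:
        k = int(is_ts[i]) + int(is_ts[j])
        if k == 1:
            ts_adj += cpg_weight
        elif k == 2:
            ts_adj += 1.0
    P = ts_adj / n
    Q = sum(is_tv) / n
    K, _sat = _k2p_formula(P, Q)
    return P, Q, K


def age_from_divergence(K: float, rate: float = DEFAULT_RATE) -> float:
    """Age in years under T = K / r."""
    if K < 0:
        raise ValueError("K must be >= 0")
    return K / rate


def records_from_alignments(alignments: list[CopyAlignment],
                            superfamily_of: dict[str, str], *,
                            cpg_weight: float = DEFAULT_CPG_WEIGHT,
                            rate: float = DEFAULT_RATE,
                            adjust_cpg: bool = True) -> list[DivergenceRecord]:
    """One divergence record per masked copy."""
    records = []
    for aln in alignments:
        if adjust_cpg:
            P, Q, K = cpg_adjusted_kimura(aln.copy_row, aln.cons_row, cpg_weight)
        else:
            P, Q, K = kimura2p(aln.copy_row, aln.cons_row)
        records.append(DivergenceRecord(
            copy_id=aln.copy_id, family=aln.family,
            superfamily=superfamily_of.get(aln.family, "unknown"),
            aligned_bp=aln.aligned_bp, P=P, Q=Q, K=K,
            age_years=None if K is None else age_from_divergence(K, rate),
            saturated=K is None))
    return records


@dataclass
class LandscapeTable:
    """Genome proportion (%) per divergence bin, per family and superfamily."""

    bin_edges: np.ndarray
    per_family: pd.DataFrame       # index = bin left edge, columns = families
    per_superfamily: pd.DataFrame
    bin_ages_my: np.ndarray        # left-edge K converted to million years
    genome_size: int

    def family_totals(self) -> pd.Series:
        return self.per_family.sum(axis=0)


def build_landscape(records: list[DivergenceRecord], genome_size: int,
                    bin_width: float = DEFAULT_BIN_WIDTH,
                    rate: float = DEFAULT_RATE) -> LandscapeTable:
    """Aggregate copy bp into divergence bins as % of the genome.

    Saturated records (K undefined) are excluded.  Output is invariant to
    record order; per-family columns sum to that family's total masked
    proportion.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    valid = [r for r in records if r.K is not None]
    kmax = max((r.K for r in valid), default=0.0)
    n_bins = max(1, int(math.floor(kmax / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    families = sorted({r.family for r in valid})
    superfams = sorted({r.superfamily for r in valid})
    fam_tab = pd.DataFrame(0.0, index=edges[:-1], columns=families)
    sup_tab = pd.DataFrame(0.0, index=edges[:-1], columns=superfams)
    for r in valid:
        b = min(int(r.K / bin_width), n_bins - 1)
        pct = 100.0 * r.aligned_bp / genome_size
        fam_tab.loc[edges[b], r.family] += pct
        sup_tab.loc[edges[b], r.superfamily] += pct
    ages = edges[:-1] / rate / 1e6
    return LandscapeTable(edges, fam_tab, sup_tab, ages, genome_size)


def plot_landscape(table: LandscapeTable, path: str, *,
                   by: str = "superfamily", title: str = "") -> None:
    """Stacked-bar landscape with a secondary age axis, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = table.per_superfamily if by == "superfamily" else table.per_family
    fig, ax = plt.subplots(figsize=(8, 4))
    width = float(np.diff(table.bin_edges).mean())
    bottom = np.zeros(len(data))
    for col in data.columns:
        ax.bar(data.index + width / 2, data[col], width=width * 0.9,
               bottom=bottom, label=str(col))
        bottom += data[col].to_numpy()
    ax.set_xlabel("Kimura distance (K, CpG adjusted)")
    ax.set_ylabel("genome proportion (%)")
    if title:
        ax.set_title(title)
    if len(data.columns):
        ax.legend(fontsize=8)
    sec = ax.secondary_xaxis(
        "top", functions=(lambda k: k / DEFAULT_RATE / 1e6,
                          lambda t: t * DEFAULT_RATE * 1e6))
    sec.set_xlabel("age (My)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
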