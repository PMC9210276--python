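"""Divergence metric vs an affine-gap DP oracle, clustering vs graph
traversal, consensus building and coverage filtering."""

import numpy as np
import pytest

from yrscout import families as fam
from yrscout import synthgen as sg
from yrscout._seq import random_dna


def gotoh_score(a, b, match=1.0, mismatch=-2.0, open_=-8.0, ext=-0.15):
    """Global affine-gap alignment score by explicit three-state DP
    (open_gap_score = cost of the first gapped residue, as in Biopython)."""
    la, lb = len(a), len(b)
    neg = -1e30
    M = np.full((la + 1, lb + 1), neg)
    Ix = np.full((la + 1, lb + 1), neg)   # gap in b (a consumed)
    Iy = np.full((la + 1, lb + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = open_ + (i - 1) * ext
    for j in range(1, lb + 1):
        Iy[0, j] = open_ + (j - 1) * ext
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                          Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + open_, Ix[i - 1, j] + ext,
                           Iy[i - 1, j] + open_)
            Iy[i, j] = max(M[i, j - 1] + open_, Iy[i, j - 1] + ext,
                           Ix[i, j - 1] + open_)
    return max(M[la, lb], Ix[la, lb], Iy[la, lb])


class TestPairwiseDivergence:
    def test_identical_zero(self, rng):
        s = random_dna(rng, 500, 0.4)
        assert fam.pairwise_divergence(s, s) == 0.0

    def test_ten_percent_substituted(self):
        s = "ACGT" * 25
        mutated = list(s)
        for i in range(0, 40, 4):  # 10 of 100 positions, A->G transitions
            mutated[i] = "G"
        assert fam.pairwise_divergence(s, "".join(mutated)) == \
            pytest.approx(0.10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_aligner_score_matches_dp_oracle(self, seed):
        r = np.random.default_rng(seed)
        a = random_dna(r, 200, 0.4)
        b = sg.mutate_copy(a, float(r.uniform(0, 0.4)), r)[
            : int(r.integers(150, 200))]
        aligner = fam.make_divergence_aligner()
        assert aligner.score(a, b) == pytest.approx(gotoh_score(a, b))

    def test_unrelated_sequences_exceed_family_threshold(self, rng):
        a = random_dna(rng, 3000, 0.4)
        b = random_dna(rng, 3000, 0.4)
        assert fam.pairwise_divergence(a, b) > 0.80

    def test_same_family_decayed_copies_stay_below_threshold(self, rng):
        anc = random_dna(rng, 3000, 0.4)
        x = sg.mutate_copy(anc, 0.25, rng)
        y = sg.mutate_copy(anc, 0.25, rng)
        assert fam.pairwise_divergence(x, y) < 0.80


def cc_oracle(matrix, threshold):
    """Connected components by breadth-first traversal."""
    n = matrix.shape[0]
    labels = [-1] * n
    cur = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        stack = [start]
        while stack:
            v = stack.pop()
            if labels[v] != -1:
                continue
            labels[v] = cur
            stack.extend(w for w in range(n)
                         if labels[w] == -1 and matrix[v, w] <= threshold)
        cur += 1
    return labels


def _partition(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestClusterFamilies:
    def test_two_groups(self):
        m = np.full((6, 6), 0.85)
        m[:3, :3] = 0.1
        m[3:, 3:] = 0.15
        np.fill_diagonal(m, 0)
        labels = fam.cluster_families(m, 0.80)
        assert _partition(labels) == {frozenset({0, 1, 2}),
                                      frozenset({3, 4, 5})}

    def test_single_group(self):
        m = np.full((5, 5), 0.2)
        np.fill_diagonal(m, 0)
        assert len(set(fam.cluster_families(m, 0.80))) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_component_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = 12
        m = r.uniform(0, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        assert _partition(fam.cluster_families(m, 0.5)) == \
            _partition(cc_oracle(m, 0.5))

    def test_order_invariance(self):
        r = np.random.default_rng(9)
        m = r.uniform(0, 1, (8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        base = _partition(fam.cluster_families(m, 0.5))
        perm = r.permutation(8)
        mp = m[np.ix_(perm, perm)]
        permuted = _partition(fam.cluster_families(mp, 0.5))
        mapped = {frozenset(int(perm[i]) for i in grp) for grp in permuted}
        assert mapped == base


class TestMajorityConsensus:
    def test_plurality_column(self):
        assert fam.majority_consensus(["A", "A", "A", "G"]) == "A"

    def test_tie_gives_ambiguity(self):
        assert fam.majority_consensus(["A", "A", "G", "G"]) == "R"

    def test_gap_majority_column_dropped(self):
        rows = ["A-C", "A-C", "AGC", "A--"]
        assert fam.majority_consensus(rows) == "AC"

    def test_identical_sequences_identity(self, rng):
        s = random_dna(rng, 400, 0.4)
        assert fam.build_family_consensus([s] * 5) == s

    def test_ancestor_recovery(self, rng):
        anc = random_dna(rng, 1500, 0.4)
        copies = [sg.mutate_copy(anc, 0.05, np.random.default_rng(40 + i))
                  for i in range(12)]
        cons = fam.build_family_consensus(copies)
        assert fam.pairwise_divergence(cons, anc) < 0.01


class TestFilterRtCoverage:
    def test_full_length_kept_fragment_dropped(self):
        items = [("full", "M" * 120), ("frag", "M" * 60)]
        kept = fam.filter_rt_coverage(items, 0.70, ref_length=120)
        assert [n for n, _ in kept] == ["full"]

    def test_boundary_70pct_kept(self):
        items = [("edge", "M" * 84)]  # exactly 70% of 120
        assert fam.filter_rt_coverage(items, 0.70, ref_length=120) == items

    def test_aligned_rows_denominator(self):
        rows = [("a", "MKV-LL"), ("b", "M---LL")]
        kept = fam.filter_rt_coverage(rows, 0.70)
        assert [n for n, _ in kept] == ["a"]
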