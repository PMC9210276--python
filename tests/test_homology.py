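"""Translated search, genome masking and EST filtering against the
generator's truth tables and a Smith-Waterman oracle."""

import numpy as np
import pytest

from yrscout import homology, synthgen as sg
from yrscout._seq import random_dna, revcomp, translate


@pytest.fixture(scope="module")
def rt_query(small_world):
    cons = small_world.library[0]  # D1, DIRS-like
    orf2 = cons.orfs[1]
    pos = orf2.marker_positions["RT"]
    return translate(cons.sequence[pos - 90:pos + 90 + 90])


class TestTranslatedSearch:
    def test_exact_planted_orf_found(self, rng):
        genome = random_dna(rng, 20_000, 0.4)
        prot = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 80))
        nt = "".join({"A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT",
                      "C": "TGT", "Q": "CAA", "E": "GAA", "G": "GGT",
                      "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
                      "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT",
                      "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT"}[aa]
                     for aa in prot)
        genome = genome[:8000] + nt + genome[8000 + len(nt):]
        hits = homology.translated_search(prot, genome, flank_bp=500)
        assert hits[0].genome_start == 8000
        assert hits[0].genome_end == 8000 + len(nt)
        assert hits[0].strand == "+"
        assert hits[0].flank_start == 7500
        assert len(hits[0].flanked_sequence) == len(nt) + 1000

    def test_top_n_cap(self, small_world, rt_query):
        # the world has 5 D1 copies + 4 N1 copies; D1's RT query hits its
        # own copies (the shared marker may also pull weak cross-hits), and
        # at top_n=3 exactly 3 come back
        hits = homology.translated_search(rt_query, small_world.genome,
                                          top_n=3)
        assert len(hits) == 3

    def test_planted_copies_recovered_with_strand(self, small_world, rt_query):
        hits = homology.translated_search(rt_query, small_world.genome,
                                          top_n=5)
        truth = small_world.truth[small_world.truth.family == "D1"]
        for hit in hits:
            row = truth[(truth.genome_start <= hit.genome_start)
                        & (truth.genome_end >= hit.genome_end)]
            assert len(row) == 1
            assert row.iloc[0].strand == hit.strand

    def test_strand_symmetry(self, small_world, rt_query):
        genome = small_world.genome[:40_000]
        n = len(genome)
        fwd = homology.translated_search(rt_query, genome, top_n=5)
        rev = homology.translated_search(rt_query, revcomp(genome), top_n=5)
        mirrored = {(n - h.genome_end, n - h.genome_start,
                     "+-"[h.strand == "+"]) for h in rev}
        assert {(h.genome_start, h.genome_end, h.strand)
                for h in fwd} == mirrored


class TestMaskGenome:
    def test_empty_library(self, small_world):
        recs, summary = homology.mask_genome([], small_world.genome[:5000])
        assert recs == [] and len(summary) == 0

    def test_truth_recovery(self, small_world):
        ds = small_world
        lib = [(c.name, c.sequence) for c in ds.library]
        recs, summary = homology.mask_genome(lib, ds.genome)
        cov_ok = cov_tot = 0
        for row in ds.truth.itertuples():
            cov_tot += row.genome_end - row.genome_start
            for r in recs:
                if r.family == row.family:
                    cov_ok += max(0, min(r.genome_end, row.genome_end)
                                  - max(r.genome_start, row.genome_start))
        assert cov_ok / cov_tot >= 0.95
        # strand agreement for intact copies
        for row in ds.truth[ds.truth.intact].itertuples():
            match = [r for r in recs
                     if abs(r.genome_start - row.genome_start) < 50
                     and abs(r.genome_end - row.genome_end) < 50]
            assert match and match[0].strand == row.strand

    def test_summary_conservation(self, small_world):
        lib = [(c.name, c.sequence) for c in small_world.library]
        recs, summary = homology.mask_genome(lib, small_world.genome)
        total = sum(r.aligned_bp for r in recs)
        assert int(summary["masked_bp"].sum()) == total
        assert summary["masked_pct"].sum() == pytest.approx(
            100.0 * total / len(small_world.genome))


# ---------------------------------------------------------------------------
# EST filter + Smith-Waterman oracle (linear gaps)


def sw_oracle(a, b, match=1.0, mismatch=-1.5, gap=-2.0):
    """Best local alignment identity/length by straight DP."""
    la, lb = len(a), len(b)
    H = np.zeros((la + 1, lb + 1))
    for i in range(1, la + 1):
        sub = np.where(np.frombuffer(b.encode(), dtype=np.uint8)
                       == ord(a[i - 1]), match, mismatch)
        for j in range(1, lb + 1):
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub[j - 1],
                          H[i - 1, j] + gap, H[i, j - 1] + gap)
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    length = matches = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        if H[i, j] == H[i - 1, j - 1] + (match if a[i - 1] == b[j - 1]
                                         else mismatch):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
        length += 1
    return matches / length if length else 0.0, length


class TestMatchEsts:
    def test_exact_substring_kept(self, rng):
        cons = random_dna(rng, 3000, 0.4)
        est = cons[1000:1150]
        matches, table = homology.match_ests([("e1", est)], [("F", cons)])
        assert [m.est_id for m in matches] == ["e1"]
        assert bool(table.iloc[0].has_transcript)

    def test_low_identity_discarded(self, rng):
        cons = random_dna(rng, 3000, 0.4)
        frag = sg.mutate_copy(cons[1000:1200], 0.30, rng)  # ~75% identity
        matches, _t = homology.match_ests([("e1", frag)], [("F", cons)])
        assert matches == []

    def test_short_match_discarded(self, rng):
        cons = random_dna(rng, 3000, 0.4)
        matches, _t = homology.match_ests([("e1", cons[500:580])],
                                          [("F", cons)])
        assert matches == []

    def test_matches_filter_oracle(self, rng):
        cons = random_dna(rng, 2000, 0.4)
        ests = []
        for i in range(12):
            start = int(rng.integers(0, 1500))
            ln = int(rng.integers(80, 400))
            k = float(rng.choice([0.0, 0.02, 0.25, 0.5]))
            ests.append((f"e{i}", sg.mutate_copy(cons[start:start + ln], k,
                                                 rng)))
        got, _t = homology.match_ests(ests, [("F", cons)])
        kept = {m.est_id for m in got}
        expected = set()
        for est_id, seq in ests:
            ident, length = sw_oracle(seq, cons)
            if ident > 0.85 and length > 100:
                expected.add(est_id)
        assert kept == expected
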