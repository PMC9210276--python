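"""Self-similarity scanning and structural classification, checked against
an exhaustive diagonal-scan oracle and the generator's truth tables."""

import numpy as np

from yrscout import architecture as arch
from yrscout import synthgen as sg
from yrscout._seq import random_dna, revcomp, seq_to_codes


# ---------------------------------------------------------------------------
# oracle: exact maximal repeats by brute diagonal comparison


def _runs(eq, min_len):
    out = []
    start = None
    for i, v in enumerate(eq):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                out.append((start, i))
            start = None
    if start is not None and len(eq) - start >= min_len:
        out.append((start, len(eq)))
    return out


def exact_repeat_oracle(seq, min_len):
    """All maximal exact repeat pairs (direct + inverted), brute force."""
    n = len(seq)
    codes = seq_to_codes(seq)
    rc = seq_to_codes(revcomp(seq))
    direct, inverted = set(), set()
    for d in range(1, n - min_len + 1):
        for s, e in _runs(codes[:-d] == codes[d:], min_len):
            direct.add(((s, e), (s + d, e + d)))
    for d in range(-(n - min_len), n - min_len + 1):
        if d >= 0:
            eq = codes[:n - d] == rc[d:]
            offset_q, offset_s = 0, d
        else:
            eq = codes[-d:] == rc[:n + d]
            offset_q, offset_s = -d, 0
        for s, e in _runs(eq, min_len):
            a = (offset_q + s, offset_q + e)
            rs, re = offset_s + s, offset_s + e
            b = (n - re, n - rs)
            lo, hi = min(a, b), max(a, b)
            if lo != hi:
                inverted.add((lo, hi))
    return direct, inverted


class TestSelfSimilarityScan:
    def test_planted_inverted_terminal_pair(self, rng):
        x = random_dna(rng, 120, 0.5)
        seq = x + random_dna(rng, 1500, 0.5) + revcomp(x)
        pairs = arch.self_similarity_scan(seq, min_length=50)
        inv = [p for p in pairs if p.orientation == "inverted"]
        # boundaries may overshoot the planted repeat by a chance match
        assert inv[0].interval_a[0] == 0
        assert abs(inv[0].interval_a[1] - 120) <= 3
        assert abs(inv[0].interval_b[0] - (len(seq) - 120)) <= 3
        assert inv[0].interval_b[1] == len(seq)
        assert inv[0].identity == 1.0

    def test_planted_direct_pairs(self, rng):
        a = random_dna(rng, 90, 0.5)
        b = random_dna(rng, 70, 0.5)
        seq = a + random_dna(rng, 400, 0.5) + b + a + b
        pairs = arch.self_similarity_scan(seq, min_length=50)
        found = {(p.interval_a, p.interval_b)
                 for p in pairs if p.orientation == "direct"}
        assert ((0, 90), (560, 650)) in found
        assert ((490, 560), (650, 720)) in found

    def test_matches_exhaustive_oracle(self, rng):
        x = random_dna(rng, 80, 0.5)
        y = random_dna(rng, 60, 0.5)
        seq = (x + random_dna(rng, 500, 0.5) + y + random_dna(rng, 600, 0.5)
               + x + random_dna(rng, 300, 0.5) + revcomp(y))
        oracle_d, oracle_i = exact_repeat_oracle(seq, 50)
        pairs = arch.self_similarity_scan(seq, min_length=50,
                                          max_mismatch_frac=0.0)
        got_d = {(p.interval_a, p.interval_b)
                 for p in pairs if p.orientation == "direct"}
        got_i = {(p.interval_a, p.interval_b)
                 for p in pairs if p.orientation == "inverted"}
        assert got_d == oracle_d
        assert got_i == oracle_i

    def test_random_sequence_no_repeats(self, rng):
        seq = random_dna(rng, 2000, 0.5)
        oracle_d, oracle_i = exact_repeat_oracle(seq, 50)
        assert oracle_d == set() and oracle_i == set()
        assert arch.self_similarity_scan(seq, min_length=50,
                                         max_mismatch_frac=0.0) == []

    def test_short_sequence_empty(self):
        assert arch.self_similarity_scan("ACGT" * 10, min_length=50) == []

    def test_strand_symmetry(self, rng):
        x = random_dna(rng, 100, 0.5)
        seq = x + random_dna(rng, 800, 0.5) + revcomp(x)
        n = len(seq)
        fwd = arch.self_similarity_scan(seq, min_length=50)
        rev = arch.self_similarity_scan(revcomp(seq), min_length=50)

        def mirrored(pairs):
            out = set()
            for p in pairs:
                a = (n - p.interval_b[1], n - p.interval_b[0])
                b = (n - p.interval_a[1], n - p.interval_a[0])
                out.add((min(a, b), max(a, b), p.orientation))
            return out

        assert mirrored(rev) == {(p.interval_a, p.interval_b, p.orientation)
                                 for p in fwd}


def _jaccard(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union


class TestFindItrs:
    def test_exact_roundtrip(self, rng):
        spec = sg.FamilySpec.dirs_default("X", icr_itr_overlap=0)
        cons = sg.make_dirs_like_consensus(spec, rng)
        pairs = arch.self_similarity_scan(cons.sequence)
        itrs = arch.find_itrs(cons.sequence, pairs)
        assert itrs == (cons.repeats["itr5"], cons.repeats["itr3"])

    def test_mutated_jaccard(self, dirs_consensus):
        jacc = []
        for i in range(20):
            mut = sg.mutate_copy(dirs_consensus.sequence, 0.05,
                                 np.random.default_rng(900 + i))
            pairs = arch.self_similarity_scan(mut)
            itrs = arch.find_itrs(mut, pairs)
            assert itrs is not None
            jacc.append(_jaccard(itrs[0], dirs_consensus.repeats["itr5"]))
            jacc.append(_jaccard(itrs[1], dirs_consensus.repeats["itr3"]))
        assert np.mean(jacc) >= 0.90

    def test_ngaro_has_no_itrs(self, ngaro_consensus):
        pairs = arch.self_similarity_scan(ngaro_consensus.sequence)
        assert arch.find_itrs(ngaro_consensus.sequence, pairs) is None


class TestFindIcr:
    def test_exact_roundtrip(self, dirs_consensus):
        s = dirs_consensus.sequence
        pairs = arch.self_similarity_scan(s)
        itrs = arch.find_itrs(s, pairs)
        icr = arch.find_icr(s, itrs)
        assert icr is not None
        licr, ricr = icr
        assert _jaccard(licr, dirs_consensus.repeats["icr_l"]) >= 0.9
        assert _jaccard(ricr, dirs_consensus.repeats["icr_r"]) >= 0.9

    def test_icr_may_overlap_itr(self, dirs_consensus):
        # generator elements carry a 10 bp ICR/ITR annotation overlap;
        # detection must tolerate it (cap is 20 bp)
        s = dirs_consensus.sequence
        pairs = arch.self_similarity_scan(s)
        itrs = arch.find_itrs(s, pairs)
        _licr, ricr = arch.find_icr(s, itrs)
        true_itr3 = dirs_consensus.repeats["itr3"]
        overlap = ricr[1] - true_itr3[0]
        assert 0 < overlap <= 20

    def test_deleted_icr_absent(self, rng):
        spec = sg.FamilySpec.dirs_default("X", icr_itr_overlap=0)
        cons = sg.make_dirs_like_consensus(spec, rng)
        il, ir = cons.repeats["icr_l"], cons.repeats["icr_r"]
        gutted = (cons.sequence[:il[0]] + random_dna(rng, ir[1] - il[0], 0.4)
                  + cons.sequence[ir[1]:])
        pairs = arch.self_similarity_scan(gutted)
        itrs = arch.find_itrs(gutted, pairs)
        assert itrs is not None
        assert arch.find_icr(gutted, itrs) is None
        domains = {"GAG", "RT", "RH", "YR"}
        a = arch.analyze_element(gutted, domains)
        assert a.superfamily_call == "DIRS-like"
        assert a.completeness == "partial"  # downgraded


class TestFindSdrs:
    def test_block_lengths_recovered(self, ngaro_consensus):
        pairs = arch.self_similarity_scan(ngaro_consensus.sequence)
        sdrs = arch.find_sdrs(ngaro_consensus.sequence, pairs)
        assert sdrs is not None
        a1, b1, _a2, _b2 = sdrs
        # blocks of 236 and 152 bp (X-drop may extend over a boundary by a
        # few chance-matching bases)
        assert abs((a1[1] - a1[0]) - 236) <= 5
        assert abs((b1[1] - b1[0]) - 152) <= 5

    def test_deleted_3prime_sdrs_absent(self, ngaro_consensus, rng):
        s = ngaro_consensus.sequence
        b1 = ngaro_consensus.repeats["sdr_b1"]
        truncated = s[:b1[0]] + random_dna(rng, len(s) - b1[0], 0.4)
        pairs = arch.self_similarity_scan(truncated)
        assert arch.find_sdrs(truncated, pairs) is None

    def test_shuffled_order_rejected(self, rng):
        a = random_dna(rng, 200, 0.4)
        b = random_dna(rng, 150, 0.4)
        filler = random_dna(rng, 3000, 0.4)
        seq = a + filler + b + b + a  # A1 B1 B2 A2: wrong arrangement
        pairs = arch.self_similarity_scan(seq)
        assert arch.find_sdrs(seq, pairs) is None


class TestClassify:
    def test_intact_roundtrip(self, dirs_consensus, ngaro_consensus):
        a = arch.analyze_element(dirs_consensus.sequence,
                                 {"GAG", "RT", "RH", "MT", "YR"})
        assert (a.superfamily_call, a.completeness) == ("DIRS-like", "complete")
        b = arch.analyze_element(ngaro_consensus.sequence,
                                 {"GAG", "RT", "RH", "YR", "SGNH"})
        assert (b.superfamily_call, b.completeness) == ("Ngaro-like", "complete")

    def test_broken_orf2_degenerate(self, dirs_consensus):
        # missing RT/RH domains: structurally DIRS-like but degenerate
        a = arch.analyze_element(dirs_consensus.sequence, {"GAG", "YR"})
        assert (a.superfamily_call, a.completeness) == ("DIRS-like",
                                                        "degenerate")

    def test_never_both_superfamilies(self, dirs_consensus, ngaro_consensus):
        for seq, domains in ((dirs_consensus.sequence, {"GAG", "RT"}),
                             (ngaro_consensus.sequence, {"SGNH"})):
            a = arch.analyze_element(seq, domains)
            dirs_fields = a.itr5 or a.icr_l
            ngaro_fields = a.sdr_a1
            assert not (dirs_fields and ngaro_fields)

    def test_unclassified_plain_sequence(self, rng):
        a = arch.analyze_element(random_dna(rng, 3000, 0.5))
        assert a.superfamily_call == "unclassified"
        assert a.reason != ""
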