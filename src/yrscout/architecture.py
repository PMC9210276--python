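"""Terminal-repeat architecture of YR retrotransposons.

A single element sequence is compared against itself (direct and inverted
orientation) with a seed-and-extend scanner; the repeat pairs found are then
interpreted structurally:

* DIRS-like — a pair of inverted terminal repeats (ITRs, ~120 bp) plus an
  internal complementary region (ICR) whose two halves are reverse
  complements of the element's 5' and 3' termini, and thymine trinucleotide
  ("TTT") termini;
* Ngaro-like — split direct repeats (SDRs): identical blocks arranged
  A1 ... B1 A2 B2 with A1 at the 5' end.

The ICR annotation is allowed to overlap the ITR by a bounded number of
bases, as seen in most real families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import Segment, scan_pair
from ._seq import revcomp

DIRS_LIKE = "DIRS-like"
NGARO_LIKE = "Ngaro-like"
UNCLASSIFIED = "unclassified"

#: domain markers expected intact for a "complete" call
EXPECTED_DOMAINS = {
    DIRS_LIKE: frozenset({"GAG", "RT", "RH", "YR"}),
    NGARO_LIKE: frozenset({"RT", "RH", "YR", "SGNH"}),
}

Interval = tuple[int, int]


@dataclass
class RepeatPair:
    """Two matching intervals of one sequence, direct or inverted."""

    interval_a: Interval
    interval_b: Interval
    orientation: str  # "direct" | "inverted"
    identity: float

    @property
    def length(self) -> int:
        return self.interval_a[1] - self.interval_a[0]

    @property
    def score(self) -> float:
        return self.identity * self.length


@dataclass
class RepeatArchitecture:
    """Structural call for one element."""

    superfamily_call: str = UNCLASSIFIED
    completeness: str = "degenerate"
    itr5: Interval | None = None
    itr3: Interval | None = None
    icr_l: Interval | None = None
    icr_r: Interval | None = None
    sdr_a1: Interval | None = None
    sdr_b1: Interval | None = None
    sdr_a2: Interval | None = None
    sdr_b2: Interval | None = None
    terminal_5_trinucleotide: str = ""
    terminal_3_trinucleotide: str = ""
    reason: str = ""
    repeat_pairs: list[RepeatPair] = field(default_factory=list)


# ---------------------------------------------------------------------------
# self comparison


def self_similarity_scan(seq: str, min_word: int = 11, min_length: int = 50,
                         max_mismatch_frac: float = 0.2) -> list[RepeatPair]:
    """All non-trivial repeat pairs of ``seq`` with itself.

    Direct pairs come from a self-scan excluding the main diagonal; inverted
    pairs from scanning against the reverse complement.  Each pair is
    reported once with ``interval_a`` 5' of (or equal-start to) ``interval_b``.
    """
    n = len(seq)
    if n < 2 * min_length:
        return []
    pairs: list[RepeatPair] = []
    for seg in scan_pair(seq, seq, k=min_word, min_length=min_length,
                         max_mismatch_frac=max_mismatch_frac,
                         exclude_diagonal=True, positive_diagonals_only=True):
        pairs.append(RepeatPair((seg.qs, seg.qe), (seg.ss, seg.se),
                                "direct", seg.identity))
    seen: set[tuple[Interval, Interval]] = set()
    for seg in scan_pair(seq, revcomp(seq), k=min_word, min_length=min_length,
                         max_mismatch_frac=max_mismatch_frac):
        a = (seg.qs, seg.qe)
        b = (n - seg.se, n - seg.ss)  # map back from the reverse complement
        if b < a:
            a, b = b, a
        if a == b or (a, b) in seen:   # palindromic self-image / mirror dup
            continue
        seen.add((a, b))
        pairs.append(RepeatPair(a, b, "inverted", seg.identity))
    pairs.sort(key=lambda p: (-p.score, p.interval_a))
    return pairs


# ---------------------------------------------------------------------------
# interpretation


def find_itrs(seq: str, pairs: list[RepeatPair],
              terminal_window_frac: float = 0.15) -> tuple[Interval, Interval] | None:
    """Best inverted pair with one member in each terminal window, or None.

    Candidates are ranked by identity x length, ties to the 5'-most.
    """
    n = len(seq)
    w = int(round(terminal_window_frac * n))
    best: RepeatPair | None = None
    for p in pairs:
        if p.orientation != "inverted":
            continue
        if p.interval_a[0] < w and p.interval_b[1] > n - w:
            if best is None or (p.score, -p.interval_a[0]) > (best.score, -best.interval_a[0]):
                best = p
    if best is None:
        return None
    return best.interval_a, best.interval_b


def find_icr(seq: str, itrs: tuple[Interval, Interval], *,
             terminal_segment: int = 45, min_segment: int = 20,
             max_itr_overlap: int = 20, max_join_gap: int = 15,
             max_mismatch_frac: float = 0.2) -> tuple[Interval, Interval] | None:
    """Locate the internal complementary region given the ITR pair.

    Searches the internal region (allowed to reach ``max_itr_overlap`` bases
    into the right ITR) for two adjacent segments reverse-complementary to
    the element's 5'-terminal and 3'-terminal stretches.
    """
    itr5, itr3 = itrs
    lo = itr5[1]
    hi = min(len(seq), itr3[0] + max_itr_overlap)
    if hi - lo < 2 * min_segment:
        return None
    internal = seq[lo:hi]
    lter = seq[:terminal_segment]
    rter = seq[-terminal_segment:]

    def _best(target: str) -> Segment | None:
        segs = scan_pair(revcomp(target), internal, k=11,
                         min_length=min_segment,
                         max_mismatch_frac=max_mismatch_frac)
        return max(segs, key=lambda g: g.identity * g.length, default=None)

    left = _best(lter)
    right = _best(rter)
    if left is None or right is None:
        return None
    licr = (lo + left.ss, lo + left.se)
    ricr = (lo + right.ss, lo + right.se)
    if licr[0] > ricr[0]:
        return None
    gap = ricr[0] - licr[1]
    if gap > max_join_gap or gap < -max_join_gap:
        return None
    return licr, ricr


def find_sdrs(seq: str, pairs: list[RepeatPair],
              terminal_window_frac: float = 0.15, order_slack: int = 10,
              ) -> tuple[Interval, Interval, Interval, Interval] | None:
    """Direct-repeat blocks arranged A1 ... B1 A2 B2, or None.

    A1 must start in the 5' terminal window; the B1/A2/B2 run must sit 3' of
    A1 in increasing order (``order_slack`` bases of overlap are tolerated:
    X-drop extension can overrun a true block boundary on chance matches).
    Among consistent combinations the one maximising total
    identity x length wins.
    """
    n = len(seq)
    w = int(round(terminal_window_frac * n))
    direct = [p for p in pairs if p.orientation == "direct"]
    best = None
    best_score = -1.0
    for pa in direct:
        a1, a2 = pa.interval_a, pa.interval_b
        if a1[0] >= w:
            continue
        for pb in direct:
            if pb is pa:
                continue
            b1, b2 = pb.interval_a, pb.interval_b
            # required order: A1 <= B1 < A2 < B2 (up to the slack)
            if not (a1[1] <= b1[0] + order_slack
                    and b1[1] <= a2[0] + order_slack
                    and a2[1] <= b2[0] + order_slack):
                continue
            score = pa.score + pb.score
            if score > best_score:
                best_score = score
                best = (a1, b1, a2, b2)
    return best


def classify_superfamily(arch: RepeatArchitecture,
                         domains_found: set[str] | None = None,
                         ) -> tuple[str, str]:
    """Final (superfamily, completeness) decision from structural evidence.

    DIRS-like iff an ITR pair was found; Ngaro-like iff the SDR arrangement
    was found (or a hydrolase marker plus direct repeats); conflicting
    evidence gives 'unclassified' with a reason recorded on ``arch``.
    Completeness: 'complete' needs every expected repeat and (when domain
    hits are supplied) every expected domain; missing/broken ORF domains give
    'degenerate', missing accessory repeats give 'partial'.
    """
    has_itr = arch.itr5 is not None
    has_sdr = arch.sdr_a1 is not None
    has_direct = any(p.orientation == "direct" for p in arch.repeat_pairs)
    hydro = domains_found is not None and "SGNH" in domains_found
    dirs_evidence = has_itr
    ngaro_evidence = has_sdr or (hydro and has_direct)
    if dirs_evidence and ngaro_evidence:
        arch.reason = "conflicting-evidence"
        return UNCLASSIFIED, "degenerate"
    if not dirs_evidence and not ngaro_evidence:
        arch.reason = "no-terminal-repeat-evidence"
        return UNCLASSIFIED, "degenerate"
    call = DIRS_LIKE if dirs_evidence else NGARO_LIKE
    if call == DIRS_LIKE:
        repeats_ok = (arch.icr_l is not None
                      and arch.terminal_5_trinucleotide == "TTT"
                      and arch.terminal_3_trinucleotide == "TTT")
    else:
        repeats_ok = has_sdr
    domains_ok = (domains_found is None
                  or EXPECTED_DOMAINS[call] <= domains_found)
    if not domains_ok:
        completeness = "degenerate"
    elif not repeats_ok:
        completeness = "partial"
    else:
        completeness = "complete"
    return call, completeness


def analyze_element(seq: str, domains_found: set[str] | None = None, *,
                    min_word: int = 11, itr_min_length: int = 50,
                    sdr_min_length: int = 50, icr_min_segment: int = 20,
                    max_mismatch_frac: float = 0.2,
                    terminal_window_frac: float = 0.15) -> RepeatArchitecture:
    """Run the full structural diagnosis on one element sequence."""
    pairs = self_similarity_scan(seq, min_word=min_word,
                                 min_length=min(itr_min_length, sdr_min_length),
                                 max_mismatch_frac=max_mismatch_frac)
    arch = RepeatArchitecture(repeat_pairs=pairs)
    if len(seq) >= 3:
        arch.terminal_5_trinucleotide = seq[:3]
        arch.terminal_3_trinucleotide = seq[-3:]
    itrs = find_itrs(seq, [p for p in pairs if p.length >= itr_min_length],
                     terminal_window_frac)
    if itrs:
        arch.itr5, arch.itr3 = itrs
        icr = find_icr(seq, itrs, min_segment=icr_min_segment,
                       max_mismatch_frac=max_mismatch_frac)
        if icr:
            arch.icr_l, arch.icr_r = icr
    sdrs = find_sdrs(seq, [p for p in pairs if p.length >= sdr_min_length],
                     terminal_window_frac)
    if sdrs:
        arch.sdr_a1, arch.sdr_b1, arch.sdr_a2, arch.sdr_b2 = sdrs
    arch.superfamily_call, arch.completeness = classify_superfamily(
        arch, domains_found)
    if arch.superfamily_call != DIRS_LIKE:
        arch.itr5 = arch.itr3 = arch.icr_l = arch.icr_r = None
    if arch.superfamily_call != NGARO_LIKE:
        arch.sdr_a1 = arch.sdr_b1 = arch.sdr_a2 = arch.sdr_b2 = None
    return arch
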