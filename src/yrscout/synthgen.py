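"""Synthetic tyrosine-recombinase retrotransposon data.

Builds consensus elements with the diagnostic terminal-repeat architecture of
the two YR superfamilies (DIRS-like: TTT termini, ~120 bp inverted terminal
repeats, an internal complementary region; Ngaro-like: split direct repeats
A1 ... B1 A2 B2), plants mutated copies of them into a random background
genome as amplification waves of known Kimura divergence, and emits EST-like
reads — together with machine-readable truth tables, so that every
downstream annotation stage can be scored against a known answer.

Mutation follows the Kimura 2-parameter model with an optional multiplier on
the transition rate at CpG dinucleotides of the source sequence, emulating
vertebrate CpG hypermutability.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seq import STOP_CODONS, random_dna, revcomp
from .markers import MARKER_LENGTH, MARKERS

DIRS_LIKE = "DIRS-like"
NGARO_LIKE = "Ngaro-like"

#: codon used to encode each amino acid when writing marker/filler peptides
_CODON_FOR_AA = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_SENSE_CODONS = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
                 if c not in STOP_CODONS]


class ConfigurationError(ValueError):
    """Element or generator specification that cannot be realised."""


class PlacementError(RuntimeError):
    """Copies could not be placed without overlap within the retry budget."""


# ---------------------------------------------------------------------------
# specs


@dataclass
class FamilySpec:
    """Blueprint of one synthetic element family.

    DIRS-like families use ``itr_length``/``icr_segment_length`` (plus an
    optional annotation overlap of the ICR into the right ITR); Ngaro-like
    families use the split-direct-repeat block lengths instead.
    ``orf_layout`` is a list of ``(start, end, labels)`` with 0-based
    half-open nucleotide coordinates inside the element and ``labels`` the
    marker peptides written into that ORF, in order.
    """

    name: str
    superfamily: str
    length: int
    orf_layout: list[tuple[int, int, tuple[str, ...]]]
    itr_length: int = 0
    icr_segment_length: int = 0
    icr_itr_overlap: int = 0
    sdr_a_length: int = 0
    sdr_b_length: int = 0
    terminal_trinucleotide: str = "TTT"

    def __post_init__(self) -> None:
        if self.superfamily not in (DIRS_LIKE, NGARO_LIKE):
            raise ConfigurationError(f"unknown superfamily {self.superfamily!r}")
        if self.superfamily == DIRS_LIKE:
            if self.itr_length <= 0:
                raise ConfigurationError("DIRS-like spec requires itr_length > 0")
            if self.sdr_a_length or self.sdr_b_length:
                raise ConfigurationError("DIRS-like spec must not set SDR lengths")
        else:
            if self.sdr_a_length <= 0 or self.sdr_b_length <= 0:
                raise ConfigurationError("Ngaro-like spec requires SDR lengths > 0")
            if self.itr_length:
                raise ConfigurationError("Ngaro-like spec must not set itr_length")
        for start, end, _labels in self.orf_layout:
            if not 0 <= start < end <= self.length:
                raise ConfigurationError(
                    f"ORF [{start},{end}) outside element of length {self.length}")
            if (end - start) % 3:
                raise ConfigurationError(f"ORF [{start},{end}) not a codon multiple")

    @staticmethod
    def dirs_default(name: str, *, length: int = 5400, itr_length: int = 120,
                     icr_segment_length: int = 30, icr_itr_overlap: int = 10,
                     with_mt: bool = True) -> "FamilySpec":
        """Canonical DIRS-like layout: gag / RT-RH(-MT) / YR, ORF2-ORF3 overlap."""
        orf2_markers = ("RT", "RH", "MT") if with_mt else ("RT", "RH")
        # interior must end before the ICR block, which sits flush against
        # the right ITR (minus the annotation overlap)
        icr_start = (length - 3 - itr_length + icr_itr_overlap
                     - 2 * icr_segment_length)
        orf3_start = 3224  # 28 nt overlap with ORF2, frame shifted by 2
        orf3_end = orf3_start + ((icr_start - 5 - orf3_start) // 3) * 3
        if orf3_end - orf3_start < 300:
            raise ConfigurationError("element too short for the default layout")
        layout = [
            (150, 1452, ("GAG",)),
            (1452, 3252, orf2_markers),
            (orf3_start, orf3_end, ("YR",)),
        ]
        return FamilySpec(name=name, superfamily=DIRS_LIKE, length=length,
                          orf_layout=layout, itr_length=itr_length,
                          icr_segment_length=icr_segment_length,
                          icr_itr_overlap=icr_itr_overlap)

    @staticmethod
    def ngaro_default(name: str, *, length: int = 5200, sdr_a_length: int = 236,
                      sdr_b_length: int = 152) -> "FamilySpec":
        """Canonical Ngaro-like layout: gag / RT-RH / YR / SGNH, all overlaps."""
        b1_start = length - (2 * sdr_b_length + sdr_a_length)
        orf4_start = 4116  # each consecutive ORF pair overlaps 28 nt
        orf4_end = orf4_start + ((b1_start - 50 - orf4_start) // 3) * 3
        if orf4_end - orf4_start < 150:
            raise ConfigurationError("element too short for the default layout")
        layout = [
            (300, 1500, ("GAG",)),
            (1472, 2972, ("RT", "RH")),
            (2944, 4144, ("YR",)),
            (orf4_start, orf4_end, ("SGNH",)),
        ]
        return FamilySpec(name=name, superfamily=NGARO_LIKE, length=length,
                          orf_layout=layout, sdr_a_length=sdr_a_length,
                          sdr_b_length=sdr_b_length)


@dataclass
class WaveSpec:
    """One amplification wave: copies of a family planted at a target divergence."""

    family: str
    n_copies: int
    target_K: float
    intact_fraction: float = 1.0
    max_truncation: float = 0.5  # max fraction of length lost by a truncated copy

    def __post_init__(self) -> None:
        if self.target_K < 0:
            raise ConfigurationError("target_K must be >= 0")
        if not 0.0 <= self.intact_fraction <= 1.0:
            raise ConfigurationError("intact_fraction must be in [0,1]")


@dataclass
class GeneratorConfig:
    """Full description of one synthetic dataset."""

    seed: int
    genome_length: int
    families: list[FamilySpec]
    waves: list[WaveSpec]
    gc_content: float = 0.4
    est_count: int = 0
    est_families: list[str] | None = None
    est_divergence: float = 0.02
    kappa: float = 2.0
    cpg_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigurationError("gc_content must be in (0,1)")
        lengths = {f.name: f.length for f in self.families}
        for wave in self.waves:
            if wave.family not in lengths:
                raise ConfigurationError(f"wave references unknown family {wave.family!r}")
        total = sum(lengths[w.family] * w.n_copies for w in self.waves)
        if total > self.genome_length:
            raise ConfigurationError("genome shorter than total planted copy length")

    @staticmethod
    def from_dict(data: dict) -> "GeneratorConfig":
        fams = [FamilySpec(**{**f, "orf_layout": [
            (int(s), int(e), tuple(labels)) for s, e, labels in f["orf_layout"]]})
            for f in data["families"]]
        waves = [WaveSpec(**w) for w in data["waves"]]
        keys = {f.name for f in dataclasses.fields(GeneratorConfig)}
        rest = {k: v for k, v in data.items()
                if k in keys and k not in ("families", "waves")}
        return GeneratorConfig(families=fams, waves=waves, **rest)

    @staticmethod
    def from_yaml(path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return GeneratorConfig.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class OrfTruth:
    start: int
    end: int
    labels: tuple[str, ...]
    marker_positions: dict[str, int] = field(default_factory=dict)  # nt offsets


@dataclass
class ElementConsensus:
    """A named consensus sequence plus its true internal annotations."""

    name: str
    superfamily: str
    sequence: str
    orfs: list[OrfTruth]
    repeats: dict[str, tuple[int, int]]
    terminal_trinucleotide: str = ""

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.sequence)


@dataclass
class TruthRecord:
    """One planted genomic copy, forward-strand coordinates."""

    copy_id: str
    family: str
    superfamily: str
    genome_start: int
    genome_end: int
    strand: str
    target_K: float
    intact: bool
    lost_5: int = 0   # bp truncated from the element 5' end
    lost_3: int = 0


# ---------------------------------------------------------------------------
# ORF writing


def _encode_peptide(peptide: str) -> str:
    return "".join(_CODON_FOR_AA[aa] for aa in peptide)


def _write_orfs(arr: list[str], orfs: list[tuple[int, int, tuple[str, ...]]],
                rng: np.random.Generator,
                anchored: set[int]) -> list[OrfTruth]:
    """Write ATG...markers...stop into ``arr`` for every ORF.

    Overlapping ORFs are reconciled by a stochastic repair loop: any codon
    that reads as a premature stop in some ORF's frame is resampled at its
    un-anchored positions until all frames are clean.  Marker codons, start
    and stop codons are anchored and never resampled.
    """
    truths: list[OrfTruth] = []
    for start, end, labels in sorted(orfs):
        n_aa = (end - start) // 3
        needed = 1 + len(labels) * MARKER_LENGTH + 1  # ATG + markers + stop
        if n_aa < needed:
            raise ConfigurationError(
                f"ORF [{start},{end}) too short for {len(labels)} markers")
        # interior codons, random sense
        for c in range(1, n_aa - 1):
            pos = start + 3 * c
            if not any(p in anchored for p in (pos, pos + 1, pos + 2)):
                arr[pos:pos + 3] = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
        # start / stop anchors; also a stop just 5' of the start in the same
        # frame, so the planted ATG is the segment's first (the ORF found by
        # a maximal-ORF scan then has exactly the planted coordinates)
        arr[start:start + 3] = "ATG"
        arr[end - 3:end] = "TAA"
        anchored.update(range(start, start + 3))
        anchored.update(range(end - 3, end))
        if start >= 3 and not any(p in anchored for p in range(start - 3, start)):
            arr[start - 3:start] = "TAA"
            anchored.update(range(start - 3, start))
        # markers spread over the middle third (kept clear of overlap zones)
        marker_positions: dict[str, int] = {}
        slots = len(labels)
        span_aa = n_aa - 2
        gap = max(1, (span_aa - slots * MARKER_LENGTH) // (slots + 1))
        aa_off = 1 + gap
        for label in labels:
            pep = MARKERS[label]
            pos = start + 3 * aa_off
            arr[pos:pos + 3 * MARKER_LENGTH] = _encode_peptide(pep)
            anchored.update(range(pos, pos + 3 * MARKER_LENGTH))
            marker_positions[label] = pos
            aa_off += MARKER_LENGTH + gap
        truths.append(OrfTruth(start, end, tuple(labels), marker_positions))

    # repair premature stops introduced by overlapping frames
    for _round in range(2000):
        violation = None
        for t in truths:
            for pos in range(t.start + 3, t.end - 3, 3):
                if "".join(arr[pos:pos + 3]) in STOP_CODONS:
                    violation = pos
                    break
            if violation is not None:
                break
        if violation is None:
            break
        free = [p for p in range(violation, violation + 3) if p not in anchored]
        if not free:
            raise ConfigurationError(
                "overlapping ORF layout over-constrained: stop codon at "
                f"position {violation} cannot be repaired")
        for p in free:
            arr[p] = "ACGT"[rng.integers(4)]
    else:
        raise ConfigurationError("ORF repair did not converge")
    return truths


# ---------------------------------------------------------------------------
# consensus builders


def make_dirs_like_consensus(spec: FamilySpec, rng: np.random.Generator,
                             gc_content: float = 0.4) -> ElementConsensus:
    """Build a DIRS-like consensus.

    Layout (5'->3'): TTT, left ITR, ORFs, ICR (lICR+rICR), right ITR, TTT.
    The right ITR is the exact reverse complement of the left one; the lICR
    and rICR are reverse complements of the element's first and last
    ``icr_segment_length`` bases.  With ``icr_itr_overlap`` > 0 the ICR block
    is shifted so its right edge extends that many bases into the right ITR
    (mimicking the slight ICR/ITR overlap of real elements, at the cost of
    the same number of ITR mismatches).
    """
    if spec.superfamily != DIRS_LIKE:
        raise ConfigurationError("spec is not DIRS-like")
    tri = spec.terminal_trinucleotide
    t, L, m = len(tri), spec.length, spec.icr_segment_length
    itr5 = (t, t + spec.itr_length)
    itr3 = (L - t - spec.itr_length, L - t)
    icr_end = itr3[0] + spec.icr_itr_overlap
    icr_start = icr_end - 2 * m
    if spec.orf_layout and max(end for _s, end, _l in spec.orf_layout) > icr_start:
        raise ConfigurationError("ORFs collide with the ICR block")
    if spec.orf_layout and min(s for s, _e, _l in spec.orf_layout) < itr5[1]:
        raise ConfigurationError("ORFs collide with the left ITR")
    if icr_start < itr5[1]:
        raise ConfigurationError("element too short to pack ITRs and ICR")

    arr = list(random_dna(rng, L, gc_content))
    arr[0:t] = tri
    arr[L - t:L] = tri
    litr = random_dna(rng, spec.itr_length, gc_content)
    arr[itr5[0]:itr5[1]] = litr
    arr[itr3[0]:itr3[1]] = revcomp(litr)
    orf_truths = _write_orfs(arr, spec.orf_layout, rng, anchored=set())
    if m:
        licr = revcomp("".join(arr[0:m]))
        ricr = revcomp("".join(arr[L - m:L]))
        arr[icr_start:icr_end] = licr + ricr
    seq = "".join(arr)
    assert seq[:t] == tri and seq[-t:] == tri
    repeats = {"itr5": itr5, "itr3": itr3}
    if m:
        repeats["icr_l"] = (icr_start, icr_start + m)
        repeats["icr_r"] = (icr_start + m, icr_end)
    return ElementConsensus(spec.name, DIRS_LIKE, seq, orf_truths, repeats, tri)


def make_ngaro_like_consensus(spec: FamilySpec, rng: np.random.Generator,
                              gc_content: float = 0.4) -> ElementConsensus:
    """Build a Ngaro-like consensus: A1 [ORF body] B1 A2 B2, A1==A2, B1==B2."""
    if spec.superfamily != NGARO_LIKE:
        raise ConfigurationError("spec is not Ngaro-like")
    a_len, b_len, L = spec.sdr_a_length, spec.sdr_b_length, spec.length
    tail = 2 * a_len + 2 * b_len - a_len  # B1+A2+B2
    b1_start = L - (b_len + a_len + b_len)
    if spec.orf_layout:
        if max(end for _s, end, _l in spec.orf_layout) > b1_start:
            raise ConfigurationError("ORFs collide with the 3' SDR blocks")
        if min(s for s, _e, _l in spec.orf_layout) < a_len:
            raise ConfigurationError("ORFs collide with the A1 block")
    if b1_start < a_len or tail <= 0:
        raise ConfigurationError("element too short for the SDR blocks")

    arr = list(random_dna(rng, L, gc_content))
    a_block = random_dna(rng, a_len, gc_content)
    b_block = random_dna(rng, b_len, gc_content)
    arr[0:a_len] = a_block
    arr[b1_start:b1_start + b_len] = b_block
    a2_start = b1_start + b_len
    arr[a2_start:a2_start + a_len] = a_block
    b2_start = a2_start + a_len
    arr[b2_start:b2_start + b_len] = b_block
    orf_truths = _write_orfs(arr, spec.orf_layout, rng, anchored=set())
    seq = "".join(arr)
    repeats = {
        "sdr_a1": (0, a_len),
        "sdr_b1": (b1_start, b1_start + b_len),
        "sdr_a2": (a2_start, a2_start + a_len),
        "sdr_b2": (b2_start, b2_start + b_len),
    }
    return ElementConsensus(spec.name, NGARO_LIKE, seq, orf_truths, repeats, "")


def make_consensus(spec: FamilySpec, rng: np.random.Generator,
                   gc_content: float = 0.4) -> ElementConsensus:
    if spec.superfamily == DIRS_LIKE:
        return make_dirs_like_consensus(spec, rng, gc_content)
    return make_ngaro_like_consensus(spec, rng, gc_content)


# ---------------------------------------------------------------------------
# mutation


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TS_PARTNER = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"GTAC"):     # A<->G, C<->T
    _TS_PARTNER[_a] = _b
_TV_PARTNERS = np.zeros((256, 2), dtype=np.uint8)
for _a, (_x, _y) in zip(b"ACGT", [b"CT", b"AG", b"CT", b"AG"]):
    _TV_PARTNERS[_a] = (_x, _y)


def mutate_copy(seq: str, target_K: float, rng: np.random.Generator, *,
                kappa: float = 2.0, cpg_factor: float = 1.0,
                indel_rate: float = 0.0, indel_mean_len: float = 2.0) -> str:
    """Mutate a sequence to an expected Kimura-2-parameter distance ``target_K``.

    Site-wise substitution under K2P with transition/transversion ratio
    ``kappa`` (= alpha/beta).  Transitions at positions lying in a CpG
    dinucleotide of the *input* occur with their rate multiplied by
    ``cpg_factor``.  Optional indels: per-site event rate ``indel_rate``
    (insertion or deletion equally likely) with geometric lengths.
    """
    if target_K < 0:
        raise ConfigurationError("target_K must be >= 0")
    if target_K == 0 and indel_rate == 0:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = codes.size
    # branch "lengths": a = alpha*t, b = beta*t (per-transversion), K = a + 2b
    a = target_K * kappa / (kappa + 2.0)
    b = target_K / (kappa + 2.0)

    def _probs(a_eff: float) -> tuple[float, float]:
        e1 = np.exp(-4.0 * b)
        e2 = np.exp(-2.0 * (a_eff + b))
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        q_tv = 0.5 - 0.5 * e1
        return p_ts, q_tv

    p_ts, q_tv = _probs(a)
    p_ts_cpg, _ = _probs(a * cpg_factor)

    is_c = codes == ord("C")
    is_g = codes == ord("G")
    cpg = np.zeros(n, dtype=bool)
    if n > 1:
        start_cg = is_c[:-1] & is_g[1:]
        cpg[:-1] |= start_cg
        cpg[1:] |= start_cg
    p_site = np.where(cpg, p_ts_cpg, p_ts)
    u = rng.random(n)
    ts_mask = u < p_site
    tv_mask = (~ts_mask) & (u < p_site + q_tv)
    codes[ts_mask] = _TS_PARTNER[codes[ts_mask]]
    which = rng.integers(2, size=int(tv_mask.sum()))
    codes[tv_mask] = _TV_PARTNERS[codes[tv_mask], which]
    out = codes.tobytes().decode("ascii")

    if indel_rate > 0:
        p_geo = min(1.0, 1.0 / max(indel_mean_len, 1.0))
        n_events = rng.binomial(n, indel_rate)
        if n_events:
            positions = np.sort(rng.integers(0, n, size=n_events))[::-1]
            chars = list(out)
            for pos in positions:
                length = int(rng.geometric(p_geo))
                if rng.random() < 0.5:
                    del chars[pos:pos + length]
                else:
                    chars[pos:pos] = list(random_dna(rng, length))
            out = "".join(chars)
    return out


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class SynthDataset:
    """Everything ``build_genome`` produces, in memory."""

    config: GeneratorConfig
    genome: str
    library: list[ElementConsensus]
    truth: pd.DataFrame
    ests: list[tuple[str, str, str]]  # (est_id, sequence, source family)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome/library/EST FASTA, a BED6 truth table and a JSON config echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "library": outdir / "library.fasta",
            "ests": outdir / "ests.fasta",
            "truth_bed": outdir / "truth.bed",
            "truth_tsv": outdir / "truth.tsv",
            "config": outdir / "config.json",
        }
        _write_fasta(paths["genome"], [("genome", self.genome)])
        _write_fasta(paths["library"],
                     [(c.name, c.sequence) for c in self.library])
        _write_fasta(paths["ests"], [(i, s) for i, s, _f in self.ests])
        with open(paths["truth_bed"], "w") as fh:
            for rec in self.truth.itertuples():
                fh.write(f"genome\t{rec.genome_start}\t{rec.genome_end}\t"
                         f"{rec.family}\t{round(1000 * rec.target_K)}\t{rec.strand}\n")
        self.truth.to_csv(paths["truth_tsv"], sep="\t", index=False)
        with open(paths["config"], "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=1, default=list)
        return paths


def _write_fasta(path: Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def build_genome(config: GeneratorConfig) -> SynthDataset:
    """Realise a full synthetic dataset from a :class:`GeneratorConfig`.

    Copies are planted at non-overlapping, uniformly drawn positions on a
    random strand; non-intact copies lose a random fraction of their 5'
    and/or 3' end.  Determinism: everything derives from ``config.seed``
    through named substreams, so equal configs give byte-identical output.
    """
    root = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(s) for name, s in
               zip(("library", "copies", "placement", "background", "ests"),
                   root.spawn(5))}
    specs = {f.name: f for f in config.families}
    library = [make_consensus(f, streams["library"], config.gc_content)
               for f in config.families]
    by_name = {c.name: c for c in library}

    # realise copy sequences
    rng_c = streams["copies"]
    planted: list[tuple[TruthRecord, str]] = []
    counter = 0
    for wave in config.waves:
        cons = by_name[wave.family]
        for _ in range(wave.n_copies):
            counter += 1
            seq = mutate_copy(cons.sequence, wave.target_K, rng_c,
                              kappa=config.kappa, cpg_factor=config.cpg_factor)
            intact = bool(rng_c.random() < wave.intact_fraction)
            lost_5 = lost_3 = 0
            if not intact:
                frac = rng_c.uniform(0.05, wave.max_truncation)
                lost = int(frac * len(seq))
                side = rng_c.integers(3)
                if side == 0:
                    lost_5 = lost
                elif side == 1:
                    lost_3 = lost
                else:
                    lost_5, lost_3 = lost // 2, lost - lost // 2
                seq = seq[lost_5:len(seq) - lost_3]
            strand = "+" if rng_c.random() < 0.5 else "-"
            rec = TruthRecord(f"copy{counter:04d}", wave.family, cons.superfamily,
                              -1, -1, strand, wave.target_K, intact, lost_5, lost_3)
            planted.append((rec, seq if strand == "+" else revcomp(seq)))

    # place without overlap
    rng_p = streams["placement"]
    intervals: list[tuple[int, int]] = []
    for rec, seq in planted:
        ln = len(seq)
        for _try in range(2000):
            start = int(rng_p.integers(0, config.genome_length - ln + 1))
            end = start + ln
            if all(end <= s or start >= e for s, e in intervals):
                intervals.append((start, end))
                rec.genome_start, rec.genome_end = start, end
                break
        else:
            raise PlacementError(
                f"could not place {rec.copy_id} after 2000 attempts")

    genome_arr = np.frombuffer(
        random_dna(streams["background"], config.genome_length,
                   config.gc_content).encode("ascii"), dtype=np.uint8).copy()
    for rec, seq in planted:
        genome_arr[rec.genome_start:rec.genome_end] = np.frombuffer(
            seq.encode("ascii"), dtype=np.uint8)
    genome = genome_arr.tobytes().decode("ascii")

    # ESTs: lightly mutated subsequences of chosen family consensuses
    rng_e = streams["ests"]
    est_pool = config.est_families or [f.name for f in config.families]
    ests: list[tuple[str, str, str]] = []
    for i in range(config.est_count):
        fam = est_pool[int(rng_e.integers(len(est_pool)))]
        cons = by_name[fam].sequence
        ln = int(rng_e.integers(150, 401))
        start = int(rng_e.integers(0, len(cons) - ln + 1))
        frag = mutate_copy(cons[start:start + ln], config.est_divergence, rng_e,
                           kappa=config.kappa)
        ests.append((f"est{i + 1:04d}", frag, fam))

    truth = pd.DataFrame([dataclasses.asdict(rec) for rec, _ in planted],
                         columns=[f.name for f in dataclasses.fields(TruthRecord)])
    return SynthDataset(config, genome, library, truth, ests)


def demo_config(seed: int = 0, *, genome_length: int = 200_000,
                est_count: int = 40) -> GeneratorConfig:
    """The default demo world: 2 DIRS-like + 1 Ngaro-like family, two clear
    amplification waves (a recent one and an ancient one) plus a small
    partly-truncated Ngaro wave.  CpG transitions run 10x hot, the
    vertebrate hypermutability that the landscape stage's CpG adjustment
    (weight 0.1) is built to compensate."""
    return GeneratorConfig(
        seed=seed,
        genome_length=genome_length,
        cpg_factor=10.0,
        families=[
            FamilySpec.dirs_default("DIRS-A"),
            FamilySpec.dirs_default("DIRS-B", length=4800, with_mt=False),
            FamilySpec.ngaro_default("NGARO-A"),
        ],
        waves=[
            WaveSpec("DIRS-A", n_copies=8, target_K=0.02),
            WaveSpec("DIRS-B", n_copies=8, target_K=0.25, intact_fraction=0.5),
            WaveSpec("NGARO-A", n_copies=5, target_K=0.10, intact_fraction=0.8),
        ],
        est_count=est_count,
    )
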