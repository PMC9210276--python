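"""End-to-end orchestration: generate -> annotate -> mask -> landscape ->
families -> tree -> EST evidence, as one reproducible, fully seeded run.

Every stage writes its table under the output directory and logs the
parameters it ran with; all randomness flows from the single run seed
through named substreams.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from . import architecture, families, homology, landscape, orfscan, synthgen
from .phylo import bootstrap_support
from .synthgen import GeneratorConfig, SynthDataset

log = logging.getLogger("yrscout")


@dataclass
class RunConfig:
    """Thresholds and inputs of one full analysis run."""

    seed: int
    outdir: str
    generator: GeneratorConfig | None = None
    genome_fasta: str | None = None
    library_fasta: str | None = None
    est_fasta: str | None = None
    family_threshold: float = 0.80
    consensus_threshold: float = 0.50
    rt_min_coverage: float = 0.70
    rt_halfwidth_aa: int = 45
    est_min_identity: float = 0.85
    est_min_len: int = 100
    bootstrap_reps: int = 100
    bin_width: float = landscape.DEFAULT_BIN_WIDTH
    rate: float = landscape.DEFAULT_RATE
    cpg_weight: float = landscape.DEFAULT_CPG_WEIGHT
    max_cluster_copies_per_family: int = 6
    cluster_prefix_bp: int = 3000

    def __post_init__(self) -> None:
        if not 0 < self.family_threshold <= 1:
            raise ValueError("family_threshold out of range")
        if self.generator is None and not (self.genome_fasta
                                           and self.library_fasta):
            raise ValueError("need a generator config or genome+library FASTA")


@dataclass
class ReportBundle:
    config: RunConfig
    dataset: SynthDataset | None
    architecture_table: pd.DataFrame
    mask_summary: pd.DataFrame
    copy_alignments: list[homology.CopyAlignment]
    divergence_records: list[landscape.DivergenceRecord]
    landscape_table: landscape.LandscapeTable
    cluster_table: pd.DataFrame
    cluster_consensus: dict[int, str]
    newick: str
    est_table: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _interval(iv: tuple[int, int] | None) -> str:
    return f"{iv[0]}-{iv[1]}" if iv else "."


def _annotate_library(library: list[tuple[str, str]]) -> tuple[
        pd.DataFrame, dict[str, list[orfscan.OrfAnnotation]],
        dict[str, architecture.RepeatArchitecture]]:
    columns = ["element", "length", "superfamily", "completeness", "itr5",
               "itr3", "icr_l", "icr_r", "sdr_a1", "sdr_b1", "sdr_a2",
               "sdr_b2", "terminal_5", "terminal_3", "n_orfs", "domains",
               "domain_order", "reason"]
    rows, orfs_by, arch_by = [], {}, {}
    for name, seq in library:
        orfs = orfscan.annotate_orfs(seq)
        plus_orfs = [o for o in orfs if o.strand == "+"]
        domains = orfscan.domains_found(plus_orfs)
        arch = architecture.analyze_element(seq, domains)
        orfs_by[name], arch_by[name] = plus_orfs, arch
        rows.append({
            "element": name, "length": len(seq),
            "superfamily": arch.superfamily_call,
            "completeness": arch.completeness,
            "itr5": _interval(arch.itr5), "itr3": _interval(arch.itr3),
            "icr_l": _interval(arch.icr_l), "icr_r": _interval(arch.icr_r),
            "sdr_a1": _interval(arch.sdr_a1), "sdr_b1": _interval(arch.sdr_b1),
            "sdr_a2": _interval(arch.sdr_a2), "sdr_b2": _interval(arch.sdr_b2),
            "terminal_5": arch.terminal_5_trinucleotide,
            "terminal_3": arch.terminal_3_trinucleotide,
            "n_orfs": len(plus_orfs),
            "domains": ",".join(sorted(domains)) or ".",
            "domain_order": ">".join(orfscan.domain_order(plus_orfs)) or ".",
            "reason": arch.reason or ".",
        })
    return pd.DataFrame(rows, columns=columns), orfs_by, arch_by


def _make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _rt_window(orfs: list[orfscan.OrfAnnotation], halfwidth: int,
               ) -> tuple[orfscan.OrfAnnotation, int, int] | None:
    """The ORF carrying the RT marker and the aa window around it."""
    for orf in orfs:
        for hit in orf.domain_hits:
            if hit.label == "RT":
                lo = max(0, hit.protein_interval[0] - halfwidth)
                hi = min(len(orf.protein), hit.protein_interval[1] + halfwidth)
                return orf, lo, hi
    return None


def _copy_region_protein(aln: homology.CopyAlignment, nt_start: int,
                         nt_end: int) -> str:
    """Translate the copy nucleotides aligned to a consensus nt window."""
    out = []
    cpos = aln.cons_start
    for a, b in zip(aln.copy_row, aln.cons_row):
        if b != "-":
            if nt_start <= cpos < nt_end and a != "-":
                out.append(a)
            cpos += 1
    nt = "".join(out)
    from ._seq import translate
    return translate(nt)


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute every stage and write the report bundle under the outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")
    log.info("run config: %s", dataclasses.asdict(config))

    # -- stage 1: inputs -----------------------------------------------------
    if config.generator is not None:
        log.info("[generate] seed=%d genome=%d bp", config.generator.seed,
                 config.generator.genome_length)
        dataset = synthgen.build_genome(config.generator)
        paths.update(dataset.write(outdir / "inputs"))
        genome = dataset.genome
        library = [(c.name, c.sequence) for c in dataset.library]
        ests = [(i, s) for i, s, _f in dataset.ests]
    else:
        dataset = None
        genome = str(next(SeqIO.parse(config.genome_fasta, "fasta")).seq).upper()
        library = [(r.id, str(r.seq).upper())
                   for r in SeqIO.parse(config.library_fasta, "fasta")]
        ests = ([(r.id, str(r.seq).upper())
                 for r in SeqIO.parse(config.est_fasta, "fasta")]
                if config.est_fasta else [])

    # -- stage 2: structural annotation of the library ----------------------
    log.info("[annotate] %d consensus elements", len(library))
    arch_table, orfs_by, arch_by = _annotate_library(library)
    paths["architecture"] = outdir / "architecture.tsv"
    arch_table.to_csv(paths["architecture"], sep="\t", index=False)
    superfamily_of = dict(zip(arch_table["element"], arch_table["superfamily"]))

    # -- stage 3: genome masking --------------------------------------------
    log.info("[mask] genome %d bp vs %d consensuses", len(genome), len(library))
    copy_alns, mask_summary = homology.mask_genome(library, genome)
    paths["mask_summary"] = outdir / "mask_summary.tsv"
    mask_summary.to_csv(paths["mask_summary"], sep="\t", index=False)
    paths["alignments"] = outdir / "copy_alignments.tsv"
    pd.DataFrame([{
        "copy_id": a.copy_id, "family": a.family, "start": a.genome_start,
        "end": a.genome_end, "strand": a.strand, "cons_start": a.cons_start,
        "cons_end": a.cons_end, "score": round(a.score, 2),
        "identity": round(a.identity, 4)}
        for a in copy_alns]).to_csv(paths["alignments"], sep="\t", index=False)

    # -- stage 4: divergence + landscape ------------------------------------
    records = landscape.records_from_alignments(
        copy_alns, superfamily_of, cpg_weight=config.cpg_weight,
        rate=config.rate)
    paths["divergence"] = outdir / "divergence.tsv"
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        paths["divergence"], sep="\t", index=False)
    table = landscape.build_landscape(records, len(genome), config.bin_width,
                                      config.rate)
    paths["landscape"] = outdir / "landscape.tsv"
    table.per_family.to_csv(paths["landscape"], sep="\t")
    paths["landscape_plot"] = outdir / "landscape.png"
    landscape.plot_landscape(table, str(paths["landscape_plot"]))

    # -- stage 5: family clustering + consensus -----------------------------
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    chosen: list[homology.CopyAlignment] = []
    for fam in sorted({a.family for a in copy_alns}):
        fam_alns = sorted((a for a in copy_alns if a.family == fam),
                          key=lambda a: -a.aligned_bp)
        chosen.extend(fam_alns[:config.max_cluster_copies_per_family])
    copy_seqs = [a.copy_row.replace("-", "")[:config.cluster_prefix_bp]
                 for a in chosen]
    log.info("[families] clustering %d copies at threshold %.2f",
             len(copy_seqs), config.family_threshold)
    if copy_seqs:
        dmat = families.divergence_matrix(copy_seqs)
        labels = families.cluster_families(dmat, config.family_threshold)
    else:
        labels = []
    cluster_table = pd.DataFrame({
        "copy_id": [a.copy_id for a in chosen],
        "assigned_family": [a.family for a in chosen],
        "cluster": labels})
    paths["clusters"] = outdir / "clusters.tsv"
    cluster_table.to_csv(paths["clusters"], sep="\t", index=False)
    cluster_consensus: dict[int, str] = {}
    for lab in sorted(set(labels)):
        members = [s for s, l in zip(copy_seqs, labels) if l == lab]
        if len(members) > 8:   # cap the star alignment size
            members = members[:8]
        cluster_consensus[lab] = families.build_family_consensus(
            members, config.consensus_threshold)
    paths["consensus"] = outdir / "cluster_consensus.fasta"
    with open(paths["consensus"], "w") as fh:
        for lab, seq in cluster_consensus.items():
            fh.write(f">cluster{lab}\n{seq}\n")

    # -- stage 6: RT tree ----------------------------------------------------
    rt_prots: list[tuple[str, str]] = []
    for fam, seq in library:
        win = _rt_window(orfs_by[fam], config.rt_halfwidth_aa)
        if win is None:
            continue
        orf, lo, hi = win
        rt_prots.append((fam, orf.protein[lo:hi]))
        nt_lo, nt_hi = orf.start + 3 * lo, orf.start + 3 * hi
        for aln in copy_alns:
            if aln.family != fam:
                continue
            prot = _copy_region_protein(aln, nt_lo, nt_hi)
            if prot:
                rt_prots.append((aln.copy_id, prot))
    newick = ""
    if len(rt_prots) >= 4:
        ref_len = max(len(p) for _n, p in rt_prots)
        rt_prots = families.filter_rt_coverage(rt_prots,
                                               config.rt_min_coverage,
                                               ref_length=ref_len)
        if len(rt_prots) >= 4:
            log.info("[tree] %d RT sequences, %d bootstrap replicates",
                     len(rt_prots), config.bootstrap_reps)
            prot_aligner = _make_protein_aligner()
            msa = families.center_star_msa([p for _n, p in rt_prots],
                                           prot_aligner)
            aligned = list(zip([n for n, _p in rt_prots], msa))
            tree = bootstrap_support(aligned, config.bootstrap_reps,
                                     seed=int(rng.integers(2 ** 31)))
            newick = tree.newick(with_support=True)
    paths["tree"] = outdir / "rt_tree.nwk"
    paths["tree"].write_text(newick + "\n")

    # -- stage 7: EST evidence ----------------------------------------------
    log.info("[ests] %d reads vs %d consensuses", len(ests), len(library))
    _matches, est_table = homology.match_ests(
        ests, library, config.est_min_identity, config.est_min_len)
    paths["ests"] = outdir / "est_evidence.tsv"
    est_table.to_csv(paths["ests"], sep="\t", index=False)

    bundle = ReportBundle(config, dataset, arch_table, mask_summary, copy_alns,
                          records, table, cluster_table, cluster_consensus,
                          newick, est_table, paths)
    paths["summary"] = outdir / "summary.md"
    paths["summary"].write_text(summarize(bundle))
    return bundle


def summarize(bundle: ReportBundle) -> str:
    """One-page markdown summary of a run (the Tables S1/S2 analog)."""
    arch = bundle.architecture_table
    lines = ["# yrscout run summary", ""]
    lines.append(f"Elements in library: {len(arch)}")
    for superfam in ("DIRS-like", "Ngaro-like", "unclassified"):
        sub = arch[arch["superfamily"] == superfam]
        if len(sub) == 0 and superfam == "unclassified":
            continue
        by_c = sub["completeness"].value_counts().to_dict()
        detail = ", ".join(f"{k}: {v}" for k, v in sorted(by_c.items()))
        lines.append(f"- {superfam}: {len(sub)} ({detail or 'none'})")
    lines.append("")
    lines.append("## Genome masking")
    total_bp = int(bundle.mask_summary["masked_bp"].sum())
    genome_size = bundle.landscape_table.genome_size
    lines.append(f"Total masked: {total_bp} bp "
                 f"({100.0 * total_bp / genome_size:.3f}% of {genome_size} bp)")
    superfamily_of = dict(zip(arch["element"], arch["superfamily"]))
    for superfam in ("DIRS-like", "Ngaro-like"):
        fams = [f for f, s in superfamily_of.items() if s == superfam]
        bp = int(bundle.mask_summary[
            bundle.mask_summary["family"].isin(fams)]["masked_bp"].sum())
        lines.append(f"- {superfam}: {bp} bp "
                     f"({100.0 * bp / genome_size:.3f}%)")
    lines.append("")
    lines.append("## Families and divergence")
    n_clusters = bundle.cluster_table["cluster"].nunique() if len(
        bundle.cluster_table) else 0
    lines.append(f"Copy clusters at the family threshold: {n_clusters}")
    valid = [r for r in bundle.divergence_records if r.K is not None]
    if valid:
        ks = np.array([r.K for r in valid])
        ages = np.array([r.age_years for r in valid]) / 1e6
        lines.append(f"Copies dated: {len(valid)}; K range "
                     f"{ks.min():.3f}-{ks.max():.3f} "
                     f"(ages {ages.min():.1f}-{ages.max():.1f} My)")
    lines.append("")
    lines.append("## Transcription evidence")
    for rec in bundle.est_table.itertuples():
        flag = "yes" if rec.has_transcript else "no"
        lines.append(f"- {rec.family}: {flag} ({rec.n_ests} ESTs)")
    lines.append("")
    if bundle.newick:
        lines.append(f"RT tree taxa: {bundle.newick.count(',') + 1}")
    return "\n".join(lines) + "\n"


def demo_run_config(seed: int = 0, outdir: str = "yrscout_demo", **kwargs,
                    ) -> RunConfig:
    """The default demo analysis over the generator's demo world."""
    gen = synthgen.demo_config(seed)
    return RunConfig(seed=seed, outdir=outdir, generator=gen, **kwargs)
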