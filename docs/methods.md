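# Methods

This note documents the models, defaults and numerical decisions behind
`yrscout`, and what its synthetic worlds do and do not establish.

## Structural model of the two superfamilies

An element is diagnosed from repeat pairs found by comparing the sequence
with itself (direct orientation) and with its reverse complement (inverted
orientation) using seed-and-extend: exact k-mer seeds (default word 11)
grouped by diagonal, merged when closer than 40 bp, X-drop extended
(+1/−2, drop 12) and trimmed to the longest window within the mismatch
budget (default 20%). An exhaustive diagonal-scan oracle verifies the
scanner on small inputs in the test suite.

* **DIRS-like** requires an inverted pair with one member in each terminal
  window (default: the outer 15% of the element; no published figure exists
  for "terminal", this is a package decision). Minimum ITR length 50 bp.
  The ICR is then sought in the internal region as two adjacent segments
  (>= 20 bp each, joined within 15 bp) reverse-complementary to the
  element's terminal stretches; its annotation may overlap the right ITR by
  up to 20 bp, since the real elements' ICR and ITR overlap slightly and no
  published number quantifies "slightly".
* **Ngaro-like** requires direct-repeat pairs arranged `A1 ... B1 A2 B2`
  with A1 starting in the 5' terminal window. Ten bases of interval overlap
  are tolerated in the order test because X-drop extension can overrun a
  true block boundary on chance matches (a 1-in-4 event per base).
* Conflicting evidence (both patterns) yields `unclassified` with a reason
  code rather than an arbitrary pick.

Completeness: `complete` needs every expected repeat (ICR and `TTT` termini
for DIRS-like, all four SDR blocks for Ngaro-like) and, when ORF domain
hits are supplied, every expected domain (gag, RT, RH, YR for DIRS-like —
the methyltransferase is optional, being absent from many real families —
and RT, RH, YR, SGNH for Ngaro-like). Missing domains give `degenerate`;
missing accessory repeats give `partial`.

## ORFs and domain markers

ORFs are ATG-initiated, stop-terminated, >= 75 nt counting the stop codon
(the common ORFfinder convention; `include_stop=False` flips it), reported
for all six frames as the 5'-most ATG of each stop-to-stop segment.

Domain detection runs offline against six packaged 30-aa synthetic marker
peptides (gag, RT, RH, MT, YR, SGNH stand-ins; the RT marker carries a
YxDD-style box, the SGNH marker its four namesake residues). A marker hit
is an ungapped window whose BLOSUM62 sum reaches mean + 5 SD of a null
distribution of random windows (uniform amino-acid background, 1000
windows, fixed seed) — a conserved-domain-database search is deliberately
out of scope, so these markers define the package's notion of "domain".

## Homology search and masking

`translated_search` seeds with BLOSUM62 4-mer neighbourhoods (threshold 13,
the classic BLASTP choice) on all six reading frames and extends ungapped
with X-drop 20; the top hits are returned with 3 kb flanks by default.
`mask_genome` seeds nucleotide 11-mers, chains collinear segments
(gap <= 500 bp, diagonal band 100), stitches them into gapped alignments
(short gaps filled by a global affine aligner: +1/−1.5, open −4,
extend −0.5), and resolves overlapping hits from different families by
score, ties to the earlier library entry. No low-complexity filtering is
implemented: the synthetic background is i.i.d. random, so there is nothing
to filter; the flag is reserved.

## Divergence, CpG adjustment, ages

K2P is computed over ungapped alignment columns; the distance is flagged
saturated (and the copy excluded from landscapes) when a log argument is
non-positive. The CpG rule follows the RepeatMasker utility convention: a
transition at a consensus CpG counts 0.1 of a transition, two transitions
at one CpG count as one. The 0.1 weight is the inverse of an assumed ~10x
CpG transition hypermutability; accordingly the demo world's generator runs
CpG transitions 10x hot, which makes the adjusted K the consistent
estimator there (raw K2P overestimates a K=0.02 wave as ~0.031). With CpG
hypermutation off (`cpg_factor=1`), raw K2P is unbiased to <1% at K <= 0.3
and the adjustment would undercount by design — tests therefore pair each
estimator with its matching world.

Ages use T = K/r, r = 3.1e-9 substitutions/site/year (the averaged rate of
the two Xenopus genomes). Landscapes bin masked copy bp by K in 0.01-wide
bins as % of the genome. A wave planted exactly on a bin edge necessarily
splits between the two adjacent bins (the per-copy K standard error is
~0.002 at K=0.02 on a 5.4 kb copy), so wave recovery is asserted as "mode
within one bin of the truth bin".

## Families and consensus

Pairwise divergence is 1 − matches/columns on a global affine alignment,
**counting gap columns** — the way divergence reads off a multiple
alignment where non-homologous stretches sit against gaps. This choice is
load-bearing: gap-free identity between unrelated DNA sequences never
falls below ~25% (4-letter alphabet), so an 80% divergence threshold could
never separate anything under a gaps-excluded definition. The aligner
(match +1, mismatch −2, open −8, extend −0.15) was set so that unrelated
sequences gap out (measured divergence ≈ 0.9–0.96) while same-family copies
even at mutual distance ~0.5 stay substitution-aligned (≈ 0.55–0.63),
leaving a wide safe margin around the 0.80 threshold.
`exclude_gap_columns=True` restores the literal non-gap definition.

Clustering is single linkage (connected components of the <= 0.80 graph),
matching the practice of giving chains of similar variants one family
name; complete linkage is available by flag. Consensuses are 50%
majority-rule over a center-star progressive alignment (center = minimum
summed divergence; "once a gap, always a gap"): the most frequent residue
wins a column when it reaches 50% of non-gap residues with a strict
plurality, ties emit the IUPAC code of residues above 25%, gap-majority
columns are dropped. Center-star is not refinement-grade multiple
alignment, but at the divergences involved (<= ~0.3 within a family) it
recovers a 2 kb ancestor to within 1% from 20 copies.

RT-based trees keep sequences with >= 70% coverage of the reference RT
length (boundary inclusive). Distances are Poisson-corrected by default
(−ln(1−p)); gamma correction (shape 1.0) and p-distance are options. A
maximum-likelihood JTT+Γ distance is deliberately not implemented: at
these divergences the distances, not the substitution model, drive
neighbor joining, and the model choice in the original analysis was a
model-selector artifact. Corrected distances clamp p at 0.99 to stay
finite in bootstrap resamples. NJ is the canonical Saitou–Nei
agglomeration; negative branch lengths are clamped to zero with the
excess moved to the sister branch, and zero-length internal edges are
collapsed to polytomies (identical taxa give a star, not an arbitrary
binary shape). Bootstrap support is the percentage of column-resampled
replicate trees containing each bipartition of the full-data tree; the
library test default is 100 replicates (scaled down from the conventional
1000, which remains the CLI default).

## The synthetic world

The generator writes elements with exactly the structures above: `TTT`
termini, exact 120 bp ITR reverse complements (a configurable 10 bp
ICR-into-ITR annotation overlap trades that many ITR mismatches for
realism), ICR segments complementary to the element termini, 236/152 bp
SDR blocks at 100% identity, and overlapping ORFs whose frames are
reconciled by stochastic repair (premature stops resampled until all
frames are clean; start/stop/marker codons anchored, plus a stop just 5'
of each start so planted ORFs are exactly maximal). Mutation is site-wise
K2P (default transition/transversion ratio kappa = 2, a typical nuclear
value) with the CpG multiplier applied to input CpG sites; indels are off
by default (no indel model is published for these elements) and, when
enabled, geometric with rate <= the substitution rate. Copies are planted
uniformly without overlap on random strands; truncated copies lose 5–50%
from one or both ends. ESTs are 150–400 bp consensus fragments at K=0.02.
The background is i.i.d. at GC 0.4 — roughly the frog genome average — with
no repeats other than the planted ones, which keeps masking unambiguous.

The demo world (200 kb, two DIRS-like families with 8 copies each at
K=0.02 and K=0.25, one Ngaro-like with 5 copies at K=0.10, 40 ESTs) states
wave sizes that the source analysis never quantified: per-family copy
numbers are free parameters and were chosen once to give clearly separable
waves at desk scale.

Hence a green test establishes: correct structural logic, unbiased
divergence estimation, faithful landscape accounting and tree consistency
— on clean, non-nested, indel-free insertions in random background. It
does not establish performance on real genomes with nested/fragmented
repeats, low-complexity sequence, or assembly artifacts, nor
database-grade domain annotation.

## Degenerate inputs and tie-breaks

Sequences shorter than twice the minimum repeat length scan to an empty
result rather than an error. Repeat-pair ties break by identity x length,
then 5'-most. Masking ties break toward the earlier library entry.
Cluster labels follow first appearance; landscape output is invariant to
record order. All randomness flows from a single seed through named
substreams (library/copies/placement/background/ests; the pipeline spawns
one more for the bootstrap), so equal configs give byte-identical FASTA,
BED and TSV outputs.
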