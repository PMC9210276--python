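# yrscout

Structural annotation and evolutionary dynamics of tyrosine-recombinase
(YR, DIRS-order) retrotransposons.

## The problem

DIRS-order retrotransposons integrate through a tyrosine recombinase rather
than an integrase or endonuclease, and their two main superfamilies carry
diagnostic non-coding terminal structures instead of ordinary LTRs:

* **DIRS-like** — inverted terminal repeats (ITRs, ~120 bp) flanking the
  coding region, an internal complementary region (ICR) whose two halves are
  reverse complements of the element's 5' and 3' termini, thymine
  trinucleotide (`TTT`) termini, and three ORFs (gag; RT/RH, often with a
  DAM-methyltransferase; YR).
* **Ngaro-like** — split direct repeats (SDRs) arranged `A1 ... B1 A2 B2`
  with `A1 = A2` and `B1 = B2`, and an extra ORF encoding an SGNH-hydrolase
  domain after the YR. The ORF reading frames overlap.

`yrscout` turns those diagnostics into a reusable pipeline: it detects the
repeat architecture of a consensus element by self-comparison, finds ORFs
(ATG-only, >= 75 nt) and conserved-domain markers, retrieves and masks
genomic copies, groups copies into families at the 80%-divergence threshold
with 50% majority-rule consensuses, computes CpG-adjusted Kimura
2-parameter divergence landscapes with age dating, and builds
neighbor-joining trees with bootstrap support from RT protein alignments.

Because the real inputs (Repbase libraries, frog genome assemblies) are not
shippable, the package includes a first-class synthetic-data generator that
emulates them — consensus elements with known architecture, a genome with
planted copies forming amplification waves of known divergence, EST-like
reads — together with truth tables, so every stage is testable end-to-end.

## The statistics at the core

Divergence of a copy from its family consensus is the Kimura 2-parameter
distance over ungapped alignment columns,

    K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)),

with P and Q the transition and transversion fractions. Transitions at
consensus CpG dinucleotides are down-weighted to 0.1 of a transition (two
transitions at one CpG count as a single full transition), compensating the
~10x hypermutability of methylated CpG sites. Copy age follows

    T = K / r,      r = 3.1e-9 substitutions/site/year,

the average substitution rate of the *Xenopus tropicalis* and *X. laevis*
genomes. The evolutionary landscape bins masked copy bp by K (bin width
0.01) as a percentage of the genome; peaks are amplification waves.

## Worked example

```python
>>> import numpy as np
>>> from yrscout import synthgen, analyze_element, kimura2p, age_from_divergence
>>> cons = synthgen.make_dirs_like_consensus(
...     synthgen.FamilySpec.dirs_default("DIRS-A"), np.random.default_rng(1))
>>> arch = analyze_element(cons.sequence, {"GAG", "RT", "RH", "MT", "YR"})
>>> arch.superfamily_call, arch.completeness, arch.itr5, arch.itr3
('DIRS-like', 'complete', (3, 114), (5286, 5397))
>>> copy = synthgen.mutate_copy(cons.sequence, 0.10, np.random.default_rng(2))
>>> P, Q, K = kimura2p(copy, cons.sequence)
>>> round(K, 3), round(age_from_divergence(K) / 1e6, 1)
(0.093, 30.1)
```

The full pipeline runs from one config (or the shell):

```bash
yrscout run --seed 1 --out demo_run
```

and prints a summary like

```
Elements in library: 3
- DIRS-like: 2 (complete: 2)
- Ngaro-like: 1 (complete: 1)
Total masked: 96421 bp (48.211% of 200000 bp)
- DIRS-like: 72225 bp (36.112%)
- Ngaro-like: 24196 bp (12.098%)
Copy clusters at the family threshold: 3
Copies dated: 21; K range 0.019-0.260 (ages 6.0-84.0 My)
```

for the built-in demo world (two DIRS-like families amplifying at K=0.02
and K=0.25, one Ngaro-like at K=0.10): the three planted families come back
as three clusters, the masked densities match the planted proportions, and
the landscape modes sit at the planted wave divergences.

Other subcommands: `yrscout generate`, `annotate`, `orfs`, `search`,
`mask`, `ests`, `families`, `tree` — each a thin wrapper over one library
module.

## Acceptance script

`scripts/acceptance.py` re-runs the package's full demo analysis from
scratch (generation, annotation, masking, divergence landscape, family
clustering, RT tree, EST evidence) under a given seed and writes the
results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the models, defaults and numerical choices.
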