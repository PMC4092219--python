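# singlecopy

Comparative-genomics toolkit for identifying and characterizing
**single-copy genes** across multiple annotated genomes.

Single-copy genes — genes with no detectable paralog in their own genome —
are prized in plant comparative genomics: they escape repeated rounds of
whole-genome duplication (WGD), tend to be under strong purifying
selection, and make clean phylogenetic markers because orthology is
unambiguous. This package implements the full analysis around them:

* **Identification.** Within-genome all-vs-all protein search (affine-gap
  local alignment, Karlin–Altschul E-values) at E ≤ 1e-10 with a
  200-alignment cap marks genes without in-paralogs as *single copy*.
  Cross-genome search at E ≤ 1e-5, query coverage ≥ 70 % and identity
  ≥ 30 % feeds a from-scratch Markov Cluster (MCL) algorithm at inflation
  5.0; clusters are confirmed by iterated reciprocal-hit filtering.
  A single-copy gene with no cross-genome hit at all is a *singleton*;
  a confirmed cluster with exactly one member from every genome is a
  *shared single-copy* gene (strict 1:1:…:1).
* **Duplicate blocks.** Collinear duplicate blocks are chained from paralog
  anchors by dynamic programming over gene ranks (≥ 5 collinear pairs,
  ≤ 20 intervening genes per chromosome), linking single-copy abundance to
  segmental/whole-genome duplication history.
* **Codon usage.** Per-gene Nc (Wright's effective number of codons,
  `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆` over family homozygosities,
  clamped to [20, 61]), GC3, RSCU and CAI (geometric mean of relative
  adaptiveness weights from a highly-expressed reference set).
* **Ka/Ks.** NG86 counting over protein-guided codon alignments of
  reciprocal-best-hit pairs: 1/3-per-position site counting, minimal
  mutational pathway averaging, Jukes–Cantor correction
  `d = −(3/4)·ln(1 − (4/3)p)`.
* **Statistics.** Spearman rank correlation (mid-rank ties, two-sided
  t-approximation), Mann–Whitney U (exact enumeration for small samples),
  one-way ANOVA + Tukey HSD, and alternative-splicing comparisons binned
  by family size (single copy / 2–10 members / > 10).
* **Phylogeny.** Shared single-copy genes are aligned (progressive global
  alignment), concatenated into partitioned supermatrices — CDS-only or
  including introns — and analyzed with neighbor joining + bootstrap;
  relaxed-PHYLIP matrices and partition files are exported for external
  maximum-likelihood tools.
* **Simulation.** A multi-genome generator evolves gene families by
  birth–death duplication/loss and WGD along a species tree, with
  class-dependent codon bias, GC3 and omega, planted collinear blocks, and
  family-size-dependent alternative-splicing counts — every emitted gene
  carries truth labels, so the entire pipeline is verifiable end to end
  without any downloads.

## Worked example

Run the numbered analysis scripts from the repository root (each regenerates
the default five-genome simulation from its seed and writes tables under
`results/`):

```bash
python analysis/01_simulate.py
python analysis/02_identify_single_copy.py
```

Output of `02_identify_single_copy.py`:

```
single-copy: precision 1.000 recall 1.000
singleton: precision 1.000 recall 1.000
shared 1:1 clusters detected: 62
  A: 105 genes, 105 single copy (100.0%), 5 singletons (4.8%), 0 blocks
  B: 105 genes, 105 single copy (100.0%), 5 singletons (4.8%), 0 blocks
  C: 108 genes, 102 single copy (94.4%), 5 singletons (4.9%), 0 blocks
  D: 108 genes, 102 single copy (94.4%), 5 singletons (4.9%), 0 blocks
  E: 141 genes, 70 single copy (49.6%), 5 singletons (7.1%), 2 blocks
```

Genome E carries the simulated WGD (retention 0.25): its single-copy
fraction halves and it is the only genome with detected collinear blocks —
the duplication/single-copy trade-off the comparative analysis measures.
Classification recovers the simulator's truth labels exactly here.

`analysis/07_genome_survey.py` applies the same summary statistics to the
bundled survey of 29 published angiosperm genome annotations:

```
single-copy percentage: 7.6% - 35.5%
singleton/single-copy ratio: 10.9% - 68.3%
Spearman blocks vs single-copy %: rho=-0.694, p=2.956e-05
```

i.e. genomes with more duplicate blocks retain proportionally fewer
single-copy genes. The remaining scripts cover codon-usage contrasts (03),
Ka/Ks between genome pairs (04), alternative-splicing binning with
ANOVA/Tukey (05) and the supermatrix phylogenies with and without introns
(06).

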