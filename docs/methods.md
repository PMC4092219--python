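# Methods

This note documents the models, parameter choices and numerical conventions
behind `singlecopy`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Similarity search and filters

Protein pairs are aligned with exact affine-gap local alignment (BLOSUM62,
gap open 11, gap extend 1 — a gap of length k costs 11 + k). E-values use
the Karlin–Altschul form E = K·m·n·exp(−λS) with the standard gapped
constants λ = 0.267, K = 0.041; m is the query length and n the total
residue count of the searched genome(s). Two filter regimes drive the whole
analysis:

* **self-search** (within a genome): E ≤ 1e-10; at most 200 non-self
  subjects per query, ordered by E-value, then score, then subject id (the
  self-hit never counts against the cap);
* **cross-search** (between genomes): E ≤ 1e-5 AND query coverage ≥ 0.70
  AND identity ≥ 30 %.

Coverage is measured on the query only, from the single best local
alignment. Both filters are pure and idempotent and are applied identically
to hits ingested from an external tabular file, so built-in and external
search are interchangeable downstream. A shared-4-mer prefilter skips pairs
with no common 4-mer; at the package's working scale (~100–200-residue
proteins, families below ~30 % divergence) such pairs sit far below every
threshold, and `prefilter=False` forces the exact path.

## MCL clustering

The cross-genome similarity graph weights each undirected edge by
−log10(E), E capped at 1e-200, symmetrized by taking the larger direction;
`bitscore` weighting is available. Self-loops are set to the node's maximum
incident weight before column normalization (standard regularization). The
iteration is expansion (squaring), inflation (elementwise power, default
5.0 — deliberately stringent so clusters split rather than lump), pruning
below 1e-5 with renormalization, until the maximum column change falls
below 1e-8. Clusters are read off the attractor structure; a node attracted
to several systems joins the larger cluster, ties broken by the
lexicographically smallest member id, so results are deterministic.
Components are clustered independently (clusters can never span
disconnected components). An exact dense mode (no pruning) backs the test
oracle.

Cluster confirmation then removes, iteratively (3 rounds by default, fixed
point usually after 1–2), every member lacking a reciprocal filtered hit to
at least one member from each other genome in its cluster.

## Copy classification

A gene is *single copy* iff it has no passing non-self self-search hit;
family size is its connected-component size in the non-self hit graph. A
*singleton* is a single-copy gene with zero filtered cross-genome hits. A
*shared single-copy* cluster contains exactly one member from every genome
(the strict definition; the relaxed few-duplicates variant is deliberately
out of scope). Where several transcripts share a locus prefix, the longest
protein represents the locus.

## Collinear blocks

Anchors are deduplicated non-self paralog pairs (best E-value kept).
Tandem pairs (adjacent ranks on one chromosome) are collapsed before
chaining. For each chromosome pair and each orientation, the longest chain
with strictly monotone ranks and at most 20 intervening genes per
chromosome (gap = rank difference − 1) is found by O(n²) dynamic
programming; chains are extracted greedily (longest first, deterministic
leftmost tie-break; same orientation preferred on ties), each anchor used
at most once, and chains shorter than 5 pairs are discarded. Scoring is
unit-per-anchor; E-value-weighted scoring was left out because only the two
thresholds are part of the method's definition.

## Codon usage

Nc follows Wright's estimator: per synonymous family with n ≥ 2 counted
codons, F̂ = (n·Σp̂² − 1)/(n − 1); families with n < 2 or F̂ ≤ 0 are
excluded from their redundancy-class mean; Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
3/F̄₆, with the six-fold families (Leu, Ser, Arg) as their own class —
required for the analytic endpoints 20 and 61 to hold. If an entire class
has no usable family, Nc is undefined rather than imputed. The finite-sample
estimator can exceed 61 slightly, so values are clamped to [20, 61]. GC3 is
the G+C fraction at third positions of all counted sense codons (not the
synonymous-only GC3s variant). RSCU is observed count over family mean.
CAI weights are w(c) = RSCU(c)/RSCU_max(family) from a pooled reference
set; codons unobserved in the reference get RSCU 0.5 (half the family mean)
before weighting — this keeps CAI defined and makes the weights invariant
to duplicating the reference. CAI itself is the geometric mean of w over a
gene's sense codons, excluding Met, Trp and stops, computed in log space.
CAI values are comparable only within a run (they depend on the chosen
reference set); the analysis script uses the lowest-Nc gene quantile as a
bias-based stand-in for a highly-expressed reference set.

## Ka/Ks (NG86)

Reciprocal best hits (lowest E, ties by score then id, kept only when
mutual) are aligned at the protein level (global affine-gap) and
back-translated codon-wise. Synonymous sites per codon follow the
1/3-per-position rule; mutations to stops count as nonsynonymous.
Differences per codon are averaged over all minimal mutational pathways,
excluding pathways through stop codons (if every pathway passes a stop,
all differing positions count as nonsynonymous). Site counts are averaged
between the two sequences; proportions are Jukes–Cantor corrected; p ≥ 3/4
yields an undefined (saturated) value, flagged. Columns with gaps,
ambiguity codes or stop codons are excluded pairwise. The estimator is
exactly symmetric in its inputs.

A counting estimator was chosen over likelihood-based codon models because
it is deterministic, oracle-checkable by per-codon enumeration, and
standard; results carry a `method = "NG86"` tag and the result type leaves
room for alternative estimators.

## Statistics

Spearman's rho is the Pearson correlation of mid-ranks; the two-sided p
uses t = rho·√((n−2)/(1−rho²)) with n−2 degrees of freedom (adequate for
n ≈ 29; exact permutation available for n ≤ 10). Mann–Whitney U counts
x > y pairs with ties at 1/2; p is exact by enumeration for n₁+n₂ ≤ 12,
otherwise a tie-corrected normal approximation with continuity correction
(the two agree to ~0.02 at the boundary — the intrinsic accuracy of the
approximation there). ANOVA uses the standard one-way F; Tukey HSD uses
studentized-range quantiles. All tests are two-sided.

Alternative-splicing comparisons bin genes by family size: 1 → single
copy, 2–10 → small family ("1–10 in-paralogs": a single-copy gene has 0
in-paralogs, so the bin starts at size 2), ≥ 11 → large family; the edges
are arguments. ANOVA/Tukey runs on per-gene AS event counts across bins;
the per-bin distributions over event counts are reported alongside. Raw
counts are used (no arcsine transform).

## Phylogeny

Per-gene alignments are progressive: the center sequence (highest total
pairwise score) is the guide and remaining sequences merge into the profile
in decreasing score-to-center order under "once a gap, always a gap"
(match 2, mismatch −1, gap open 5, extend 1 — nucleotide scale).
Supermatrices concatenate per-gene alignments over a fixed taxon order with
1-based inclusive partitions that tile the length exactly. Distances use
pairwise deletion of gap/ambiguous columns (complete deletion by flag) and
either p-distance or Jukes–Cantor; JC saturation (p ≥ 3/4) is an error
naming the pair. Neighbor joining is canonical, with a lexicographic
tie-break on the Q-criterion so star-like inputs resolve deterministically;
on additive matrices it recovers the generating topology and branch lengths
exactly. Bootstrap resamples columns with replacement (seeded NumPy
generator); support is the percentage of replicate NJ topologies containing
each internal bipartition. Outgroup rooting requires the outgroup set to be
one side of an edge of the unrooted topology; a non-monophyletic outgroup
is an error, not a silent reroot. Maximum-likelihood inference is export
only (relaxed PHYLIP + partition file): NJ + bootstrap is the built-in,
fully testable surrogate at desk scale.

## Synthetic data

The generator is the package's verification instrument; its defaults define
the study conditions for every end-to-end test.

* **Species tree** `((A:0.06,B:0.06):0.04,(C:0.06,D:0.06):0.04,E:0.10)`,
  100 base families, 120 codons per CDS.
* **Classes.** Half the families are duplication-resistant ("conserved"):
  duplication and loss rates 0, omega 0.1, strong codon bias (preferred
  codon boosted 8×) with target GC3 0.30. The rest are "duplicable":
  duplication 0.35 and loss 0.10 per gene per unit branch length, omega
  0.5, no bias, target GC3 0.60. This plants the contrasts the analysis
  measures: conserved families stay single copy and shared, show lower Nc
  and GC3, and accumulate less nonsynonymous change.
* **WGD** on the branch to E with retention 0.25: each gene is copied and
  each extra copy kept with p = 0.25, laid down as a parallel chromosome so
  retained copies form collinear blocks at known positions (truth records
  runs of ≥ 5 pairs with gaps ≤ 20). Per branch, a lineage first survives
  loss (p = e^(−loss·t)), then spawns Poisson(dup·t) copies; new copies do
  not duplicate again within the same branch, so the expected copy number
  multiplies by e^(−loss·t)·(1 + dup·t) per branch — the closed form the
  tests check.
* **Sequences.** Root CDS are sampled per class (within each synonymous
  family, probability mass target_gc3 on G/C-ending codons; the majority
  group's first codon boosted by the bias factor). Evolution proposes
  point mutations at rate 1 per site per unit branch length; stops are
  rejected, synonymous changes accepted, nonsynonymous accepted with
  probability omega — so NG86 recovers the planted omega under uniform
  mutational pressure. Introns (2 per gene, 60 nt, GT…AG) sit at fixed
  per-family positions and evolve neutrally at 3× the exonic proposal rate.
* **Orphans** (5 % of the base-gene count per genome) are random novel
  genes — the planted singletons.
* **AS counts** are Poisson with bin-dependent means 1.2 (single copy),
  2.0 (family 2–10), 0.6 (family > 10), mirroring the observed ordering in
  which small families splice most.

One integer seed drives all randomness; identical seeds give byte-identical
output files.

What the simulation does **not** emulate: real intergenic/repeat content
and transposable elements, rate heterogeneity across sites and lineages,
alignment-hostile divergence (families sit safely inside the 30 % identity
filter), gene conversion, tandem-array expansion dynamics, and realistic
expression data. Perfect recovery on the default simulation therefore
demonstrates correctness of the pipeline's logic under its stated
assumptions, not robustness to the noise profile of real annotations.

## Problem sizes and checks

The default verification workload is the 5-genome, ~570-gene simulation
(seconds on one core). Omega recovery uses 150 replicate pairs of 300
codons per planted omega, compared as pooled mean(Ka)/mean(Ks) — the pooled
ratio avoids the upward Jensen bias of averaging per-pair ratios at small
Ks. Bootstrap examples use 100–200 replicates. Every nontrivial algorithm
is checked against an independent oracle at small size: local/global
alignment against brute-force Gotoh DP, MCL against a dense no-pruning
transcription, block chaining against exhaustive chain enumeration, NG86
against per-codon pathway enumeration, Nc against an independent
homozygosity computation, CAI against a log-domain recomputation, Spearman
and Mann–Whitney against scipy and exact enumeration, and NJ against
scikit-bio and closed-form additive fixtures.

## Known limitations

* E-values are analytic Karlin–Altschul estimates for the built-in scoring
  scheme; they are not calibrated to reproduce any external search tool's
  statistics (edge corrections, composition adjustment, HSP tiling).
* The 200-alignment cap cannot hide a paralog under the strict
  no-non-self-hit rule (any surviving hit disqualifies a gene), but
  hit-count-based variants built on top of the capped lists would need
  care for very large families.
* Block counts are per detected chain; a duplication event split by a
  large insertion is counted twice, as with gene-rank chaining generally.
* CAI depends entirely on the supplied reference set; absolute values are
  not comparable across runs or to other tools' built-in references.
* The progressive aligner is a desk-scale center-star variant; for deep
  divergences or many taxa a dedicated MSA tool should be substituted at
  the `gene_alignment` boundary.
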