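# Methods

## Model and design

The scorer is a binary classifier over 58-dimensional feature vectors of
non-coding SNVs, trained to separate pathogenic variants of monogenic
Mendelian disease from common population variants.  Its defining property is
not the learner (standard gradient-boosted trees, binary log-loss, probability
output) but the sampling and partitioning design around it:

* **Gene partitions.** Protein-coding genes are split into k = 10 partitions,
  stratified jointly by chromosome and by whether the gene carries a curated
  pathogenic variant.  Within every (chromosome, has-pathogenic) stratum the
  genes are shuffled with a seeded generator and dealt round-robin from a
  random offset, so partition counts within a stratum differ by at most one.
  Round-robin after a stratified shuffle is the simplest scheme that makes the
  balance property exact and testable rather than approximate.
* **Bundle training.** Model *j* is trained on all partitions except *j*.
  A hard gate re-derives each training row's partition from its gene and
  aborts training on any overlap with the held-out partition.  Scoring routes
  each variant to the model blind to its gene; genes absent from the partition
  map fall back to the arithmetic mean of all k member outputs and are flagged
  `model_index="mean"` (the symmetric choice; only mapped genes have a defined
  held-out model).
* **Matched negatives.** Each positive (capped at one per gene, chosen
  uniformly under the seed) draws 10 negatives without replacement from the
  common-variant pool restricted to the positive's partition and region type.
  The one-negative-per-gene cap is enforced globally across the table; when a
  (partition, region) cell cannot supply enough distinct unused genes, the cap
  is relaxed for that positive only (repeat genes allowed across pairing
  groups, never within one), the relaxation is recorded in the sampling
  metadata, and the exact 1:10 global ratio is preserved.  A cell that cannot
  supply the ratio even relaxed is a hard error naming the cell.

## Region typing

Coordinates are 1-based inclusive everywhere (VCF convention); BED-style
half-open inputs are converted at the reader boundary.  One canonical
transcript per gene is assumed — collapsing isoforms is the data producer's
job.  Typing is strand-aware: inside the transcript span, exonic positions
within the CDS span are *coding* (excluded); exonic positions 5′/3′ of the
CDS are 5′UTR/3′UTR; positions between exons are intronic.  Outside the span,
positions within the upstream/downstream windows (default 1000 bp each,
configurable — the window size is a package choice matching common annotator
practice, not an external given) are upstream/downstream; beyond that,
positions within the intergenic cap (default 10 kb) are intergenic, assigned
to the nearest gene; beyond the cap a variant is unscorable, because
gene-anchored features are meaningless at arbitrary distance.

When several genes claim a position: any coding-exon overlap excludes it;
otherwise genic non-coding (UTR5 > UTR3 > intronic) beats upstream, which
beats downstream, which beats intergenic; remaining ties go to the smaller
distance to the transcript span, then the lexicographically smaller gene id.
This makes assignment single-valued and deterministic.

## Curation

The positive-set filter cascade, in report order: SNVs only; scorable
non-coding region assigned; internally consistent pathogenic assertions;
monogenic Mendelian inheritance; no population homozygotes (threshold 0 by
default) and population allele frequency ≤ 0.1%; de-duplication by variant
key (first-seen source kept).  "Consistent pathogenic" is read strictly: the
union of a variant's assertions across sources must contain a
pathogenic-side label and must not contain any benign-side or uncertain
label — records with no pathogenic-side assertion at all fail the same
filter, since the output is a pathogenic set.  Each filter is a pure
predicate, so the surviving set is order-independent; the telescoping report
is defined by the order above.  Negative pools: *common* keeps allele
frequency ≥ 1%, *rare* keeps 0 < AF ≤ 0.1% (both configurable; the cutoffs
are package defaults, recorded in run metadata).

## Feature schema

58 features, 26 flagged new-in-v2, in four categories: interspecies
conservation (14; including four large-alignment mammal/primate slots),
human constraint (14; a global slot plus nine per-subpopulation constraint
slots), gene level (20; including loeuf and other population-scale gene
scores), sequence context (10; GC content, CpG content, the 6-way region
one-hot, and the variant- and position-level splice-delta maxima).  Outside
the structurally fixed slots the names are **provisional placeholders** that
preserve the category structure and counts; a custom schema can rename them
without touching any code path.

Annotation sources implement a small contract (declared feature subset +
per-variant lookup); tabix-indexed TSV, in-memory tables, FASTA context
windows (default 101 bp, odd, truncated at chromosome ends) and per-alt
splice-delta tables are provided.  Two sources declaring the same feature is
a configuration error at setup; a source failing at lookup leaves its
features missing with a counted warning.  Missing values are passed to the
trees as native missing and never imputed — tree learners route missing
values; inventing an imputation model would add assumptions the design does
not need.

GC fraction divides by the non-N bases of the window; CpG fraction counts CG
dinucleotides over window-length−1 positions, excluding N-containing
dinucleotides from the numerator; truncated windows shorten the denominators.

## Hyperparameters

Defaults (all configurable, all serialized with the bundle): 500 boosting
rounds with early stopping after 25 stagnant rounds on a 10% held-in
validation split grouped by gene; learning rate 0.05; max depth 6;
min-child-weight 1; subsample 0.8; column subsample 0.8; positive-class
weight 1 — the 1:10 class ratio is part of the design and deliberately left
unreweighted.  Training is single-threaded by default for bit-reproducibility;
multithreaded training is supported with the usual floating-point
reproducibility caveat.

## Synthetic data

The generator emulates exactly the statistical structure the framework
exploits, and nothing more:

* Genes with fixed two-exon geometry (2.4 kb transcript, 300 bp UTR blocks,
  1.2 kb intron) laid out every 8 kb along 22 chromosomes, random strand.
  Positions for every region type are sampled inside ranges that the
  geometric region classifier provably maps back to the same type (tested).
* A positive set with one pathogenic SNV per disease gene; region mix follows
  the cross-validation composition of the curated set (upstream 61 : 5′UTR
  133 : intronic 475 : 3′UTR 77 : downstream 9 : intergenic 10).  Reference
  scale is 765 positives over 10 000 genes with a pool of one common variant
  per gene per region type (60 000 candidates), ratio 10.
* Continuous features: unit-variance Gaussians, mean 0 for benign and *d* for
  pathogenic (per-category effect size in SD units, default 1.0 — a moderate,
  clearly-nonseparable reference signal).  Features with a [0, 1] domain pass
  through a logistic squash; the transform is monotone, so tree-based
  separability is unchanged while schema domains hold.
* Gene-level features are constant per gene and shifted for genes hosting a
  pathogenic variant.
* A per-region baseline shift is added to the features of all variants in
  that region (default +0.5 SD for 5′UTR), emulating the observed regional
  score bias.  The bias acts on features, not labels, so the per-gene bias
  analysis has a true positive control.
* A fraction of positives (default 0.3) is *splice-driven*: their non-splice
  shifts are scaled down to 0.25·d while the two splice-delta slots separate
  strongly — and the splice separation itself scales with d, so d = 0 means
  no signal anywhere.
* Missingness is applied uniformly per category (defaults 0.10 / 0.10 / 0.05 /
  0).  Decoy records violating individual curation filters, and extra
  positives violating the per-gene cap, are available behind explicit knobs
  (all zero under reference conditions).

What the generator does **not** emulate: linkage structure, mutation-rate
heterogeneity, realistic allele-frequency spectra, feature correlations
within categories, and overlapping or multi-isoform genes.  Passing tests on
synthetic data therefore demonstrate the correctness of the pipeline's
bookkeeping (matching, partitioning, leakage control, metric computation) and
its ability to recover injected signal — not clinical performance on real
genomes.

## Evaluation procedures

* **Region-stratified report**: a global row plus one row per region in the
  canonical order; regions with a single class get NA metrics and a warning.
  AUROC is the rank statistic (probability a random positive outranks a
  random negative, ties half-credited), identical to the trapezoidal ROC
  area.  AUPR is average precision — a step-sum over recalled positives with
  tied scores grouped into one threshold — chosen over trapezoidal
  interpolation because it is tie-robust and matches an exhaustive oracle
  exactly.
* **Per-gene region bias**: per-(gene, region) medians of common-variant
  scores; for each region, a one-sided rank-sum test of pathogenic scores in
  that region against the per-gene 5′UTR common medians (alternative:
  pathogenic greater).  Single-variant gene medians are kept but counted.
* **Spike-in ranking**: each inserted score is ranked within an individual's
  background score vector as `100·(#below + ties/2)/(n+1)` — the midrank
  convention avoids hard 0/100 saturation and the inserted variant itself is
  not part of the background (hence the n+1 denominator).  Pathogenic vs
  matched-common percentiles are compared with a one-sided paired signed-rank
  test; two methods are compared on their pathogenic percentiles the same
  way.
* **Splice added value**: per gene, the top splice position's raw splice
  score and the model's score at that position are converted to gene-rank
  percentiles (midrank, /(G+1) scale — the top of G=4 distinct genes sits at
  80%); disease vs non-disease genes are compared per column (two-sided
  rank-sum), and the two columns are compared on disease genes with a paired
  two-sided signed-rank test.

## Rank tests

Both Wilcoxon tests use full enumeration for small samples (combined n ≤ 12
for the rank-sum over all C(n, nx) group assignments; ≤ 12 non-zero pairs for
the signed-rank over all 2^m sign patterns), which is exact under ties
because enumeration runs on the observed midranks.  Beyond that, a
continuity-corrected normal approximation is used, refined with an Edgeworth
kurtosis term whose moments are computed exactly from the observed midranks
(finite-population sampling moments for the rank-sum; independent sign-flip
moments for the signed-rank).  The refinement subsumes the classical tie
correction and keeps the approximation within 0.01 of the enumerated p-value
at the mode boundary (tested to ~0.002 in practice).  Zero differences in
the signed-rank are discarded; an all-zero vector returns statistic 0,
p = 1 with a warning.

## Numerical and degenerate-input choices

* Scores are written at 6 decimal places; the precomputed-score writer
  requires (chrom, pos, alt)-sorted input and round-trips byte-identically.
* Metric functions raise on single-class input rather than guessing; the
  report layer converts that to NA-with-warning per region.
* Per-stage seeds derive from the global seed via
  `SeedSequence([seed, stage_index])`, so stages can be re-run independently
  yet reproducibly; every output directory carries its resolved
  configuration.
* `run-all` chains the stages on synthetic data; real-data runs compose the
  individual subcommands, whose file formats are identical to the synthetic
  outputs.

## Problem sizes in the test suite

The test suite exercises the full design at desk scale: the training-set
construction check runs at full reference scale (10 000 genes, 765
positives); bundle-dependent properties (signal recovery across effect sizes
d ∈ {0, 0.5, 1, 2, 3}, spike-in significance at 100 insertions × 20
individuals, region-bias recovery) run on 400-gene / 100-positive studies
with k = 10, chosen as the smallest configuration that keeps every region
populated and Monte-Carlo noise well inside the asserted margins.

## Known limitations

* Real annotation tracks (conservation, constraint, splice deltas) are
  consumed only through the lookup contract; the package ships no genomic
  data and does not recompute such tracks.
* One transcript per gene; indels, MNVs and non-coding genes are out of
  scope.
* Scores are raw classifier probabilities; no cross-dataset calibration is
  attempted.
* The feature identities beyond the structurally fixed slots are
  placeholders; schemas for real deployments should be supplied explicitly.
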