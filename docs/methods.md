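# Methods

This note documents the models, defaults and numerical choices behind
`organotropy`, and what the synthetic cohorts do and do not demonstrate.

## Problem decomposition

Organotropic progression is treated as N×M independent binary problems: for
each cancer type and each metastatic site with enough annotations, "did this
primary tumor progress to that site?". A tumor negative for the tested site
counts as a negative instance even if it metastasized elsewhere; patients
with several recorded sites contribute a positive label to each site's
problem independently. Rows whose progression timing contains "synchronous"
are excluded from both classes because the clinical ordering of primary and
metastasis is ambiguous there. Pair retention uses a literal reading of the
population thresholds: at least 8 positive site annotations (≥ 8) and a
total population strictly over 50 (> 50), so (n_pos = 8, n_total = 51) is
kept and (20, 50) is not. COAD and READ are merged into COADREAD before
labeling; the merge conserves sample counts.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
any particular dataset:

* **Counts.** Gamma–Poisson (negative-binomial) with per-transcript log
  means ~ N(3, 1), biological log-normal noise of s.d. σ₀ = 0.5, and
  dispersion φ (default 0.3, var = μ + φμ²).
* **Effect sizes are standardized on the observed scale.** A configured
  `effect_size` d shifts a signature transcript's log mean by d·σ_total,
  where σ_total² = σ₀² + φ + 1/μ₀ (delta-method approximation of the NB
  sampling noise). This makes d a Cohen's-d-like separation of positive vs
  negative samples per transcript after log transformation, so
  `effect_size=0` yields exactly exchangeable distributions and
  `effect_size=1.5` means what it says downstream.
* **Signatures.** Each cancer type gets a disjoint type signature
  (default 50 transcripts at d = 2), each (cancer, site) pair a tropism
  signature (default 20). Half of each tropism signature
  (`site_shared_fraction=0.5`) is a site core shared by every cancer
  metastasizing to that site — the organotropic structure the recapture and
  enrichment stages are designed to detect. Signature membership is recorded
  in a ground-truth JSON that the pipeline never reads.
* **Clinical text.** Site strings are drawn from a variant vocabulary with
  inconsistent case and whitespace, multi-site cells joined by "; ", and a
  configurable fraction of metastatic rows labeled "synchronous", so the
  harmonization stage is exercised rather than bypassed.
* **GO annotation.** Transcript→term multiplicity is 1 + Poisson(skew·Exp(1))
  — long-tailed, with skew = 0 degenerating to one term per transcript.
  Undersized terms are repaired by moving members from oversized terms,
  preserving the multiplicity distribution. An optional `seed_sets` argument
  adds terms concentrating given transcript sets (used to make planted
  signatures enrichable at desk scale). The term DAG is built by levels with
  edges only toward strictly lower levels, hence acyclic and rooted.

What passing tests show: the pipeline recovers planted mean-shift signal at
the configured effect size, does not invent signal under the null, and its
statistics match exact oracles. What they do not show: robustness to batch
effects, library-size artifacts, correlated co-expression modules, or any
real biological covariance structure — the generator draws transcripts
independently given their means.

## Balancing

SMOTE with k = 5 minority-class nearest neighbors (Euclidean on the
normalized expression scale; distance ties broken by lower instance index),
base instance and neighbor chosen uniformly at random, u ~ U[0,1]. The
stopping rule is the 80%-of-majority target: final minority count =
round_half_away(0.8 · majority), with no action if the minority already
meets it. Rounding is half-away-from-zero to avoid banker's-rounding
surprises at .5 targets. A minority of size ≤ k reduces k to minority − 1
with a warning; a minority below 2 is rejected. Synthetic provenance
(parents and u) is retained for leakage audits.

## Feature selection

Blocks are contiguous over the given feature order; with n features and B
blocks the first n mod B blocks get ⌈n/B⌉ features. Per-method notes:

* χ² uses per-block min–max scaling (the statistic requires nonnegativity);
  constant features scale to zeros and score 0.
* RFE wraps an L2 logistic estimator and removes the step fraction (default
  10%, at least one) of lowest-|coefficient| features per round; a feature's
  score is its elimination round. On convergence failure the fit is retried
  once at C/10, then the error propagates.
* Embedded methods: 100-tree forests (classifier, and regressor on the 0/1
  label) ranked by impurity importance, and L1 logistic (liblinear) ranked
  by |coefficient|.

Each method flags its top k features per block, where k is the per-block
keep count. The written sources give both "top 10%" and a fixed 50 per block
(≈ 600-feature blocks); the default honors the explicit 50 × 100 = 5000
count, with `keep_fraction=0.1` implementing the percentage reading.
Colinearity pruning (|Pearson r| ≥ 0.95, greedy in rank order so
higher-support features survive; zero-variance features treated as r = 0)
runs before truncation, so kept counts are post-pruning; exhausted blocks
are logged as shortfalls rather than padded. Cross-validated support is
available via `cv_folds` (majority-fold support); the default is a single
fit per block since no fold count is prescribed. Ranking ties break by
(vote desc, mean min–max-normalized score desc, feature index asc).

## Classifiers

Tumor type: gradient-boosted trees (histogram implementation; 300
iterations, depth 3, learning rate 0.1, seeded — all configurable), fitted
on a stratified 70/30 split. The 30% holdout mirrors the binary protocol;
the multiclass split is this package's documented assumption. Macro metrics
are unweighted means over classes present in the test set; a class never
predicted gets precision 0, and a class absent from the test set is excluded
with a warning. Site models: random forest by default (`model_kind="gbt"`
optional) on the pair's selected candidates; prediction rounds the posterior
with ties at exactly 0.5 going to the positive class (fixed, documented
convention). The evaluation protocol guarantees the holdout contains only
real samples and that every SMOTE parent is a training sample.

## Recapture and enrichment statistics

Both tests are one-sided hypergeometric upper tails: recapture asks whether
two selected-feature lists share more members than chance on the full
transcript background (the selection space of every comparison); enrichment
asks the same of a list against each GO term on the annotated-transcript
universe. A two-sided Fisher option and a Haldane–Anscombe-corrected odds
ratio are available by flag; infinite odds ratios serialize as "Inf".
Bonferroni is the only multiplicity correction, α = 0.05.

The weighted overlap null draws transcript lists without replacement with
weight w ∝ 1/m (m = term multiplicity); inverse proportionality is the
simplest monotone weighting that prioritizes sparsely annotated transcripts,
and is exposed as a config hook. Each replicate enriches two lists and
counts terms significant in both (zero significant terms ⇒ overlap 0). An
internal precomputation converts each term's significance at a fixed list
size into a minimum-hit threshold, reducing a replicate to one sparse
comparison; the full 50,000 × 15 = 750,000 schedule is therefore available
(`--full`), with a desk-scale default of 500 replicates per size pair.

Semantic similarity of enriched terms is the Jaccard index of inclusive
is_a-ancestor sets — a deliberately simplified stand-in for
information-content measures — and clustering is a recursive binary cut
(2-means on similarity rows) that stops when a cluster's mean off-diagonal
similarity reaches 0.6.

## Normalization

Counts are log1p counts-per-million per sample. The generator is
normalization-agnostic; log-CPM was chosen as the simplest library-size
correction adequate for tree ensembles and distance-based oversampling,
and every stage operates on this one scale.

## Problem sizes used by the tests

Unit and acceptance suites run desk-scale cohorts chosen as the smallest
sizes at which the claimed effects are statistically comfortable: 200
samples × 1000 transcripts × 10 blocks for planted-signal recovery (45
positives at effect 1.5), 80 samples/type × 600 transcripts for multiclass
separation, 150-term annotations with 500-replicate nulls for the overlap
contrast. The full-scale constants (60,483 transcripts, 100 blocks, 50 per
block, top 1000, 50,000 replicates) remain the configuration defaults.

## Known limitations

* Independent transcripts in the generator understate real co-expression;
  colinearity pruning is exercised only by the duplicated/negated fixtures.
* The balancing-then-selection order follows the stated three-phase design;
  selecting after augmentation can optimistically bias support scores, which
  the real-only holdout protocol contains but does not eliminate for the
  support table itself.
* Semantic clustering is not an information-content method; cluster
  boundaries should not be compared across annotations with different DAG
  densities.
* Forest and boosting hyperparameters are conventional defaults, not tuned;
  per-dataset tuning is out of scope.
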