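# organotropy

Machine-learning prediction of **organotropic metastasis** — the non-random
tendency of a primary tumor type to seed specific distant organs — from bulk
tumor transcriptomes, together with the statistics needed to ask whether the
transcripts driving those predictions are shared across tumor types.

The package is aimed at computational-biology groups who have a samples ×
transcripts expression matrix and TCGA-style clinical annotations and want to
(i) classify tumor type, (ii) build per-(cancer, metastatic-site) progression
classifiers under severe class imbalance, and (iii) test whether the selected
transcripts and their GO biological processes recur across cancers seeding
the same organ more often than chance.

## The architecture

1. **Clinical harmonization.** Free-text metastatic-site columns
   ("metastatic tissue", "sites of metastases", "metastatic tissue site") are
   canonicalized; rows whose progression timing is *synchronous* are excluded
   (the primary/metastasis ordering is ambiguous); COAD and READ are merged
   into COADREAD. A (cancer, site) pair is analyzable when it has ≥ 8
   positive annotations and a total population > 50.
2. **Tumor-type classification.** A gradient-boosted tree ensemble assigns
   each transcriptome one of the cancer-type classes with a posterior
   probability vector.
3. **Balancing.** For each pair, the minority (metastatic) class is
   oversampled with SMOTE — each synthetic point is a convex combination
   x_i + u·(x_j − x_i) of a minority instance and one of its k = 5 minority
   nearest neighbors — until the minority reaches
   round(0.8 · |majority|) instances.
4. **Consensus feature selection.** The transcriptome is split into 100
   contiguous blocks (~600 transcripts each at the 60,483-transcript scale).
   Five selectors score each block — χ² filter, RFE over a logistic
   estimator, random-forest classifier and regressor importances, and
   L1-logistic — and a feature's *support vote* (0–5) counts the methods
   that flag it. Features are ranked by (vote, mean normalized score),
   colinear features (|r| ≥ 0.95) are pruned greedily, the top 50 per block
   are kept (≈ 5000 candidates), and a global top-1000 list is exported.
5. **Site classification.** Random-forest (or GBT) binary models on the
   selected features, evaluated on a stratified 30% holdout of *real*
   samples only — synthetic points never enter the test set and no test
   sample is ever a SMOTE parent.
6. **Recapture statistics.** Independently selected top-1000 lists are
   tested for overlap with a one-sided Fisher's exact test on the full
   transcriptome background: table [[a, b], [c, d]] with a = |A∩B| and
   p = Σ_{k≥a} C(|A|,k)·C(N−|A|,|B|−k)/C(N,|B|), Bonferroni-corrected.
7. **GO overrepresentation and the weighted null.** Per-list hypergeometric
   GO-BP enrichment (Bonferroni α = 0.05), and a simulation null for the
   overlap of two significant-term lists in which transcript lists are drawn
   with weight ∝ 1/m_i (m_i = number of GO terms a transcript maps to) —
   50,000 replicates for each of the 15 size pairs from {100..500} at full
   scale (750,000 total; desk-scale default 500). Shared enriched terms are
   clustered by ancestor-set Jaccard similarity with a recursive binary cut.

A synthetic-cohort generator (negative-binomial counts, planted tumor-type
and tropism signatures, messy clinical strings, long-tailed GO multiplicity)
makes every stage testable end to end with recoverable ground truth.

## Worked example

```python
import organotropy as ot
from organotropy.preprocess import log_cpm
from organotropy.selection import SelectionConfig

cfg = ot.CohortConfig(n_cancer_types=1, samples_per_type=200, n_transcripts=1000,
                      sites=["Liver"], tropism_signature_size=20, effect_size=1.5,
                      positive_fraction=0.25, seed=1)
expr, clinical, truth = ot.generate_cohort(cfg)
X = log_cpm(expr)
labels = ot.build_progression_labels(ot.harmonize_sites(clinical), "BRCA", "Liver")
res = ot.SiteProgressionModel(
    X, labels, selection_cfg=SelectionConfig(n_blocks=10, per_block_keep=10, seed=1),
    seed=1).fit()
print(res.summary())
```

prints

```
Site progression model BRCA -> Liver (rf)
================================================
test n=59  TP=13 FP=0 FN=1 TN=45
precision 1.0000  recall 0.9286  F1 0.9630  accuracy 0.9831
features used: 100  synthetic training samples: 53
```

Of 195 analyzable samples (45 liver-metastatic after synchronous exclusion),
70% train the model: SMOTE adds 53 synthetic minority points to reach 80% of
the training majority, blockwise consensus selection keeps 100 of 1000
transcripts (recovering all 20 planted signature transcripts), and the
random forest classifies the untouched 59-sample holdout with F1 0.963.

The same flow is available from the shell:

```bash
organotropy simulate --seed 1 --out cohort/
organotropy labels --clinical cohort/clinical.tsv --out cohort/labels/
organotropy run-all --config pipeline.yaml
```

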