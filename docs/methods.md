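# Methods

## Promoter windows

A pTSS region is `[tss − flank, tss + flank)` with `flank = 1000`,
0-based half-open. The TSS of a `+` transcript is `txStart`; of a `−`
transcript, `txEnd − 1`. This single convention makes every region
exactly 2000 bp and puts the TSS at oriented offset 0 (array index 1000).
Mirror-image annotations produce mirror-image windows up to the 1-bp
half-open boundary, which is unavoidable for any fixed convention.
Windows extending below coordinate 0 are dropped; identical windows from
transcripts sharing a TSS are collapsed with concatenated ids. Blacklist
filtering removes a window sharing ≥ 1 bp with any blacklist interval
(strict half-open overlap; touching intervals do not overlap).

## Coverage and normalization

The counting unit is the sequenced *fragment* (template interval); a
fragment counts once toward every window it overlaps by ≥ 1 bp.
Normalization is fragments per kilobase per million mapped fragments,
`raw / ((L/1000)·(total/10⁶))`, recorded in the matrix's
`normalization_tag`. Any common monotone transform of the values leaves
all downstream rank statistics unchanged (only log2 fold changes move),
which is why the precise normalization is not load-bearing. A
histogram-reweighting GC correction (per-fragment weight = median bin
count / bin count) is available but off by default — the synthetic
cohorts carry no GC bias. Fetal fraction can be estimated from the chrY
fragment proportion by linear interpolation between a female background
and a fully-male reference proportion, clipped to [0, 1] (male fetuses
only).

Depth profiles are per-base fragment depth over a region set, flipped for
`−` strand regions so negative offsets are always upstream, scaled by the
overall mean depth, and averaged with SEM across regions (the averaging
unit for gene-set footprint figures; across samples would be the choice
for group contrasts).

## Differential promoter coverage

Per gene: two-sided Wilcoxon rank-sum between groups on normalized
coverage; BH step-up FDR; `log2FC = log2(mean_case / mean_ctrl)`; calls
require `FDR ≤ 0.05` **and** `|log2FC| ≥ 1`. An infinite ratio (zero
control mean) is reported as `sign · (max finite |log2FC| + 1)` so tables
stay finite; the call is still made from FDR and direction. Gene-set
footprint contrasts use the exact signed-rank test on per-sample
set-mean differences (paired mode) or the rank-sum test on per-sample
set means between groups (unpaired mode).

### Exactness and calibration

* Rank-sum: exact by enumeration when the combined sample size is ≤ 12
  with no ties; signed-rank: exact for n ≤ 25 via a polynomial
  convolution over (doubled, hence integral) midranks. Two-sided p-values
  double the smaller inclusive tail, capped at 1; with n same-sign paired
  differences the signed-rank floor is `2/2^n`.
* Beyond those sizes, the tie-corrected normal approximation **without
  continuity correction**. The correction's conservatism is invisible in
  a single test but shows up as systematic miscalibration when thousands
  of null promoters are scanned (pooled null p-values fail a uniformity
  check with it; pass without it). Exactness at small n is unaffected.
* The rank-sum statistic is discrete (atoms of mass ≈ 0.01 at 20 vs 20),
  so null p-values are only uniform up to that discreteness. The
  acceptance suite checks calibration with a randomized probability
  integral transform through the exact null law (computed independently
  by dynamic programming) — exactly Uniform(0,1) for a calibrated test —
  plus the nominal rejection rate at α = 0.05.

## Feature construction

Discretization: candidate cutoffs are midpoints of consecutive distinct
sorted values; the dichotomized feature's AUC is (Se + Sp)/2 evaluated in
both orientations; the cutoff maximizing the better orientation wins,
ties toward the smallest cutoff; the binary encoding is always
`value > cutoff` (strict), with the orientation kept as metadata.
Importance: weight-based SVM recursive feature elimination (linear SVM,
C = 1; drop the smallest squared weight each round; rank = reverse
elimination order; zero-variance features are ranked last up front).
Pruning: features visited best-rank first; a feature is retained only if
|Pearson r| ≤ 0.5 (on the binary training matrix, matching the published
order discretize → rank → prune) against every already-retained feature.
The retained set is maximal — every removed feature exceeds the
threshold against some retained one.

## Classifiers and evaluation

Model families: linear SVM (C = 1), RBF SVM (C = 1, scale gamma),
unpenalized logistic regression (ridge fallback on separable data),
random forest and XGBoost with hyperparameters from an exhaustive grid
(RF: 500 trees, max features √p / p/3 / p/2; XGB: depth 2/4/6, learning
rate 0.05/0.1/0.3, 100/300 rounds) scored by 10-fold CV AUC. No class
weighting by default. SVMs score by decision function, the rest by
predicted probability.

* **AUC** is the Mann–Whitney statistic (ties ½). **DeLong** structural
  components give the variance, Wald 95% CIs (degenerate [auc, auc] with
  a warning under perfect separation) and the paired two-sided z-test for
  correlated ROC curves.
* **k-fold CV** pools out-of-fold scores into a single AUC (stratified
  folds, one global seed).
* **Backward selection** greedily deletes the feature whose removal
  yields the largest k-fold CV AUC, continuing through ties (so equal
  quality resolves toward fewer features) and stopping when every
  deletion strictly decreases the AUC; the returned subset is the global
  maximum along the trace, ties toward fewer features. **Lasso**
  selection is L1-penalized logistic regression with the penalty chosen
  by stratified 10-fold CV AUC, keeping nonzero coefficients (falling
  back to the weakest penalty with a nonempty selection).
* **LOOCV** centers each held-out score on its round's mean training
  score before pooling. Leaving out a case makes cases the training
  minority, shifting all of that round's decision values; uncentered,
  this biases the pooled null AUC to ≈ 0.44. The centering is a
  per-round constant and inconsequential when signal exists.
* **Clinical covariates** (BMI, fetal fraction) are z-scored on training
  data and appended to the binary features under a linear or RBF kernel.

### Faithful vs leakage-safe pipeline

`pipeline_loocv` defaults to the published order of operations:
differential calling, cutoffs, ranking/pruning and backward selection are
computed once on the full cohort, with only the classifier refit per
LOOCV round. This is deliberately reproduced — and deliberately
optimistic, since the held-out sample influenced its own feature set.
`leakage_safe=True` repeats the entire selection inside every round
(held-out scores standardized against each round's training scores,
because rounds with different feature sets share no score scale). On
planted cohorts the two modes nearly agree (e.g. 1.000 vs 0.985); on
null cohorts with forced selection the faithful mode is visibly inflated
while the leakage-safe estimate stays near chance.

If no promoter clears the differential gates the pipeline returns a
constant-score result (AUC 0.5) with a warning — its genuine behavior on
a null cohort; `fallback_top_k` optionally keeps the top-k genes by raw
p so a classifier is always built.

## Synthetic cohorts

Coverage model per gene g, sample s:

```
cov = exp(N(μ₀ − κ·pct_g, σ_b)) · (1 + ff_s·(2^{±λ} − 1)) · exp(N(0, σ_s))
```

with baseline log-mean μ₀ = 2.3 (≈ 10 normalized units), gene-baseline
scatter σ_b = 0.5, footprint coefficient κ = 1 (expressed promoters are
coverage-depleted, giving the expression–coverage anticorrelation), and
per-sample multiplicative noise σ_s = 0.35 — a coverage CV of ≈ 36%,
dominated by biological/technical variability over the ≈ 7% Poisson floor
at the nominal 10 M-fragment depth, and calibrated so the planted-effect
recovery experiment (20 vs 20, 1000 genes, 60 planted at |log2FC| = 1.2)
operates near the ~80% sensitivity regime a discovery cohort of this size
is powered for. The group effect multiplies planted genes in case
samples by `1 + ff·(2^{±λ} − 1)`: fetal fraction acts as a mixture
weight, and at ff = 1 the planted log2FC is exactly the asymptotic group
log-ratio. Raw counts are Poisson draws consistent with the normalized
values, so the matrix round-trips the normalization. Defaults: 20 vs 20
samples, 1000 genes, 60 planted, |log2FC| = 1.2, ff ~ Beta(8, 72)
(mean 0.10, overridable to a fixed value). BMI (21 ± 3 kg/m²) and ff are
drawn identically for both groups, so standalone they sit at AUC ≈ 0.5;
optional group shifts produce the weakly informative (≈ 0.53) regime.

Fragment level: midpoints are drawn from a cosine-phased occupancy
profile (repeat length 190 bp, amplitude 0.5) with the NDR at oriented
offsets −150..+50 scaled by `1 − pct·(1 − ndr_depth_factor)`
(default factor 0.2). Depletion removes fragments outright — a Binomial
thinning by the retained occupancy mass — so expressed promoters
genuinely lose coverage, as digestion of open chromatin would cause.
Fragment lengths are Normal(167, 20) truncated to [50, 400] bp
(mononucleosomal).

Not emulated: GC bias, mappability structure, sequencing error, maternal
genotype, duplicate reads, chromosome-scale signals, and real LD-like
correlation between promoters (planted genes are independent). Passing
tests therefore validate the statistical machinery and its calibration,
not performance on real cfDNA, whose inter-promoter correlation and
batch structure can only reduce effective power.

## Problem sizes and numerical choices

Recovery and calibration experiments use the default 20 vs 20 × 1000-gene
cohorts: differential recovery over 20 seeds, end-to-end LOOCV over 10
seeds, null calibration over 10 seeds (10,000 pooled p-values), DeLong CI
coverage over 500 replicates at n = 200 — sizes chosen to make the
binomial/KS tolerances meaningful while the whole suite remains a
desk-scale run. Exact-test thresholds (rank-sum ≤ 12, signed-rank ≤ 25)
are where enumeration/DP is instantaneous; beyond them the asymptotic
approximations are standard. Ties in RFE weights drop the later column;
ties in backward selection delete the first-found best feature; both make
runs bit-reproducible under a fixed seed.

## Known limitations

* Reported real-cohort performance figures are properties of patient
  sequencing data this package does not have; nothing here claims to
  reproduce them — synthetic results validate machinery, not clinical
  accuracy.
* sigFeature's hybrid SVM-RFE/t-statistic ranking is replaced by plain
  weight-based SVM-RFE; downstream stages consume only the total
  ordering.
* deeptools' GC correction is replaced by the histogram-reweighting
  scheme described above.
* The faithful mode's optimism is inherent to the published procedure
  order; honest error estimates require the leakage-safe mode.
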