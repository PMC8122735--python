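# Methods

This note documents the statistical procedures, the synthetic-data model,
the defaults and the numerical conventions of `vocdx`, and what the tests
do and do not establish about real instrument data.

## The discrimination procedure

The GC-IMS branch treats each sample's intensity map as a bag of pixels
and classifies patterns without chemical identification.

1. **Crop.** One index window (0-based, half-open on both axes) is
   applied identically to all samples. The default fractional window
   keeps retention rows 10–90% and drift columns 20–95%, which removes
   the map edges and the reactant-ion line near the low-drift-time edge.
   Crop parameters are configuration, not estimated from data.
2. **Threshold.** Values strictly below τ are zeroed; values equal to τ
   survive. τ = multiplier × (upper quantile of a signal-free background
   window), defaults quantile 0.99, multiplier 1.0. The background window
   defaults to the leading retention strip above the crop, restricted to
   the crop's drift columns so the RIP never contaminates the estimate.
   Thresholding is per-sample by default; a global option applies the
   median of the per-sample estimates to every sample. The driver always
   estimates τ on the uncropped map, then crops, then thresholds, and
   records the step order in the spectrum metadata.
3. **Flatten.** Same-shaped maps are flattened row-major into a samples ×
   features matrix; each column remains traceable to its (retention,
   drift) grid cell, and `unflatten` inverts the mapping.
4. **Cross-validation.** Stratified 10-fold (90%/10%). The splitter
   shuffles within each class and deals samples to folds round-robin,
   which — unlike a strict stratified splitter — tolerates a class
   smaller than the fold count (the 7-member fibrosis group under 10
   folds) while guaranteeing both classes in every training set whenever
   each class has ≥ 2 members. Within each fold, a two-sided Wilcoxon
   rank-sum test is computed per feature on the training samples only
   (exact null distribution for small untied samples, normal
   approximation with tie correction otherwise; constant features get
   p = 1), the k = 100 smallest-p features are kept (ties broken by
   ascending feature index, a stable and documented rule), a classifier
   is fitted, and held-out probabilities are emitted. Out-of-fold scores
   are collated into one score per sample.
5. **Classifiers.** Four are supported: `random_forest` (200 trees),
   `gradient_boosting` (XGBoost, 100 trees, depth 3),
   `logistic_regression` (standardised features, L2), and
   `linear_regression` — least squares on the 0/1 labels with scores
   clipped to [0, 1], the most literal reading of that model name as a
   classifier. No hyperparameter tuning, nesting or calibration is
   performed. Degenerate training data (all features constant) yields
   the training prior rate rather than an error.

Keeping the ranking strictly inside each fold is the load-bearing design
point: selecting features on the full data before splitting leaks label
information. On pure-noise data (40 samples × 100 features, top-10
selection) the leaky variant inflates the apparent AUC by ≈ 0.3 while
the in-fold pipeline stays at chance; the acceptance suite measures this
inflation directly.

## Diagnostic evaluation

Collated scores are evaluated with fixed, documented conventions:

* Prediction rule: probability ≥ t ⇒ positive.
* ROC over all unique score thresholds; AUC by the trapezoid, identical
  to the Mann–Whitney U statistic divided by n₊·n₋ with ties counted ½
  (verified against brute-force pair enumeration and scikit-learn).
* Optimal threshold maximises Youden's J; ties resolve to the smallest
  qualifying threshold, so the rule is deterministic even on flat J.
* 95% intervals are percentile bootstrap with B = 2000 class-stratified
  resamples (positives and negatives resampled separately, so every
  replicate contains both classes; a replicate with an undefined metric
  is redrawn). The method is distribution-free and appropriate at the
  small sample sizes involved; no analytic (DeLong) variance is used.
* Published-table arithmetic: from printed FP/FN counts and group sizes,
  tp = n₊ − fn and tn = n₋ − fp, from which sensitivity = tp/(tp+fn),
  specificity = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn). A zero
  denominator reports "undefined", never 0. Rendering rounds to 2
  decimals, round-half-up; full precision is retained internally.
  Orientation (which group is "positive") is always explicit, because
  published tables are reproducible only under the
  smaller-group-positive orientation.

## GC-TOF-MS branch

The reject filter keeps rows with height ≥ 10,000, area ≥ 10,000 and
width ≥ 0.01 min (keep-at-boundary; the upstream software's convention is
not public, so ≥ is fixed and tested here). The "baseline threshold 3"
setting belongs to the upstream deconvolution software; it is stored and
echoed in reports but defines no additional filter on a
post-deconvolution table. Abundance is the summed peak **area** per
(sample, chemical) — heights and detection frequencies are alternatives,
and area was chosen as the quantity most proportional to analyte amount;
a chemical undetected in a sample counts as zero abundance, because
headspace non-detection is informative rather than missing at random.
The per-chemical test is a two-sided Mann–Whitney rank-sum test (the
nonparametric analogue of a t-test, consistent with the IMS branch);
significance is raw p < 0.05 with no multiplicity correction by default,
matching exploratory practice at this scale; Benjamini–Hochberg is
available behind a flag. The direction ("higher"/"lower" for the case
group) comes from the group medians; exactly equal medians give
"undetermined" and are excluded from the significant set. Mean detected
peaks per comparison is the per-sample mean of distinct chemicals,
rounded to an integer.

## The synthetic-data model

The generator emulates the study conditions; it is a stand-in for
undeposited spectra, not a physical model.

* **Cohort:** 20 HCC / 7 fibrosis / 31 non-fibrosis by default (58
  samples), shuffled accession order, deterministic per seed.
* **IMS map:** baseline + RIP + Σ 2D Gaussian peaks + additive Gaussian
  noise, truncated at zero. The RIP is a constant-intensity column along
  retention time with Gaussian drift-time cross-section (position 7.5 ms,
  σ 0.08 ms, intensity 1000 a.u. vs baseline 10 ± 5), reflecting its
  appearance as the dominant carrier-gas response line. Peaks are
  axis-aligned Gaussians (real IMS peaks tail; no peak-shape model is
  published, and symmetry keeps the oracles closed-form). Gaussian
  cross-sections are set to exact zero beyond 5σ so signal-free regions
  are truly zero. Peak apex = base_intensity × fold_change(group) ×
  lognormal multiplier with mean 1 and the specified coefficient of
  variation (biological variability is multiplicative; measurement noise
  additive — the raw-intensity distribution of real spectra is not
  published, so both distributions are stand-ins). The default grid is
  256 × 128 ≈ 33k points — a desk-scale stand-in for the ~11-million-
  point maps of the real instrument that preserves the
  high-dimension/low-information regime at test speed; it is
  configurable upward.
* **Peak tables:** per chemical, height ~ base_height ×
  fold_change(group) × lognormal(cv), width ~ 0.05 min with 5% jitter,
  area = 1.0645 × height × width (Gaussian-peak relation), retention
  time jittered by 0.005 min. Detection applies a height floor and a
  Bernoulli dropout. Base heights sit at detector-count scale (6 × 10⁵)
  so typical areas clear the reject settings; the default panel (7 named
  study chemicals + 85 nulls, dropout 0.05) yields ≈ 78 detected peaks
  per sample, inside the study's 70–110 range.
* **Seeding:** every sample draws from `SeedSequence([seed,
  crc32(sample_id)])`, so outputs are bit-identical per seed and
  per-sample reproducible. The pipeline derives per-stage seeds from the
  global seed by hashing the stage name (all below 2³¹).
* **Effect dial:** `effect_scale` exponentiates every fold change —
  1.0 reproduces the study conditions, 0.0 is the exact global null.

What passing tests show: the pipeline is leak-free, calibrated under the
null, and recovers multiplicative group effects of realistic size from
sparse 2D signal and from peak tables. What they do not show: robustness
to retention/drift-axis misalignment between samples, peak tailing and
overlap, heteroscedastic detector noise, or batch effects — none of which
the generator emulates (axis alignment in particular is assumed, as
cross-sample warping is out of scope).

## Problem sizes and statistical checks

The repeated-seed checks run at desk scale, chosen as the package's
standard validation conditions: null calibration uses 50 seeds of a
20 vs 20 cohort on a 48 × 32 grid with the logistic classifier (mean
out-of-fold AUC expected in 0.42–0.58); the leakage probe uses 30 seeds
of 40 × 100 pure-noise matrices with top-10 selection; planted-marker
recovery uses 20 seeds of three fold-2.5/3 markers (σ 15 s × 0.35 ms)
among null clutter on a 64 × 48 grid, scoring both the collated AUC
(median ≥ 0.9) and the fraction of selected features inside the planted
2σ footprints (median ≥ 0.5); chemical recovery uses 50 seeds of 3
planted fold-2.5 chemicals among 200 nulls at 20 vs 38 samples
(sensitivity ≥ 0.9; false selections ≈ α × 200 on average).

## Known limitations

* The published headline AUCs were computed on a private 58-patient
  cohort; with synthetic data this package validates the *procedure*,
  not those numbers.
* "Linear regression" as a classifier is intentionally naive (clipped
  least squares); it exists for completeness, not recommendation.
* The bootstrap is percentile-only; BCa intervals are not implemented.
* Axis alignment across samples is assumed; no warping correction.
* The simulator's intensity distributions are plausible stand-ins, not
  fits to instrument data.
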