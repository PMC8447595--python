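# Methods

This note records the models, estimators, numerical conventions and design
choices behind `msbatch`, and what the synthetic-data experiments do and do
not demonstrate.

## Data model

The exchange currency of all stages is a *long measurement table*
(`feature_id`, `sample_id`, `intensity`) on the log2 scale. Missing values
are **absent rows** in long form and NaN cells in wide form; no stage ever
stores sentinel zeros, because zero-filled holes corrupt every
complete-matrix diagnostic (see "Missing values" below). Sample metadata
carries a dense 1-based `run_order` (ties must be resolved before import —
LOESS needs a total order), one column per technical batch factor, optional
biological factors and an optional replicate-group label. Batches need not
be contiguous in running order. On-disk formats are TSV with `NA`/empty as
missing tokens; factor roles are declared in a small YAML file since a TSV
carries no role semantics.

## Normalization

* **Median centering**: `y' = y − median_s + M` with `M` the median of
  per-sample medians. Re-anchoring at `M` rather than 0 keeps the absolute
  log2 scale, which the CV computation needs after unlogging. Idempotent
  and exact (all post medians equal `M` to machine precision).
* **Quantile normalization**: with complete data, the classic per-rank-mean
  scheme. With missing values the reference distribution is the mean of the
  samples' interpolated quantile functions on a common grid of `m`
  probabilities (`m` = largest per-sample observation count,
  `p_j = j/(m−1)`), and each observed value maps to the reference quantile
  at its within-sample fractional rank (average ranks at ties). The
  missing-value extension is a convention of this package — the classic
  method is defined only for complete matrices — and reduces exactly to it
  when data are complete.
* **z-transformation**: per-sample mean 0 / sd 1, sd with the n−1
  denominator (small replicate groups).

The choice among normalizers is always the caller's; nothing is
auto-selected.

## LOESS and drift correction

`fit_loess` is classic local polynomial regression: for each target point
the `k = ceil(span·n)` nearest neighbours are tricube-weighted,
`w = (1−u³)³`, and a degree-1 or degree-2 polynomial is fit by weighted
least squares; no robustness iterations. Defaults: degree 2, span 0.75.
The span is deliberately a mandatory, user-visible knob: small spans
overfit (and "correct" noise as if it were drift), large spans miss real
trends. Degenerate windows (fewer positive-weight points than coefficients)
fall back to a weighted mean.

`correct_drift` fits one curve per feature per batch on **observed values
only** and subtracts it. The corrected values are re-anchored so that the
feature×batch *median is preserved exactly* (`c = median(y) −
median(y − fit)`): the continuous/discrete decomposition is only
identifiable up to per-batch constants, and constants are the discrete
step's job. Feature×batch groups with fewer than `min_points` (default 8)
observations are left untouched and logged as fallbacks. A warning is
raised when any batch has fewer than 25 samples, where curve fitting and
location/scale estimation risk over-correction.

## Discrete correction

* **Median/mean centering** per feature: every batch's statistic is moved
  onto the feature's global statistic. Exact, idempotent (median), and
  robust to missing values — features absent from a batch are corrected
  only where observed.
* **ComBat (parametric EB location–scale)**: per feature, standardize
  against the batch-size-weighted grand mean (plus optional categorical
  covariates protecting biological contrasts) and pooled variance; estimate
  per-batch locations `γ̂_gb` and scales `δ̂²_gb`; moment-match a normal
  prior on `γ` and an inverse-gamma prior on `δ²` across features within
  each batch; iterate the conditional posterior means to a relative
  tolerance of 1e-4 (max 100 iterations); back-transform. Every feature
  must be observed in every batch (whole-batch absence is an error naming
  the offending pairs and pointing to the per-batch completeness filter);
  scattered missing cells within a batch are tolerated via per-feature
  observation counts. At least 2 features and 2 samples per batch are
  required, or the EB moment matching degenerates.

Only a single batch factor is corrected per call. Confounded factors are
the user's problem by design: the confounding report (Cramér's V of the
factor cross-tabulation) quantifies separability, and nothing merges
factors silently.

## Diagnostics

* **PCA**: SVD of the feature-centred samples×features matrix with a
  deterministic sign convention; variance fractions are relative to total
  variance. Default missing policy is `complete_features` with a mandatory
  count of dropped features; filling is available only behind an explicit
  flag that warns.
* **Hierarchical clustering**: euclidean/manhattan/correlation
  (1 − Pearson r) distances with complete/average/ward linkage (ward
  restricted to euclidean), per-leaf factor labels attached.
* **PVCA**: retain the smallest set of leading PCs whose cumulative
  variance reaches the threshold (default 0.6); per PC, fit a crossed
  random-intercept model (one variance component per factor, plus pairwise
  interactions on request) by REML; normalize components plus residual
  within PC; weight by eigenvalue fraction among retained PCs; renormalize.
  Identically partitioning factor pairs are rejected as inseparable.

  Numerical care: the mixed-model optimizer can stop at inferior local
  optima or fail with singular Hessians at variance-component boundaries.
  Each PC is therefore fit with several optimizers (lbfgs, powell,
  Nelder–Mead) and the best restricted likelihood wins; if all fail, a
  direct Nelder–Mead REML optimization on the log-variances takes over.
  Scores are scaled to unit variance before fitting (proportions are
  scale-invariant).

  Interpretation caveat: with the default 0.6 threshold PVCA measures
  variance attribution *within the top-variance subspace*, which
  over-represents structured (batch) variance relative to the global
  variance fraction. Recovering a global injected fraction requires a
  threshold near 1; the calibration experiment in the acceptance suite
  uses 0.9 for exactly this reason.

## Quality control

Pearson correlations on log2 intensities over pairwise-complete
observations; sample pairs sharing fewer than `min_overlap` (default 50)
features are excluded and counted. Sample pairs are classified replicate /
within-batch / between-batch; peptide pairs same-protein /
different-protein, with different-protein pairs subsampled to a seeded cap.
CVs are computed on the **unlogged** scale (sd/mean is only meaningful on a
ratio scale) within replicate groups, averaged across groups, and binned by
log10 abundance. `qc_compare` recomputes all controls on both tables,
requires identical (feature, sample) universes, and reports paired metrics
plus deltas; swapping before/after negates every delta.

"Improved clustering by biology" and "more differential hits" are
deliberately not metrics: they cannot be distinguished from overcorrection
without external truth.

## Missing values

`missingness_by_batch` counts observed/possible cells per feature×batch and
flags features whose missing fraction differs between batches by more than
a margin (default 0.2). `completeness_filter` retains features observed at
a minimum fraction overall or in *every* batch; the per-batch variant with
fraction 1.0 is exactly the ComBat prerequisite. Imputation is opt-in,
warned, seeded where stochastic, and returns an explicit mask of imputed
cells so downstream QC can exclude them; observed values are never altered.

## Synthetic data

The generator draws, from named substreams of one seed (so adding a
component never perturbs the others):

```
y_gs = baseline_g + bioeffect_{g,group(s)} + shift_{g,b(s)}
       + sens_g · drift_{b(s)}(r_s) + eps_gs
```

* `baseline_g`: protein-level N(20, 1.5²) log2 plus peptide jitter
  N(0, 0.7²); peptides of one protein share the baseline and the protein's
  biological effect.
* `bioeffect`: 30% of proteins carry a group effect N(0, 0.5²) (two
  balanced groups by default); spike-in proteins carry none.
* `shift_gb ~ N(0, 0.5²)` per feature per batch; zero for spike-ins.
* `drift`: one curve per batch from monotone families by default
  (exponential decay, linear; a sinusoid family is available), scaled to a
  peak-to-peak amplitude of 1.0 log2 and **median-centred within the
  batch** — the drift/shift decomposition is only identifiable up to
  per-batch constants, and constants belong to the discrete component.
  Each feature responds through its own sensitivity `sens_g ~ U(0.3, 1.5)`,
  so peptides drift heterogeneously; spike-ins are fully exposed to drift
  (their variation is purely technical, like iRT standards).
* `eps ~ N(0, 0.3²)`; an optional per-individual variance term exists for
  realism studies but defaults to 0 (it is not part of the model above and
  would raise the effective noise floor).
* Replicates: two biospecimens re-injected three times each at random
  positions across the run, mimicking repeated control injections.
* Missingness (off by default): logistic in abundance with a batch-coupled
  odds multiplier applied to a random *subset of features* for the coupled
  batch — whole-batch peptide dropout is what turns zero-filling into
  spurious batch clusters; cell-wise independent holes do not reproduce
  that hazard.

Defaults: 100 proteins × 3 peptides, 90 samples, 3 equal contiguous
batches, 5 spike-in proteins. Ground truth stores every additive component
exactly (they sum to the generated matrix bit for bit).

**What passing tests show — and don't.** The generator produces additive
Gaussian structure with known decomposition; it does not emulate
intensity-dependent variance, chromatographic retention-time shifts,
interference, or correlated noise between co-eluting peptides. Recovery
results on it demonstrate that the estimators remove what they model, at
the stated sizes, not that any real dataset satisfies the model.

## Problem sizes and measurement protocols

The acceptance experiments run at desk scale: the default 300×90 study for
drift and QC; 100 features × 60 samples for PVCA calibration (20 seeds);
20 features × 12 samples for the EB-correction oracle; 10 seeds for the
imputation hazard. The drift RMSE-reduction ratio is reported as the mean
over 3 seeds: a single-seed ratio of medians has sampling noise of the
same order as its distance from the 50% mark, and the multi-seed mean is
the stabler estimate of the same quantity. The drift instance omits
biological group effects, which would otherwise act as additional point
noise beyond the stated noise level.

## Known limitations

* LOESS drift correction needs enough points per feature×batch (default 8);
  sparse features keep their drift and are only median-anchored.
* The parametric EB corrector assumes roughly normal per-batch feature
  distributions; the nonparametric prior variant is not implemented.
* PVCA proportions depend on the variance threshold (see caveat above) and
  on REML's behaviour with few factor levels, where estimates are noisy.
* Quantile normalization's missing-value mapping is a convention; other
  defensible interpolation schemes give slightly different values.
* Correction operates on one batch factor at a time; nested or crossed
  multi-factor corrections must be run sequentially by the user.
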