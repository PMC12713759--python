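# Methods

This note documents the models, defaults and numerical choices behind
`sickstate`, and what the synthetic-data experiments do and do not show.

## Synthetic data with planted structure

**FOS intensities** (`simulate.generate_fos`). Intensities are log-normal:
each region r has a baseline log-mean drawn once from
N(`baseline_log_mean` = 3.0, `baseline_log_sd` = 0.5), shared across
conditions, with within-condition noise sd `noise_sd` = 0.35 on the log
scale. A planted effect of size d for condition c adds d·`noise_sd` to the
log intensity of that region in that condition's animals — i.e. effects are
expressed in standardized units, so "effect 2.0" means a two-within-sd
group shift. The default planted map gives each non-control condition 10
informative regions at |effect| = 2.0, two of them suppressions (negative),
and makes the STAg/DSS and LPS/pI:C pairs each share 50% of their planted
regions, reproducing the deliberately confusable structure of the real
states. Sex is an independent stratum: one call generates one stratum, and
the pipeline concatenates strata and fits them separately. Log-normality is
an assumption chosen for positivity and right skew (it also gives the
Yeo-Johnson step real work to do); the distributional family of real
regional FOS intensities is not known.

**Vocalization features** (`simulate.generate_usv`). One row per call:
onsets are cumulative exponential gaps (default rate 2 calls/s), durations
are N(30, 12²) ms floored at 0.1 ms — a distribution that straddles the
5 ms detection floor so the short-call filter is exercised — and 31
acoustic features are standard normal with per-condition mean-shift
vectors (default: each non-control condition shifts its own block of 5
features by 1.2 sd). The four temporal metrics are computed by
`usv.temporal_metrics` on the generated onsets and appended, giving 35
feature columns in total.

**Spatial maps** (`simulate.generate_spatial`). Cells are uniform in a
square arena (default 1500 cells, 1000 length units) with random cell-type
and animal assignments (3 animals per condition). Baseline expression is
log-normal and iid across cells; a *focal* gene is multiplied by
2^effect only for treated cells inside a central disc (radius 25% of the
arena), a *broad* gene everywhere in treated tissue, a *null* gene
nowhere. Companion DE tables are computed from the generated values
(per cell type: empirical log2 fold change of means, Mann-Whitney p,
Benjamini-Hochberg adjustment), so they are consistent with the planted
patterns by construction rather than by assignment.

What these generators deliberately omit: spatially correlated baseline
noise, batch/animal random effects, region-structured covariance between
brain areas, heavy-tailed call-feature distributions, and count noise in
expression. Passing tests therefore demonstrate that the machinery
recovers planted structure under clean, well-specified noise — not that it
is robust to every pathology of real data.

## Normalization

Each feature column is mapped through the Yeo-Johnson transform; the
exponent λ maximizes the Gaussian profile log-likelihood (including the
log-Jacobian term) by bounded scalar optimization on [−5, 5] with
tolerance 1e-5, then the transformed column is centered and scaled. The
piecewise transform is evaluated in `expm1`/`log1p` form, which is exact at
the λ = 0 and λ = 2 branch points and free of the catastrophic
cancellation the naive power form suffers for small |λ|. Constant columns
cannot be power-transformed and are dropped with a warning. Inside
cross-validation the parameters are fitted on each training fold and
frozen for the corresponding held-out rows (a `transform_mode="global"`
flag exists for protocol exploration, and `"none"` for pre-standardized
input); fold-internal fitting is the leakage-safe default.

## Feature selection

`select.boruta_run` implements classical Boruta semantics: per iteration,
freshly permuted shadow copies of all non-rejected features are appended,
a random forest (default 500 trees, impurity importance, sqrt feature
subsampling) is fitted, and each tentative feature scores a hit if its
importance exceeds the best shadow importance. Features are confirmed or
rejected by a two-sided binomial test on hits at α = 0.05 with Bonferroni
correction over the feature universe; tentative features at termination
count as not confirmed. `select.repeated_selection` repeats this with
fresh forest/shadow randomness (derived from a master seed) and retains
every feature whose confirmation frequency reaches the top-5% quantile of
the nonzero frequencies, ties kept — a cut that can retain somewhat more
than 5% of the universe, which is the reading under which a 641-region
table yields retained sets like 36 or 25 rather than exactly 32. Whether
selection should see transformed or raw intensities is not externally
fixed; this implementation selects on transformed data.

## Classification

The multinomial logistic model is fitted in the symmetric full-K
parameterization (identifiability comes from the penalty, matching
per-state coefficient profiles) by FISTA with backtracking: the negative
log-likelihood plus ridge term is the smooth part (Lipschitz constant
found by doubling), the L1 part enters through soft-thresholding,
intercepts are unpenalized, and a function-value restart guards against
momentum overshoot. Defaults: tol 1e-7 on relative objective change,
max_iter 10⁴. On random tiny instances the fitted objective agrees with an
independent bound-constrained solver (L-BFGS-B on the split β = p − q
reformulation) to better than 1e-8.

`classify.nested_cv` draws a stratified 75–25 outer split per repetition,
tunes (λ, α) by mean held-out multinomial log-likelihood over an inner
stratified 4-fold CV (an accuracy criterion is available by flag;
grid-order tie-break), refits on the outer training set and records
held-out probabilities. Default grids: λ ∈ 10^{−4..1} (10 log-spaced
values), α ∈ {0.1, 0.3, 0.5, 0.7, 0.9}. Repetitions in which a class would
fall below the inner fold count are skipped with a logged warning.
Aggregates: mean held-out accuracy across repetitions; per-class MSE in
the Brier-style reading, mean over held-out samples of true class c of
Σ_k (p_k − 1{k=c})² (the metric's name fixes less than its formula; this
is the decomposition used here); and the averaged row-normalized confusion
matrix.

## Attribution

Per repetition, SHAP values are computed on the standardized outer-train
matrix as S(i,j,c) = X_std(i,j)·β(j,c); per sample and class they sum
exactly to the linear score minus the intercept. Because standardized
columns have mean zero, the signed mean over *all* samples is ~0 by
construction; the signed per-(feature, class) summary therefore averages
over the samples of that class (where the quantity is informative: a
suppressed region yields negative X_std times a negative β, i.e. positive
SHAP toward its state), while the magnitude summary mean|S| averages over
all samples. The hybrid score is H(j,c) = mean|S(·,j,c)|·|B̄(j,c)| with B̄
the cross-repetition mean coefficient; "weighted by the stability of β" is
read as magnitude of the mean, with a dispersion-penalized variant
|B̄|/(sd(β)+ε) behind `stability_penalized=True`. Directional annotation
(promoting/suppressing) is the sign of B̄.

## Clustering metrics

Silhouette (Euclidean, singletons scoring 0) and the Calinski-Harabasz
variance ratio quantify whether the selected feature set sharpens the
condition clusters; both are checked against O(n²)/sum-of-squares
brute-force oracles to 1e-10. Zero within-cluster dispersion is signaled
as +inf (degenerate infinite separation). The 2-D embedding (t-SNE,
PCA initialization, perplexity min(30, (n−1)/3)) is display-only and
carries no acceptance weight.

## Vocalization protocol

Calls shorter than 5 ms are excluded (exactly 5 ms is kept). Temporal
metrics are forward onset differences at lags 1–3 (missing for the last
calls) and duration/onset (missing at onset 0); missing values are imputed
with training-fold medians before forest fitting. The ensemble draws
`subsample_per_class` calls per class without replacement (the balanced
reading of the sub-sampling sizes; a pooled mode was considered and
rejected as not balancing classes), optionally permutes all subsampled
labels jointly (the shuffled baseline), splits 80/20 stratified, and fits
a forest with the fixed protocol hyperparameters (500 trees, entropy,
depth 20, all features per split). Macro F1 is computed from the printed
precision/recall formulas with the 0/0 → 0 convention; the macro mean is
unweighted. With shuffled balanced labels the expected macro F1 is 1/K,
approached from below at small test sizes because classes with zero true
positives clamp to 0.

## Spatial statistics

Moran's I uses a k-nearest-neighbor graph (default k = 6) on cell
coordinates, symmetrized by union and row-standardized, no self-edges;
expression is log1p-transformed before the statistic. ΔI is computed per
animal section and averaged within condition before differencing (pooled
mode by flag). Because the graph construction is a convention, ΔI
magnitudes are graph-dependent; only signs and orderings are treated as
reproducible. Specificity counting applies strict inequalities
(p_adj < 0.01, log2FC > 2) by default and a lax preset
(p_adj < 0.05, log2FC ≥ 1); boundary cases follow the preset exactly
(log2FC = 2 fails strict, log2FC = 1 passes lax).

## Problem sizes and runtime

The test suite and the acceptance script run everything at desk scale,
chosen once as the package's study conditions: selection recovery uses
100 regions (10 planted per condition at 1.5 sd), 60 animals per class,
20 selection repetitions with 100-tree forests and 20 Boruta iterations;
classification checks use 48 animals with 20 CV repetitions and reduced
(λ, α) grids; the shuffled-baseline ensemble uses 250 calls per class
(in place of the original 2,500/7,801) with the full 500-tree forests —
50 iterations in the acceptance script, a 10-iteration subset in the test
suite. The full suite runs in under ten minutes on one CPU; the acceptance
script in roughly fifteen.

## Known limitations

- The elastic-net path is re-solved from a zero start per grid point (no
  warm starts); fine at these problem sizes.
- Boruta's binomial test treats iterations as independent trials, as in
  the classical algorithm; early stopping at max_iter leaves weak features
  unconfirmed rather than undecided.
- The simulators' clean noise model means recovery results bound what the
  machinery can do under ideal conditions, not under real-data pathology.
- ΔI has no attached significance test here; the permutation expectation
  E[I] = −1/(n−1) is verified, but inference on ΔI is left to the caller.
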