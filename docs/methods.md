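# Methods

## The model

`clpnet` estimates a **cross-lagged panel network (CLPN)** between
questionnaire items measured on the same subjects at two waves.  With p
nodes (here 7 generalized-anxiety symptoms, GA1–GA7, and 12
intolerance-of-uncertainty elements, IU1–IU12) and q baseline covariates,
the network is built node-wise: for every target j,

    y_j(T2) = b0 + sum_i B[i, j] * x_i(T1) + sum_k g[k, j] * c_k + e_j

is fit by LASSO (L1-penalized least squares), one regression per wave-2
node on *all* wave-1 nodes plus covariates.  The assembled p × p matrix B
is the directed network: the diagonal carries autoregressive paths (a node
predicting itself across waves), the off-diagonal cross-lagged edges
(node i at T1 predicting node j at T2, controlling for all other T1 nodes
and the covariates).  Predictors are standardized to unit variance and
coefficients reported on that scale, so edge weights are comparable across
predictors; they are not back-transformed.

The penalized objective per target is `(1/2n)·||y − Xb − b0||² + λ·||b||₁`,
solved over a log-spaced grid from the data-derived λ_max (the smallest
penalty that zeroes every penalized coefficient) down four orders of
magnitude.  λ is chosen by K-fold cross-validation (default K = 10) at the
minimum mean squared prediction error; the one-standard-error rule is
available but not the default, since minimum-CV is the convention in
published CLPN applications.  Fold membership is keyed to a canonical
ordering of subject identifiers, shuffled once per target with the run seed
offset by the target index — fits are therefore deterministic given the
seed and invariant to row permutations of the input.  Covariates are
penalized like node predictors by default; the unpenalized option is solved
exactly by Frisch–Waugh residualization (project target and penalized
columns onto the orthocomplement of the unpenalized block, solve the LASSO
on the residuals, recover the unpenalized block by least squares).

The penalized solves themselves are delegated to scikit-learn's
coordinate-descent path solver; the test suite verifies fixed-penalty
solutions against an independently written cyclic coordinate-descent
implementation (agreement to 1e-6) and against closed-form soft
thresholding on orthonormal designs.

### Nonparanormal transformation

Before estimation, every node column (both waves) is Gaussianized by the
rank-based nonparanormal transform: the average-rank empirical CDF rank/n,
Winsorized to [δ_n, 1 − δ_n] with δ_n = 1/(4 n^(1/4) √(π log n)), mapped
through Φ⁻¹ and rescaled to unit sample variance.  This relaxes marginal
normality for the skewed ordinal items while preserving rank order.  Note
that once δ_n > 1/n (n ≳ 30) the Winsorization ties the most extreme ranks,
so the map is weakly rather than strictly monotone at the tails; this is a
property of the standard construction.  Covariates are left untransformed
(their treatment is an analysis choice; the numerically-coded covariates
enter the regressions as-is).  Descriptive tables and paired t-tests are
computed on the raw responses, before the transform.

### Edge retention

Cross-validated penalty selection deliberately overselects: many spurious
cross-lagged coefficients survive with tiny magnitudes.  The reported
network therefore applies an edge-retention threshold to the off-diagonal
cells: by default the mean absolute nonzero cross-lagged weight (signed-mean
and fixed-value variants are configurable).  Retention uses the weak
inequality (an edge exactly at the threshold is kept), and autoregressive
paths never enter the threshold computation or the retained list — they are
carried separately.

### Prediction centrality

In-/out-prediction quantify how much variance a node receives from, or
contributes to, the rest of the network, at two scopes (cross-lagged = all
other nodes; cross-construct = only the other construct).  These are
operationalized as differences of R² between nested *unpenalized*
least-squares refits on the LASSO-selected support:

* baseline M0 per target j: covariates plus j's own autoregressive term —
  always included, even when the penalized fit zeroed it, because every
  cross-lagged quantity is defined net of the autoregressive path;
* `crosslagged_in(j)` = R²(M0 + same-construct + other-construct) − R²(M0);
* `crossconstruct_in(j)` = R²(full) − R²(M0 + same-construct);
* `crosslagged_out(i)` = Σ over targets j ≠ i that retained i of
  [R²(full_j) − R²(full_j without i)]; `crossconstruct_out(i)` restricts
  the sum to targets in the other construct.

Out-prediction is a sum, not a mean, so hub nodes accumulate influence
across targets.  Published CLPN analyses compute these indices through
path-modeling software without stating formulas; the nested-ΔR²
construction is this package's operationalization of the verbal
"proportion of variance accounted for" definitions, and its equivalence to
any particular SEM implementation is left open.  All quantities are nested
differences, hence nonnegative (clamped at −1e-12 rounding error) and
cross-construct ≤ cross-lagged componentwise.

### Resampling

*Nonparametric bootstrap* (default 5000 resamples): subjects resampled with
replacement, the whole pipeline re-run per resample — including the
nonparanormal transform when the input is raw — yielding percentile CIs per
edge and pairwise difference tests (significant iff the percentile CI of
the difference excludes zero; unadjusted for multiplicity, as in the
methodology this follows).  A resample in which a node column goes constant
(which breaks the rank transform) is redrawn and counted.

*Case-dropping bootstrap* (default 5000 subsamples per proportion, grid
0.05–0.75 in 0.05 steps): increasing proportions of subjects dropped
without replacement, statistics recomputed and correlated with full-sample
values.  The CS coefficient is the largest *tested* proportion at which at
least 95% of subsamples correlate ≥ 0.7 with the full sample — no
interpolation between grid points, so reported CS values lie on the grid.

A caveat documented rather than engineered away: percentile CIs around an
L1-shrunk estimator undercover strong coefficients.  The cross-validated
penalty shrinks a strong standardized weight by roughly half a standard
error on average, and the percentile construction doubles the effect of
estimator bias, putting realized coverage near 88% at a nominal 95% (the
identical machinery around unpenalized least squares covers at ~94%).
Bootstrap edge CIs should be read as precision summaries, not significance
tests.

### Subgroup sensitivity analysis

The sample is split at the anxiety construct's clinical cutoff (GAD-7
cutoff 10, defined on 0-based item scoring) applied to the wave-1 sum
score; when items are stored 1-based the offset is computed from the
declared response ranges, never hard-coded.  Each group gets an independent
transform → estimate → threshold run; groups smaller than 10 × p carry an
explicit stability caveat.  Baseline (wave-1) scores are used for the split
because that is the only choice that keeps both groups' two-wave networks
comparable; either-wave caseness is a documented alternative.

## The synthetic generator

The generator draws wave-1 latent scores from a zero-mean Gaussian with a
construct-block correlation matrix (r_within = 0.4 inside a construct,
r_between = 0.2 across, defaults), propagates wave-2 latents through
`z2 = Bᵀ z1 + ε` with per-node noise (default SD 1), rescales wave-2
latents to unit theoretical variance, and discretizes both waves through
per-node Gaussian cut points into the declared ordinal ranges.  This
linear-Gaussian-latent-plus-threshold model is exactly the process the
nonparanormal + linear regression pipeline is correctly specified for,
which makes parameter recovery a fair test surface.

Default study-scale geometry: 19 nodes (7 GA stored 1–4, 12 IU stored
1–5), autoregressive weights 0.15, cross-lagged density 0.15 with nonzero
weights uniform on [0.1, 0.3], covariates off.  The default cut points —
GA (0.45, 1.3, 2.0), IU (−0.7, 0, 0.7, 1.4) on the z scale — were chosen
once to reproduce the marginal shapes typical of the two instruments in
adolescent samples (GA mean ≈ 1.45, SD ≈ 0.73, skewness ≈ 1.6 on the
4-point scale; IU mean ≈ 2.6, SD ≈ 1.24, skewness ≈ 0.3 on the 5-point
scale) and match the reported scale contrast between autoregressive and
cross-lagged paths.

What the generator does *not* emulate: item-level measurement models (IRT),
attrition, covariate confounding (available as an option but off by
default), and any particular study's realized covariate distributions.
Passing recovery tests therefore show that the pipeline recovers the
structure it assumes, at the declared marginal shapes and effect scales —
not that any real panel satisfies those assumptions.

### Recovery metrics and power analysis

Recovery is scored on the off-diagonal (cross-lagged) cells only:
sensitivity (detected true edges / true edges), specificity
(correctly-absent / truly-absent), and the Pearson correlation of true vs
estimated weights over all off-diagonal cells.  Detection in the power
analysis follows the pipeline's own edge-retention rule — an edge counts
as recovered when it survives the cross-lagged threshold — because the
thresholded network is what the analysis reports.  Scoring the raw
penalized support instead (`threshold_rule=None`) trades specificity
(≈ 0.5 at n = 7000, from deliberate CV overselection) for maximal
sensitivity; both are available, the thresholded rule is the default.  At
the default spec and n = 7000 the three properties all exceed 0.95; at
n = 250 sensitivity falls to ≈ 0.6.

## Numerical and design choices

- Standardization uses the analysis sample's (ddof = 0) standard deviation;
  the transform's unit-variance rescale uses ddof = 1 (matching the R
  convention of the reference nonparanormal implementation).
- Skewness/kurtosis are the bias-adjusted G1/G2 estimators (the SPSS/Excel
  conventions); severe non-normality is flagged at |skew| > 2 or
  |kurtosis| > 7.
- Cohen's d for paired data is mean(d)/sd(d) with a normal-approximation CI
  (SE = √(1/n + d²/2n)); the mean-difference CI is the exact t interval.
  Attrition checks use Welch's t.
- Degenerate inputs: constant columns transform to zeros with a warning;
  zero-variance predictors are dropped with a warning; a constant paired
  difference with nonzero mean is an error; rank-deficient centrality
  refits fall back to least-norm solutions.
- Ties in edge rankings break by (source, target) lexicographic order; ties
  in centrality rankings by node id.
- All randomness flows from one root seed: per-target fold shuffles use
  seed + target index; bootstrap and case-drop streams use the config seed;
  the power analysis derives per-replication seeds (< 2³¹) from its root
  seed.

## Problem sizes in the shipped tests

The test suite exercises the full pipeline at reduced scale as its own
documented choice of desk-scale conditions: bootstraps of 15–200 resamples
(5000 being the real-run default), case-drop grids of 2–7 proportions with
3–50 subsamples, networks of 2–6 nodes for resampling checks, and the full
19-node geometry for recovery (n = 5000) and power (n = 7000, 10
replications) checks.

## Known limitations

- Two waves only; no time-series or >2-wave designs.
- Raw ordinal responses are Gaussianized, not modeled ordinally (no mixed
  graphical models, no IRT measurement layer).
- Percentile edge CIs inherit L1 shrinkage bias (above); difference tests
  are unadjusted for multiplicity.
- The centrality operationalization is nested-OLS ΔR²; published tables
  computed with SEM software are format-compatible but not guaranteed
  numerically identical.
- CS coefficients are grid-resolved; a CS of 0.61-style resolution requires
  a finer drop grid than the default 0.05 steps.
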