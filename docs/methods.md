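# Methods

This note documents the modelling conventions, defaults and known
limitations of `opineq`.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Measurement model

Health outcomes are ordinal discharge diagnoses, treated as discrete
manifestations of a latent continuous health status.  The measurement is
*ex ante*: effort is never observed; the environment-only prediction
`Ĥ_i = E[H | E_i]` defines the counterfactual smoothed distribution, and any
effect of environment *through* effort is deliberately attributed to
environment.  The inequality index is the mean log deviation (MLD): zero iff
equality, scale-invariant, translation-*sensitive*.  Translation sensitivity
matters because the transformed health score must be shifted into positive
territory before an MLD is defined; the shift (default +5, which keeps the
four-category score comfortably positive) is recorded in every result object
and must be identical in the numerator and denominator of
`θ_r = I(Ĥ)/I(H)`.  Reported θ values are therefore comparable only at a
common shift.

θ_r can exceed 1 in finite samples when a flexible smoother overfits: the
package warns and reports it unclipped, since clipping would hide the
overfitting.

## Outcome transformation

- RINT with the midpoint convention `z_k = Φ⁻¹(F_{k−1} + f_k/2)`.  Per-rank
  (Blom-type) offsets are ill-defined under the massive ties of a
  four-category variable; the midpoint convention handles ties cleanly and
  keeps the map strictly increasing.  Under heavy asymmetric ties the
  transformed variable has mean only approximately 0 and variance strictly
  below 1 — both are properties of discretization, not bugs, and the test
  suite asserts them.
- Reversal is the negation of the z-score (so higher = better health),
  applied before the positivity shift.
- The composite health variant averages *transformed* scores of the primary
  and all secondary diagnoses, not raw category codes: distances are
  meaningful on the latent (transformed) scale only.  Patients without
  secondary diagnoses have composite = primary.

## Preprocessing conventions

- Study filters: age ≥ 45, ICD-10 circulatory-chapter groups, then diagnosis
  groups with **more than 30** cases (a 30-case group is dropped, a 31-case
  group kept).
- Mean imputation; ordinal/binary means are rounded to the nearest valid
  level so codings stay valid.
- Expenses are winsorized two-sided at the 1st/99th percentiles
  (linear-interpolation quantiles); winsorization is idempotent at fixed
  bounds.
- The cost-variance feature is the within-diagnosis-group variance of
  winsorized expenses, assigned to each member and quantile-binned
  (patient-weighted) into five ordinal codes 0–4.  The bin count is
  configurable; singleton groups get variance 0 with a warning.

## Model families

- **Linear**: OLS with intercept; rank-deficient designs raise an error
  naming the collinear columns.
- **Conditional inference tree** (authored in-package): at each node every
  candidate covariate is tested for independence against the response, the
  p-values are Bonferroni-adjusted across the covariates tested at that
  node, and growth stops when the smallest adjusted p-value is not below α
  (default 0.05), the depth limit is reached, or the node is smaller than
  `min_node`.  The association test defaults to the exact t-distribution
  p-value of the Pearson statistic — equivalent in rank order to the
  standardized linear permutation statistic and better calibrated in small
  samples than the normal approximation; a seeded Monte-Carlo permutation
  test is available (`test_method="permutation"`).  The split point on the
  selected covariate maximizes the standardized two-sample statistic over
  observed midpoints, ties resolved to the smallest threshold; ordinal
  covariates are treated as numeric scores, so their level partitions are
  exactly the midpoint splits.
- **Random forest**: scikit-learn regression forest behind the package
  surface.  Defaults: B = 500 trees, `m = ⌊k/3⌋` candidate covariates per
  split, `min_leaf = 5`.  Out-of-bag predictions average the trees whose
  bootstrap excluded the row; rows never out of bag (tiny forests) are
  excluded from the OOB error with a warning.
- **Depth tuning**: grid search (default 1–20) by 5-fold cross-validated
  negative MSE; ties go to the smallest depth (parsimony).  Test MSE/R² come
  from a single stratified 80/20 split (stratified on response quartiles).

## Shapley decomposition

- **Exact mode** retrains the model on every coalition:
  `v(S) = MLD(fitted of the refit on S)`, `v(∅) = 0`.  Each of the 13
  circumstance covariates is one player; the 2^13 = 8,192 coalition values
  are cached and the standard Shapley weights applied.  Efficiency
  (Σφ = θ_a) holds to numerical tolerance by construction and is asserted at
  1e-8 relative.
- Coalition forests are reduced (default B = 100; the acceptance checks use
  smaller B still) and reuse one seed derived deterministically from the
  base seed and the coalition bitmask — a documented approximation knob.
  Coalition refits consider **all** subset covariates at each split: random
  feature sub-sampling at small |S| makes coalition values incomparable
  across subset sizes and was observed in pilot runs to produce wildly
  non-monotone value functions.
- **Sampled mode** averages marginal contributions over random permutations
  and reports per-variable standard errors; when `n_perm ≥ k!` (and k ≤ 8)
  all distinct permutations are enumerated once and the estimate equals the
  exact value.
- **Surrogate mode** (the fast path for tree models): per-observation
  additive attributions are computed exactly for the path-dependent
  expectation game — features absent from a coalition are integrated out
  with training-cover weights edge by edge; repeated features on a path AND
  their indicators and multiply their cover fractions.  Each leaf's subgame
  depends only on the unique features on its path, so it is solved by subset
  enumeration over at most `depth` features and summed across leaves
  (linearity), vectorised over observations: complexity O(T · L · 2^depth ·
  n).  Local accuracy (base + Σ_j φ_ij = Ĥ_i) holds to machine precision on
  every row.  Coalition predictions are then rebuilt additively,
  `ĥ_i(S) = base + Σ_{j∈S} φ_ij`, and an exact Shapley run over their MLDs
  needs no retraining.  Exact (refit) mode is the reference; pilot runs on a
  seeded forest (k = 4, n = 500) put the surrogate within a few percentage
  points of it, and the test suite fixes a 10-point band from those pilots.
- Slightly negative contributions are possible (MLD is nonlinear); they are
  reported as-is, never clipped.  The feature-independence convention of the
  surrogate's marginal expectations is a known limitation: correlated
  circumstances can have partially confounded attributions.

## Quantile analysis

The RIF of the τ-quantile uses the linear-interpolation sample quantile and
a Gaussian-kernel density estimate at it with Silverman's rule-of-thumb
bandwidth `0.9·min(sd, IQR/1.349)·n^{-1/5}`.  UQR is the OLS of the RIF on
the circumstance covariates (no fixed effects).  Per-quantile inequality is
measured **on the RIF scale**: one positivity shift common to all τ (chosen
so the global minimum of actual and fitted RIF values is at least ε = 1),
then `θ_a(τ) = MLD(fitted RIF)`, `θ_r(τ)` its ratio to the MLD of the actual
RIF, with an exact Shapley decomposition over UQR subset refits (cheap via a
precomputed Gram matrix).  This RIF-MLD convention is the package's declared
reading of "per-quantile opportunity inequality"; other conventions exist.

Discrete outcomes create a real degeneracy: when a τ-quantile falls inside
an outcome atom (e.g. the top category holds more than 25% of patients, so
the 0.75 quantile is the top value), the RIF is constant — there is no
inequality at that quantile.  The package reports θ_a(τ) = 0 with undefined
(NaN) relative value and shares, with a warning, rather than failing or
fabricating a number.

## Synthetic data generator

The generator emulates the marginal structure of a provincial inpatient
sample of cardiovascular/cerebrovascular patients aged 45+ (means, sds and
ranges of the thirteen circumstance covariates; a four-category discharge
mix defaulting to 35/50/12/3%).  Design choices:

- Continuous covariates are truncated normals whose parent parameters are
  solved numerically so the *truncated* moments match the targets; ordinal
  covariates are categorical distributions solved from the printed
  mean/sd moment equations; binaries are Bernoulli.
- Bed density, doctor density, rail transit and old-area status are
  **city-level**: drawn once per synthetic city (default 11) and shared by
  that city's patients, preserving the clustered structure of macro
  covariates.  Because 11 cluster draws cannot hit patient-level moments,
  city values are calibrated after the draw — continuous values by an
  affine rescale of the patient-weighted moments (then clamped to range),
  binary flags by the subset of cities whose patient share is closest to the
  target mean.  City-level covariates therefore match their targets almost
  exactly by construction; the clustered correlation structure is what a
  macro-matched administrative sample would show.
- The latent health score is
  `h* = √env_share · standardize(s(E)) + √(1−env_share) · ε`, `ε ~ N(0,1)`
  a single effort/luck noise term.  `s` is linear (default), linear plus
  bed×doctor and surgery×age interactions, or a threshold score; the linear
  weights put surgical level, bed density and doctor density first.  Three
  increasing cutpoints discretize `h*` into the discharge categories.
  Joint dependence between patient-level covariates is available through an
  optional Gaussian copula (default: independence).
- Secondary diagnoses are noisy copies of the primary category (rate 0.35,
  1–3 codes); expenses are lognormal with group-specific location and
  dispersion plus loadings on surgery and admission severity, giving the
  cost-variance feature real between-group signal.
- `oracle_iop` integrates the effort noise out in closed form (the
  conditional category distribution given the circumstance score is
  normal-CDF differences), Monte-Carlo averaging over circumstances only,
  under the same RINT + reversal + shift convention as preprocessing.  It is
  exactly 0 at `env_share = 0` and exactly 1 at `env_share = 1`.

What the generator does **not** emulate: the joint dependence of real
administrative covariates (default is independence given city), disease
-specific clinical structure, any sampling-frame effects.  Passing tests on
synthetic data therefore demonstrate correctness of the estimators under a
known mechanism, not the realism of any particular empirical estimate.

## Problem sizes and numerical choices

The shipped demonstrations and checks run at desk scale, chosen as the
package's defaults: pipeline demonstrations at n = 20,000; exact Shapley
over all 8,192 coalitions of 13 covariates at n = 5,000 with depth-limited
refits (depth-2 trees, 8-tree depth-3 forests); parameter recovery at
n = 50,000 × 20 replicates; the generator calibration check at n = 100,000.
Zero-variance covariates test at p = 1; argmax tie-breaks take the first
(smallest-threshold / smallest-depth) candidate; empty coalitions evaluate
to exactly 0; all randomness flows from one root seed through named
substreams, and reruns at a fixed seed reproduce every CSV byte for byte.

## Known limitations

- Exogeneity of circumstances is assumed; surgical level in particular may
  absorb effort-like variation in real data.
- RINT does not identify the spacing between adjacent ordinal categories;
  estimated health distances are approximate by construction.
- The MLD positivity shift is a substantive parameter: θ values are only
  comparable at a common shift.
- No bootstrap standard errors for θ_a/θ_r (extension point); no ex-post
  measurement; no dependence-aware (conditional) Shapley attribution.
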