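# opineq — measuring and decomposing health opportunity inequality

`opineq` implements the ex-ante parametric measurement of *opportunity
inequality* in health outcomes — the share of outcome inequality attributable
to circumstances beyond individual control (Roemer's environment/effort
framework) — together with a Shapley-value decomposition of that inequality
into per-circumstance contributions, overall and at chosen quantiles.

It is written for health economists and epidemiologists working with
patient-level administrative records whose outcome is an ordinal discharge
diagnosis (1 = cured, 2 = improved, 3 = not cured, 4 = death) and whose
circumstance set mixes individual covariates (age, gender, ethnicity, marital
status, occupational risk, admission condition...) with regional healthcare
accessibility (beds and doctors per 1,000 residents, rail transit,
old-revolutionary-area status, surgical level, cost dispersion per
diagnosis).  Because such records are confidential, the package ships a
calibrated synthetic generator with *known* ground truth so the whole chain
is testable end to end.

## The method

Let `H_i` be health and `E_i` the circumstance (environment) vector.  Under
the ex-ante parametric approach the health determination equation
`H_i = f(E_i, e_i)` is estimated with environment-only predictors, and the
fitted values `Ĥ_i` form a counterfactual "smoothed" distribution in which
within-circumstance (effort) variation has been averaged out.  With the mean
log deviation

    I(y) = (1/n) Σ_i ln( μ_y / y_i ),

absolute and relative opportunity inequality are

    θ_a = I(Ĥ),        θ_r = I(Ĥ) / I(H) ∈ [0, 1].

Three model families produce `Ĥ`: OLS (the linear benchmark), a conditional
inference tree (recursive partitioning by Bonferroni-adjusted independence
tests, avoiding impurity-based selection bias), and a random regression
forest (B bootstrap trees, m random candidate covariates per split,
prediction = per-tree average, OOB error reported).  Tree depth is tuned by
k-fold cross-validated negative MSE.

θ_a is then attributed to the individual circumstances by Shapley value over
variable coalitions, `v(S) = I(Ĥ_S)` with `Ĥ_S` the refit on subset `S`
(exact mode, 2^k refits), by Monte-Carlo permutation sampling, or by a fast
tree-structure surrogate: per-observation additive attributions computed
exactly from the tree paths (the TreeSHAP shortcut, path-dependent cover
weighting) are recombined into coalition predictions so no retraining is
needed.  Per-quantile analysis regresses the recentered influence function
of the τ-quantile on `E` (unconditional quantile regression) and repeats the
measurement and decomposition at τ ∈ {0.25, 0.5, 0.75}.

The ordinal outcome enters as a continuous variable via the rank-based
inverse normal transformation at cumulative-frequency midpoints,
`z_k = Φ⁻¹(F_{k-1} + f_k/2)`, reversed so higher = healthier and shifted to
positivity (MLD needs positive values; the shift is a declared parameter).

## Worked example

```python
from opineq import (GeneratorConfig, generate, preprocess, fit_linear,
                    fit_cit, fit_forest, opportunity_inequality, oracle_iop)

cfg = GeneratorConfig(n=10_000, seed=2, env_share=0.3)   # 30% of latent-health
prep = preprocess(generate(cfg))                          # variance is environmental
X, hv = prep.env, prep.health["primary"]

for name, model in {
    "linear": fit_linear(X, hv.values),
    "cit":    fit_cit(X, hv.values, max_depth=4, min_node=100),
    "forest": fit_forest(X, hv.values, n_trees=100, max_depth=4, seed=2),
}.items():
    res = opportunity_inequality(model.fitted, hv.values, family=name)
    print(name, round(res.absolute_iop, 4), round(res.relative_iop, 3))
```

prints

```
linear 0.0033 0.213
cit 0.0028 0.18
forest 0.0018 0.119
```

i.e. the linear model attributes 21.3% of the MLD of transformed health to
circumstances; the ground truth for this configuration,
`oracle_iop(cfg) ≈ 0.205`, is computed by integrating the effort noise out of
the known data-generating process.  The `examples/` directory has one short
script per capability (simulation and ground truth, measurement,
decomposition, quantile profiles, the full pipeline); a thin CLI wraps the
pipeline:

```bash
opineq simulate --n 20000 --seed 1 --out patients.csv
opineq run --config examples/run_config.yaml
```

A pipeline run writes `table1.csv` (θ_a, θ_r, total MLD, depth, MSE, R² per
model family × health variant), `table3.csv` (per-circumstance Shapley
shares), `table4.csv` (per-quantile results) and a run-metadata JSON, all
reproducible byte for byte under a fixed seed.

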