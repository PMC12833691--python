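"""Measure opportunity inequality with the three environment-only models.

Preprocessing turns the ordinal discharge diagnosis into a continuous,
reversed, positivity-shifted health score; each model's fitted values form a
counterfactual distribution purged of within-circumstance (effort) variation,
and the mean log deviation of that distribution is the absolute opportunity
inequality theta_a; dividing by the MLD of actual health gives the relative
share theta_r.
"""

from opineq import (GeneratorConfig, fit_cit, fit_forest, fit_linear,
                    generate, opportunity_inequality, preprocess)

prep = preprocess(generate(GeneratorConfig(n=10_000, seed=2, env_share=0.3)))
X, hv = prep.env, prep.health["primary"]

models = {
    "linear": fit_linear(X, hv.values),
    "cit": fit_cit(X, hv.values, max_depth=4, min_node=100),
    "forest": fit_forest(X, hv.values, n_trees=100, max_depth=4, seed=2),
}
for name, model in models.items():
    res = opportunity_inequality(model.fitted, hv.values, family=name,
                                 variant="primary", shift=hv.shift)
    print(f"{name:>7}: theta_a = {res.absolute_iop:.4f}  "
          f"theta_r = {res.relative_iop:.3f}  (total MLD {res.total_mld:.4f})")

print("\n-> theta_r is the share of health inequality attributable to the 13 "
      "circumstance covariates; tree models can exceed the linear benchmark "
      "when the true mechanism is nonlinear.")
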