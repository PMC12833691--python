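"""Attribute opportunity inequality to individual circumstances by Shapley value.

Exact mode refits the model on every covariate coalition (2^k refits); the
surrogate mode reads per-observation additive attributions off the fitted
tree structure and needs no retraining — the trade the TreeSHAP shortcut
makes.  Both satisfy efficiency: contributions sum to theta_a.
"""

import pandas as pd

from opineq import GeneratorConfig, fit_forest, generate, preprocess
from opineq.decomposition import (ForestRecipe, LinearRecipe,
                                  attribution_matrix, shapley_exact,
                                  surrogate_inequality_shares)

prep = preprocess(generate(GeneratorConfig(n=5_000, seed=3, env_share=0.3)))
X, y = prep.env, prep.health["primary"].values

linear = shapley_exact(LinearRecipe(X, y))

forest = fit_forest(X, y, n_trees=60, max_depth=4, seed=3)
surrogate = surrogate_inequality_shares(attribution_matrix(forest, X))

table = pd.DataFrame({
    "linear_exact_pct": dict(zip(linear.variables, linear.shares)),
    "forest_surrogate_pct": dict(zip(surrogate.variables, surrogate.shares)),
}).sort_values("linear_exact_pct", ascending=False)
print(table.round(2))
print(f"\ncolumn sums: {table.sum().round(4).to_dict()} "
      "(efficiency: shares always total 100%)")
print("-> surgical level and regional bed/doctor density should dominate: "
      "they carry the largest weights in the synthetic mechanism.")
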