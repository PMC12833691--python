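"""One seeded end-to-end run producing the three report tables.

Equivalent to `opineq run --config examples/run_config.yaml`.
"""

from opineq import RunConfig, run

cfg = RunConfig(
    generator={"n": 8_000, "env_share": 0.35, "nonlinearity": "interaction"},
    seed=1,
    depth_grid=(2, 4, 6),
    cv_folds=3,
    forest={"n_trees": 60, "min_leaf": 10},
    cit={"alpha": 0.05, "min_node": 100},
    out_dir="opineq_demo_run",
)
res = run(cfg)

print(res["table1"].round(4).to_string(index=False))
print("\ntop contributions (primary health):")
t3 = res["table3"].query("variant == 'primary'")
print(t3.pivot(index="variable", columns="family", values="share_pct")
      .round(2).sort_values("linear", ascending=False).head(6))
print(f"\nCSV tables and run metadata written to {res['out_dir']}/")
print("-> under the interaction mechanism the tree families fit better "
      "(higher R2) and register more opportunity inequality than the "
      "linear benchmark.")
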