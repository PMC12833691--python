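# pipeline configuration: `opineq run --config examples/run_config.yaml`
# exactly one of `generator` / `input_path` may be set
generator:
  n: 8000
  env_share: 0.35
  nonlinearity: interaction   # linear | interaction | threshold
seed: 1
shift: 5.0                    # positivity shift of the transformed health score
variants: [primary, composite]
taus: [0.25, 0.5, 0.75]
depth_grid: [2, 4, 6]         # cross-validated depth search grid
cv_folds: 3
cit:
  alpha: 0.05
  min_node: 100
forest:
  n_trees: 60
  min_leaf: 10
decomposition_mode: auto      # auto | exact | sampled | none
out_dir: opineq_demo_run
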