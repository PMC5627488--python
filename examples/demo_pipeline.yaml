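# Demo pipeline config: walkmap run --config examples/demo_pipeline.yaml
seed: 5
out_dir: scratch/demo_run
generator:
  grid_side: 8
  cohort_size: 5000
mcmc:
  iterations: 5000
  thin: 5
  n_chains: 2
outcomes:
  - sufficient_walking
models: [M1, M2, M3]
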