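# Demo run: full pipeline on a 2,000-gene / 9-sample synthetic dataset.
#   altipop run --config configs/demo.yaml
out_dir: scratch/demo_run
seed: 1
simulation:
  n_transcripts: 2000
abc_n_sims: 10000
abc_tolerance: 0.01
n_permutations: 999
outlier_quantile: 0.99
lsbl_threshold: 0.5
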