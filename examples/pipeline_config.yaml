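# Demo configuration for `demosfs run-all --config examples/pipeline_config.yaml`
# Simulates a small dataset under the bundled six-taxon model (model: null),
# filters it, builds all pairwise 2D-mSFS, refits the oldest divergence time
# and writes goodness-of-fit summaries, all under outputs/demo/.
out_dir: outputs/demo
model: null          # null -> bundled best six-taxon model (e1)
n_sites: 2000
seed: 7
filter:
  r: 0.8
  p: 6
  min_mac: 0         # keep monomorphic sites: they calibrate absolute times
  max_obs_het: 0.5
schedule:
  n_starts: 1
  n_cycles: 4
  n_sims: 1500
free_params: [T1]    # refit only the oldest split in this quick demo
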