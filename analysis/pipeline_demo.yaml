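# End-to-end demo configuration for `orncausal run-all`.
# Scaled for a few minutes on one CPU; raise forest.n_trees to 2000,
# grid_step to 1 and n_boot to 1000 for a production run.
sim:
  n_vmat: 931
  n_pbspt: 335
  seed: 1
forest:
  n_trees: 200
  centering_trees: 100
  seed: 0
grid_step: 4
n_boot: 50
rule: max_z
out_dir: results/pipeline
seed: 7
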