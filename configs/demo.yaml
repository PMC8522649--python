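# Demo run: fully synthetic inputs, scaled for a quick end-to-end pass.
out_dir: run_demo
seed: 7
simulate: true
sim:
  n_per_group: 50
  n_regions: 308
  n_left_regions: 151
  n_genes: 2000
  effect_size: 1.5
  coupling_strength: 0.8
  memory_coupling: 0.5
B: 500
B_perm: 500
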