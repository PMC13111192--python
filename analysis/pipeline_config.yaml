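# Example end-to-end pipeline configuration for `cascnet full`.
# Simulates a 38-patient / 23-control cohort with a planted
# source -> relay -> sink motif, then runs every analysis stage.
rng_seed: 1
data_dir: dataset
grid_shape: [20, 20, 20]
vbm:
  n_permutations: 300
gc:
  gc_threshold: 0.39
  z_threshold: 3.75
sim:
  n_patients: 38
  n_controls: 23
  roi_names: [TPOmid.L, ITG.L, PHG.L, PHG.R, CAU.L, CAU.R, REC.R, PUT.L, CC1.R]
  planted_edges:
    - [PHG.R, ITG.L, 2.0]
    - [PHG.R, TPOmid.L, -1.5]
    - [TPOmid.L, ITG.L, 1.2]
  atrophy_profile: {TPOmid.L: -0.006}
  group_deficit: {TPOmid.L: 0.9}
  noise_sd: 0.3
  rng_seed: 1
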