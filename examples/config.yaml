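# Desk-scale end-to-end run (minutes on one CPU).
# Raise n_nulls to 1000 and n_permutations to 5000 for full-scale analysis.
n_cn: 20
n_emci: 20
n_lmci: 20
metrics: [GMV]
grid_size: 128
n_nulls: 20
outer_folds: 5
inner_folds: 3
penalty_grid_size: 8
n_permutations: 50
effects:
  GMV:
    affected_rois:
      - [AAL116, Hippocampus_L]
      - [AAL116, Hippocampus_R]
      - [AAL116, Thalamus_L]
    effect_size_emci: -0.3
    effect_size_lmci: -0.8
    cognition_coupling: -2.0
    noise_sd: 2.0
    samples_per_roi_mean: 100
seed: 1
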