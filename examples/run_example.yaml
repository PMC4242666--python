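# Full pipeline run for the wild-type receptor preset.
preset: WT
seed: 7
n_cells: 50
replicates: 3
noise_cv: 0.05
readouts: [ca_i, ip1, perk, phe_response]
outdir: casr_run_wt
make_figures: true
dynamics:
  n_residues: 20
  n_frames: 2000
  blocks:
    - {set_a: [0, 1, 2], set_b: [0, 1, 2], correlation: 0.9}
    - {set_a: [10, 11, 12], set_b: [10, 11, 12], correlation: 0.9}
    - {set_a: [0, 1, 2], set_b: [10, 11, 12], correlation: -0.8}
  sites:
    site1: [0, 1, 2]
    site3: [10, 11, 12]
  couplings:
    - {a: site1, b: site3}
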