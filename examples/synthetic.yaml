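seed: 1
output_dir: corrshuttle_out
synthetic:
  n_trajectories: 6
  switching:
    mean_a:
    - 3.2
    - 2.5
    mean_b:
    - 2.7
    - 2.8
    sigma: 0.08
    theta: 1.0
    k_ab: 0.05
    k_ba: 0.05
    dt: 0.1
    n_frames: 20000
    coupled: true
  one_x:
    mu: 2.6
    sigma: 0.15
    theta: 1.0
  network:
    n_residues: 24
    planted_path:
    - 0
    - 1
    - 2
    - 3
    - 4
    - 5
    - 6
    - 7
    - 8
    - 9
    - 10
    - 11
    - 12
    on_path_correlation: 0.9
    off_path_correlation: 0.1
    chain_geometry: 0.4
    n_frames: 20000
    displacement_std: 0.05
    mobile_scale: 2.0
    mobile_residues:
    - 12
    - 13
    - 14
    - 15
    - 16
    - 17
    - 18
    - 19
    - 20
    - 21
    - 22
    - 23
    subunit_split: 12
  write_trajectory: false
trim_ns: 200.0
occupancy:
  c_min: 0.67
  c_max: 1.0
  c_step: 0.01
  d_min: 1.5
  d_max: 4.5
  d_step: 0.01
  highlight_c:
  - 0.8
  - 0.9
  - 1.0
distributions:
  bin_width: 0.05
  bandwidth: auto
  min_prominence: 0.05
flexibility:
  selections:
    docked: RINGA:1-12
    distant: RINGB:1-12
  reference: first
network:
  contact_cutoff: 0.5
  occupancy: 0.75
  source: RINGA:1
  sink: RINGB:1
  hop_cutoff: 0.8
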