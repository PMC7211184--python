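layout:
  well_side_um: 300.0
  well_depth_um: 39.0
  well_spacing_um: 50.0
  n_well_rows: 12
  n_well_cols: 14
  post_side_um: 40.0
  post_grid_rows: 3
  post_grid_cols: 3
  post_pitch_um: 100.0
  pixel_size_um: 5.0
plex:
  control: cel-miR-54
  posts:
  - row: 0
    col: 0
    probe: miR-21
    role: target
  - row: 0
    col: 1
    probe: let-7a
    role: target
  - row: 0
    col: 2
    probe: miR-16
    role: target
  - row: 1
    col: 0
    probe: miR-19b
    role: target
  - row: 1
    col: 1
    probe: miR-210
    role: target
  - row: 1
    col: 2
    probe: miR-20a
    role: target
  - row: 2
    col: 0
    probe: miR-15b
    role: target
  - row: 2
    col: 1
    probe: cel-miR-54
    role: negative_control
  - row: 2
    col: 2
    probe: blank
    role: blank
scenario:
  gain_afu_per_amol: 1000.0
  background_afu: 1500.0
  slide_afu: 100.0
  pixel_noise_sd_afu: 50.0
  saturation_afu: 65535.0
  missing_post_prob: 0.005
  seed: 7
  dust:
    count: 4
    side_um:
    - 60.0
    - 120.0
    intensity_afu:
    - 40000.0
    - 60000.0
  regions:
  - label: Tumor 1
    polygon:
    - - 873.0
      - 622.5
    - - 2182.5
      - 622.5
    - - 2182.5
      - 2075.0
    - - 873.0
      - 2075.0
    amounts:
      miR-21: 15.0
      let-7a: 8.0
      miR-16: 6.0
      miR-19b: 4.0
      miR-210: 1.0
      miR-20a: 1.5
      miR-15b: 2.5
  - label: Tumor 2
    polygon:
    - - 2667.5
      - 1867.5
    - - 4365.0
      - 1867.5
    - - 4365.0
      - 3527.5
    - - 2667.5
      - 3527.5
    amounts:
      miR-21: 25.0
      let-7a: 8.0
      miR-16: 6.0
      miR-19b: 10.0
      miR-210: 1.0
      miR-20a: 1.5
      miR-15b: 2.5
  - label: NAT
    polygon:
    - - 242.5
      - 207.5
    - - 4607.5
      - 207.5
    - - 4607.5
      - 3942.5
    - - 242.5
      - 3942.5
    amounts:
      miR-21: 5.0
      let-7a: 4.0
      miR-16: 6.0
      miR-19b: 2.0
      miR-210: 1.0
      miR-20a: 1.5
      miR-15b: 2.5
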