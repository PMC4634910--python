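# Example configuration for `cinedense simulate` / `cinedense sweep`.
# Sections map one-to-one onto PhantomConfig / EncodingConfig /
# ExperimentConfig fields.
phantom:
  grid_size: 128
  pixel_mm: 2.8
  n_frames: 30
  frame_ms: 17.0
  endo_radius_mm: 25.0
  epi_radius_mm: 35.0
  peak_ecc: -0.20          # peak global circumferential Lagrangian strain
  peak_twist_deg: 8.0
  es_frame: 20
encoding:
  ke_cycles_per_mm: 0.10   # sweep range: 0.02 .. 0.10
  kd_thru_plane: 0.08      # cycles/mm across the slice
  slice_mm: 8.0
  cspamm: true
  target_snr: 20.0
  fov_mm: 360.0
  seed: 1
experiment:
  n_subjects: 10
  ke_list: [0.02, 0.04, 0.06, 0.08, 0.10]
  repeat_reference: true   # second 0.10 acquisition for inter-test repeatability
  target_snr: 20.0
  seed: 1
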