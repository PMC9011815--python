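# ribotrace demonstration configuration.
# Any omitted section falls back to the package defaults shown here.

seed: 7

migration:
  t_ref: 49.0        # s, apex of the reference construct
  s_ref: 2000.0      # nt
  slope: 23.3        # s per decade of size
  run_length: 70.0   # s
  sample_rate: 20.0  # Hz

ladder:
  transcript_sizes: [200, 500, 1000, 1500, 2000, 3000, 4000, 6000]
  lower_marker_time: 19.0

noise:
  white_sd: 1.0        # signal units
  drift_amplitude: 2.0 # signal units over the run
  drift_order: 1

kinetic_truth:
  Ea: 74.8    # kJ/mol
  lnA: 25.712 # ln(1/day)

scenario:
  concentration: 10.0   # ug/mL
  intact_fraction: 0.8
  construct_size: 2000.0
  brij_pct: 10.0
  formamide_pct: 85.0
  heated: true

study:
  start_integrity: 80.0
  temperatures: [-20, 4, 25, 37, 45, 60]   # deg C
  timepoints: [0, 4, 7, 14, 30, 60, 90]    # days

integration:
  marker_window: [15.0, 22.0]
  marker_halfwidth: 2.4
  snr_floor: 3.0

qualification:
  lod_snr: 3.0
  loq_snr: 10.0
  linearity_concs: [2.5, 5.0, 7.5, 10.0, 12.5, 15.0]
  dilution_concs: [0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.5, 5.0, 10.0, 15.0]
  n_blanks: 3
  n_suitability: 6
  recovery_purity_high: 71.7
  recovery_purity_low: 22.9
  recovery_mix_fraction: 0.5
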