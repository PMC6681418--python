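# Single eight-frequency scan of beads in water on a chip whose resonance
# sits at 7.54 MHz: the voltage minimum marks the optimal trapping frequency.
name: chip_scan_754
seed: 1
cavity:
  tune: {frequency_mhz: 7.54, medium: water25C}
  quality_factor: 1000
  peak_pressure_pa: 5.0e+5
piezo:
  baseline_vpp: 2.0
  dip_depth_vpp: 0.5
  noise_sigma_v: 0.02
scan:
  start_mhz: 7.48
  points: 8
  span_mhz: 0.14
  dwell_s: 0.1
track:
  step_mhz: 0.01
  dwell_s: 2.0
  rise_threshold: 2.0
  max_steps: 20
phases:
  - {name: beads_water, medium: water25C, mode: scan, expected_mhz: 7.54}
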