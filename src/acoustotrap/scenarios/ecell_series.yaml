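# Epithelial-lysate series: beads in water on a chip tuned to 7.76 MHz, then
# lysate surrogates for 75k, 100k and 150k ruptured cells (sound-speed shift
# calibrated to the observed resonance series). Six-point 0.02 MHz grid.
# Each scan phase also renders synthetic trap-site stills whose aggregate
# area follows the stored acoustic energy, for the yellow-pixel scorer.
name: ecell_series
seed: 1
cavity:
  tune: {frequency_mhz: 7.76, medium: water25C}
  quality_factor: 1000
  peak_pressure_pa: 5.0e+5
piezo:
  baseline_vpp: 2.0
  dip_depth_vpp: 0.5
  noise_sigma_v: 0.02
scan:
  start_mhz: 7.72
  points: 6
  span_mhz: 0.10
  dwell_s: 0.1
track:
  step_mhz: 0.01
  dwell_s: 2.0
  rise_threshold: 2.0
  max_steps: 20
imaging:
  max_area_px: 1600
  frame_shape: [160, 160]
phases:
  - {name: water, medium: water25C, mode: scan, expected_mhz: 7.76}
  - {name: lysate75k, medium: "lysate:75000", mode: scan, expected_mhz: 7.78}
  - {name: lysate100k, medium: "lysate:100000", mode: scan, expected_mhz: 7.78}
  - {name: lysate150k, medium: "lysate:150000", mode: scan, expected_mhz: 7.80}
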