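# Mock sexual-assault sample session: eight-point chip scan with the bead
# scanning solution (minimum at 7.59 MHz), then upward tracking of the lysed
# sample (+0.264% sound speed, resonance 7.61 MHz), then a wash hold.
# The scan grid starts at 7.49 MHz so the 7.59 MHz chip frequency is a grid
# point of the 8-point, 0.14 MHz-span sweep.
name: mock_sample
seed: 1
cavity:
  tune: {frequency_mhz: 7.59, medium: water25C}
  quality_factor: 1000
  peak_pressure_pa: 5.0e+5
piezo:
  baseline_vpp: 2.0
  dip_depth_vpp: 0.5
  noise_sigma_v: 0.02
scan:
  start_mhz: 7.49
  points: 8
  span_mhz: 0.14
  dwell_s: 0.1
track:
  step_mhz: 0.01
  dwell_s: 2.0
  rise_threshold: 2.0
  max_steps: 20
phases:
  - {name: scanning_solution, medium: water25C, mode: scan, expected_mhz: 7.59}
  - name: mock_sample
    medium: {preset: water25C, sound_speed_scale: 1.00264}
    mode: track
    expected_mhz: 7.61
  - {name: wash, medium: water25C, mode: hold}
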