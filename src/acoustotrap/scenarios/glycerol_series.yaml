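# Viscosity-shift series: fluorescent beads in water, then 5% and 10%
# glycerol, on one chip tuned so the water voltage minimum sits at 7.58 MHz.
# Expected minima: 7.58 (water), 7.64 (5%); the 10% phase lands at 7.70 from
# the 25 degC literature sound speed (printed value 7.68, one grid step off).
name: glycerol_series
seed: 1
cavity:
  tune: {frequency_mhz: 7.58, medium: water25C}
  quality_factor: 1000
  peak_pressure_pa: 5.0e+5
piezo:
  baseline_vpp: 2.0
  dip_depth_vpp: 0.5
  noise_sigma_v: 0.02
scan:
  start_mhz: 7.52
  points: 13
  span_mhz: 0.24
  dwell_s: 0.1
track:
  step_mhz: 0.01
  dwell_s: 2.0
  rise_threshold: 2.0
  max_steps: 20
phases:
  - {name: water, medium: water25C, mode: scan, expected_mhz: 7.58}
  - {name: glycerol5, medium: "glycerol:0.05", mode: scan, expected_mhz: 7.64}
  - {name: glycerol10, medium: "glycerol:0.10", mode: scan, expected_mhz: 7.70}
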