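"""Classic vs wideband peak detector at trapping frequencies.

Simulates both detector variants holding the envelope of a 6 Vpp signal.
At 1 MHz both track the 3 V peak closely; at the 8 MHz used for trapping,
the per-cycle conduction window shrinks below the comparator's 15 ns
propagation delay and the classic detector's held voltage sags past the 5%
error budget, while the wideband variant's constant charging current keeps
it closer. The downward-step lag shows the R4-limited tracking speed.
"""

from acoustotrap import (
    DetectorComponents,
    SignalSpec,
    divider,
    downward_lag_estimate,
    simulate,
    steady_state_error,
    tracking_lag,
)

amplitude = divider(18.0, 3.0) / 2.0  # 18 Vpp piezo drive -> 6 Vpp -> 3 V peak
print(f"input after divider: {divider(18.0, 3.0):.0f} Vpp (peak {amplitude:.0f} V)\n")

print(f"{'variant':>9s} {'carrier':>8s} {'steady-state error %':>21s}")
for variant in ("classic", "wideband"):
    comp = DetectorComponents(variant=variant)
    for f, duration in ((1e6, 400e-6), (8e6, 200e-6)):
        trace = simulate(SignalSpec(frequency=f, amplitude=amplitude), comp, duration=duration)
        err = steady_state_error(trace, amplitude)
        print(f"{variant:>9s} {f / 1e6:>6.0f}MHz {err:>21.2f}")

wide = DetectorComponents(variant="wideband")
step = SignalSpec(frequency=8e6, amplitude=3.0, step_time=40e-6, amplitude_after=1.0)
lag = tracking_lag(wide, step)
print(
    f"\ndownward-step lag (3 V -> 1 V): {lag * 1e6:.1f} us simulated,"
    f" {downward_lag_estimate(wide, 3.0, 1.0) * 1e6:.1f} us from the RC closed form"
    "\n— four orders of magnitude inside the 0.1 s tracking budget."
)
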