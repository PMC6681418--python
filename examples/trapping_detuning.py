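"""Why the lock matters: retention collapses off resonance.

Simulates 500 ten-micron beads flowing through the default trap zone at
45 uL/min while the drive is detuned from the 7.6 MHz resonance in 0.01 MHz
steps. Retention is the fraction of beads pulled to within 5 um of the
pressure node before they exit the 2 mm zone. A 0.05 MHz error — under 1%
of the drive — costs more than an order of magnitude of retention.
"""

from acoustotrap import (
    DEFAULT_GEOMETRY,
    POLYSTYRENE_BEAD,
    WATER,
    ResonatorCavity,
    trapping_efficiency,
    tune_height,
)

cavity = ResonatorCavity(height=tune_height(7.6e6, WATER), quality_factor=1000.0,
                         peak_pressure=0.5e6)

print(f"{'detuning MHz':>13s} {'efficiency':>11s}")
efficiencies = {}
for step in range(0, 6):
    detuning = step * 0.01e6
    res = trapping_efficiency(
        POLYSTYRENE_BEAD, 500, DEFAULT_GEOMETRY, cavity, WATER, 7.6e6 + detuning, seed=1
    )
    efficiencies[detuning] = res.efficiency
    print(f"{detuning / 1e6:>13.2f} {res.efficiency:>11.3f}")

fold = efficiencies[0.0] / efficiencies[0.05e6]
print(
    f"\nfold loss at 0.05 MHz detuning: {fold:.1f}x — the narrow Lorentzian"
    "\nof a Q=1000 cavity leaves almost no pressure amplitude that far out."
)
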