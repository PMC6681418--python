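"""How the medium moves the trapping resonance.

Builds a cavity tuned to 7.58 MHz in water and prints where the half-wave
resonance lands when the fluid is switched to glycerol mixtures and lysate
surrogates. The fractional frequency shift equals the fractional sound-speed
shift, which is why a few-percent glycerol spike or a heavy lysate load is
enough to detune a high-Q trap.
"""

from acoustotrap import (
    WATER,
    ResonatorCavity,
    glycerol_medium,
    lysate_medium,
    resonant_frequency,
    sound_speed,
    tune_height,
)

cavity = ResonatorCavity(height=tune_height(7.58e6, WATER))
print(f"cavity height for a 7.58 MHz water resonance: {cavity.height * 1e6:.2f} um\n")

print(f"{'medium':>16s} {'sound speed m/s':>16s} {'resonance MHz':>14s}")
for medium in (
    WATER,
    glycerol_medium(0.05),
    glycerol_medium(0.10),
    lysate_medium(75_000),
    lysate_medium(150_000),
):
    f_res = resonant_frequency(cavity, medium)
    print(f"{medium.label:>16s} {sound_speed(medium):>16.1f} {f_res / 1e6:>14.4f}")

print(
    "\nEach row is the frequency the controller must find: stiffer media carry"
    "\nsound faster, so the half-wave condition is met at a higher frequency."
)
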