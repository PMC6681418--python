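# Methods

This note documents the models behind `acoustotrap`, the defaults and why
they were chosen, the numerical choices, and what the simulations do and do
not establish about a physical trapping rig.

## Scope of the model

The package simulates the *feedback chain* of a resonance-tracked acoustic
trap: medium → resonance → pressure amplitude → radiation force → retention,
alongside the electronics (piezo voltage dip, peak detector) and the
controller logic that reads them. It does not model chip fabrication,
hardware I/O, pumping, lysis chemistry, or downstream DNA analysis. All
units are SI internally; frequencies appear in MHz only at the CLI and in
printed reports.

## Media and particles (`media`)

The sound speed is computed as `v = 1/sqrt(beta * rho)` with `beta` the
isothermal compressibility in 1/Pa — i.e. the "compressibility" of the
textbook relation `v = (K/rho)^1/2` is read as the bulk modulus `K = 1/beta`,
the only reading dimensionally consistent with the contrast factor's
`beta_c/beta_w` ratio.

**Glycerol–water presets** are a seven-row 25 °C literature table (mass
fraction 0–0.30 → density, sound speed, viscosity) interpolated with a
monotone PCHIP scheme, so the sound speed is strictly increasing in the
fraction. Compressibility is back-computed as `1/(rho v^2)` so each preset
reproduces its tabulated speed exactly. The table ends at 30% glycerol
because acoustic trapping fails beyond that load. The 5% entry (1508.5 m/s)
places a 7.58 MHz water chip's minimum at 7.64 MHz; the 10% entry
(1521.0 m/s, from the 1521–1525 m/s literature range) predicts 7.70 MHz,
one 0.02 MHz grid step above the 7.68 MHz observed on the bench — a real
discrepancy between tabulated mixture properties and that measurement,
reported as such rather than absorbed into the table.

**Lysate surrogates.** No property data exist for epithelial-cell lysate,
only the resonance shifts it produces, so the mapping is *calibration, not
prediction*: a one-parameter linear model `Δc/c = s · cells`, with the
default `s = 3.211e-8` per cell the least-squares fit (through the origin)
to the observed series — 7.76 MHz baseline, 7.78 MHz at 75k and 100k cells,
7.80 MHz at 150k. `fit_lysate_sensitivity` refits `s` from any
(count, resonance) pairs. Only the compressibility is adjusted; density and
viscosity are left at the base medium's values because the data constrain
only the sound speed.

## Resonator and piezo response (`resonator`)

The half-wave condition `f_res = n v / (2h)` sets the resonance; the
standing-wave pressure follows a Lorentzian in the detuning,
`p0(f) = p0_max / sqrt(1 + (2Q (f − f_res)/f_res)^2)`, with half-power
points at `f_res (1 ± 1/2Q)`. The piezo's measured output voltage is a
phenomenological dip riding on a baseline,
`V(f) = V_base − ΔV (p0/p0_max)^2 + noise`: the instrument data constrain
only the dip *location*, so a full Butterworth–Van Dyke equivalent circuit
would add parameters nothing pins down. The model deliberately equates the
voltage-minimum frequency with the fluid-cavity resonance; on hardware the
piezo's own series resonance and the cavity resonance are not separable
from the voltage trace alone.

Defaults: `Q = 1000` (glass-clad cavity), `p0_max = 0.5 MPa`,
`V_base = 2.0 Vpp`, `ΔV = 0.5 Vpp`, per-sample noise
`σ_V = 0.01 · V_base`. Dwell-averaging draws `100 · dwell` independent
noise samples per reading, so the 2 s tracking dwell is ~14× quieter than a
single sample. All defaults are overridable in configs and constructors.

## Radiation force and retention (`trapping`)

The primary radiation force
`F_r(x) = −(π p0² V β_w / 2λ) φ sin(2kx)` restores positive-contrast
particles toward the pressure node. Lateral motion is quasi-static against
Stokes drag, `dx/dt = F_r(x)/(6πμa)`: at micron scale the momentum
relaxation time (~µs) is three orders below migration times (~ms), so
inertia is dropped.

**Retention criterion.** A particle crossing the 2 mm trap zone at the mean
flow speed (45 µL/min through 1 mm × 98.75 µm gives a 0.263 s residence) is
retained iff its lateral migration brings it within a 5 µm capture radius
of the node before it exits. Initial positions are drawn uniformly over the
annulus `5 µm < |x₀| < λ/4`: a particle that *enters* already inside the
capture radius carries no information about the wave (it would be scored
"trapped" even with the drive off), so it is excluded from the ensemble.
This makes the three limiting behaviours consistent — zero field traps
nothing, a strong field in slow flow traps everything, and the
resonance/0.05 MHz-detuned efficiency ratio lands near 25× (the force drops
by `p0²`, a factor ~174 at `Q = 1000`), comfortably past the ten-fold loss
documented for high-Q traps.

Default scenario: 10 µm polystyrene beads (ρ = 1050 kg/m³,
β = 2.16e-10 1/Pa, φ ≈ 0.57 in water), 500 particles, seed recorded in the
result. The acceptance script uses this ensemble size; it resolves
efficiencies down to 0.2% and runs in well under a second.

Note on throughput arithmetic: at 45 µL/min a 100 ms dwell passes
`flow · dwell = 75 nL` through the trap; the module reports exactly this
product and makes no attempt to match smaller figures sometimes quoted for
per-step sample exposure.

## Peak detector (`peakdetect`)

Both variants are simulated in the time domain with a fixed step
(default `dt = 1/(100 · carrier)`, rejected above `1/(50 · carrier)`):
explicit Euler on the capacitor, comparator evaluated per sample,
`V_a(t)` precomputed vectorised. While the comparator output is high the
capacitor charges with

- classic: `I_c = (5 − 2V_D − V_c)/R3` (droops as the capacitor fills),
- wideband: `I_c = (5 − 2V_D)/R3 − 2V_D/R5 + V_c(−1/R3 + (G−1)/R5)`,

clamped at zero (the diode blocks reverse flow); in both states it bleeds
through `R4`. The gain `G = 1 + R5/R3` is the unique value nulling the
`V_c` term; with `R5 = R3` (hence `G = 2`) the current is the constant
`(5 − 4V_D)/R3` — with the defaults, 2.6 mA at any held voltage.

**Comparator delay semantics.** With an *ideal* comparator the steady-state
error is frequency-independent: the per-cycle conduction window and the
per-cycle bleed both scale with the carrier period, and the balance
`I_c · w = V_c · T / R4` cancels `T`. A pure transport delay does not change
this — it shifts the conduction window without shrinking it. The delay is
therefore modelled with **inertial (deglitch) semantics**, standard in logic
simulation: a comparison state must persist for `t_pd` before the output
switches, so conduction windows shorter than `t_pd` never propagate. At
8 MHz the window a nearly-full capacitor needs (≈5 ns classic, ≈1.5 ns
wideband at balance) falls below `t_pd = 15 ns`; the held voltage sags to
roughly `A·cos(π t_pd/T)` before marginal pulses recharge it, and the two
variants separate because each propagated pulse deposits `I_c · t_pd / C` —
83 mV for the wideband's constant 2.6 mA versus 26 mV for the classic's
drooped 0.8 mA. Simulated steady-state errors with the defaults: classic
0.4% at 1 MHz and 6.6% at 8 MHz; wideband 5.7% at 8 MHz.

Default components (`C = 470 pF`, `R3 = R5 = 1 kΩ`, `R4 = 100 kΩ`,
`G = 2`, `V_D = 0.6 V`, rails 0/+5 V, `t_pd = 15 ns`): no board values are
published for this class of detector, so these are declared assumptions —
plausible for a fast comparator and chosen so the envelope time constant
`R4C = 47 µs` keeps ripple ~2% per cycle at 1 MHz while tracking amplitude
drops in ~50 µs (`R4C ln(old/1.05·new)` ≈ 49 µs for a 3 V → 1 V step),
four orders inside the 0.1 s budget. All are constructor arguments.

Numerical notes: the explicit integrator can overshoot a peak by at most one
charging step `I_c·dt/C`, which bounds the observed ripple at
bleed-per-period plus that term; refining `dt` tenfold moves the
steady-state mean by <0.05%. `steady_state_error` refuses traces whose last
two half-tails still drift by more than 0.1% of the amplitude.

## Controller (`resfinder`)

The chip scan returns the voltage argmin over its grid (ties toward the
lower frequency, for determinism). Tracking steps *upward only* by default
(0.01 MHz / 2 s), mirroring how the instrument is driven — lysis and
viscosity loads raise the sound speed, so the sample minimum sits above the
chip frequency; a bidirectional mode exists behind a flag. The stop rule is
a single rise of more than `η·σ` above the running minimum (`η = 2`), with
`σ` estimated from repeated dwell samples at the start frequency; in the
noiseless limit this reduces to "any rise solidifies the previous minimum".
A consecutive-rise count is configurable for noisier rigs. With
`σ_V = 0.01·V_base` and the 2 s dwell, 200 seeded sessions lock within one
step of the true minimum in ≥95% of runs (the suite checks this).

## Imaging (`imaging`)

Frames are 8-bit sRGB (D65), converted with scikit-image's fixed constants
for bit-reproducibility. The yellow-pixel score counts HSB hue ∈ [40°, 70°]
with saturation and brightness ≥ 0.3 — thresholds chosen to accept the
fluorescent-bead yellow and reject grey channel background and dim noise;
all three are parameters. The chroma adjustment scales each pixel's (a, b)
about the **image-mean** chroma, then rotates about the origin, leaving L*
untouched: the convention of the ImageJ plugin this emulates is not fully
specified, and mean-centred scaling is the reading that leaves neutral
scenes neutral. Out-of-gamut results are clipped on conversion back, so
rotation round-trips are exact only for in-gamut chroma. The synthetic
trap-frame generator (grey background, elliptical yellow aggregate of a
requested pixel area, seeded Gaussian noise) recovers its drawn area under
the counter to within ~5% (rasterisation rim ± noise).

## Scenarios (`fixtures`)

The four shipped scenarios are YAML data, not code: a cavity tuned to a
target resonance in a named medium, a piezo spec, scan/track settings, and
ordered media phases. They encode the bench conditions — glycerol series on
a 7.58 MHz chip, lysate series on a 7.76 MHz chip (six-point grid), the
mock-sample session (7.59 MHz chip scan, +0.264% sample → 7.61 MHz lock),
and a single 8-point scan on a 7.54 MHz chip. The mock-sample scan grid
starts at 7.49 MHz so the 8-point, 0.14 MHz-span grid actually contains the
7.59 MHz chip frequency. Sound-speed perturbations standing in for lysate
and serum are calibrated constants declared in the scenario files. Per-phase
RNG seeds derive from the scenario seed; re-running a scenario reproduces
every CSV byte for byte.

## What passing tests do and do not show

The synthetic layer reproduces *relationships* — medium-driven resonance
shifts, the voltage dip marking the optimum, the controller's lock logic,
the detuning cost of mistuning, the detector's frequency-dependent error —
under idealised conditions: additive Gaussian voltage noise, a single
lateral dimension, no acoustic streaming, no particle–particle forces, no
thermal drift, plug flow at the mean speed, ideal diode and op-amp buffers.
Passing tests show the feedback logic and the physics plumbing are
self-consistent and reproduce the documented operating points; they do not
certify retention percentages on a physical chip, where streaming,
aggregation kinetics and 3D flow profiles matter.

## Problem sizes

Defaults were sized for a laptop-class single core: 500-particle ensembles
(vectorised RK4, ~0.1 s per frequency), 200 µs detector transients at
1.25 ns steps (~160k samples, ~0.3 s), 200-session controller robustness
sweeps (~2 s). The full test suite runs in ~10 s; the acceptance script in
~2 s.
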