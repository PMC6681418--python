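"""Time-domain simulation of the classic and wideband peak detectors.

The detector holds the envelope of an attenuated AC signal ``V_a(t)`` on a
capacitor ``C``. A fast comparator swings its output to the high rail
whenever the instantaneous input exceeds the held voltage ``V_c``; the high
output drives a charging current into ``C`` through ``R3`` and a diode,
while a bleed resistor ``R4`` lets ``V_c`` sag to follow downward amplitude
changes.

Charging current while the comparator output is high (rail = 5 V, diode
drop ``V_D`` per junction):

    classic:   I_c = (5 - 2 V_D - V_c) / R3
    wideband:  I_c = (5 - 2 V_D)/R3 - 2 V_D/R5 + V_c (-1/R3 + (G-1)/R5)

The wideband variant adds an amplifier (gain ``G``) acting as a second
current source; choosing ``G = 1 + R5/R3`` nulls the ``V_c``-dependent
bracket, and with additionally ``R5 = R3`` (hence ``G = 2``) the current is
the constant ``(5 - 4 V_D)/R3``. A voltage-independent charging current is
what lets the wideband detector top up the capacitor inside the few-ns
conduction window available per cycle at MHz carriers.

Comparator non-ideality is a propagation delay ``t_pd`` with inertial
(deglitch) semantics: a comparison state must persist for ``t_pd`` before
the output switches, so conduction windows shorter than ``t_pd`` never
appear at the output. This is what makes the steady-state error frequency
dependent: per-cycle conduction window and bleed both scale with the
carrier period, so with an ideal comparator the error would be the same at
1 MHz and 8 MHz; with the delay, the window a nearly-full capacitor needs
at 8 MHz falls below ``t_pd`` and the held voltage sags until pulses
propagate again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "DetectorComponents",
    "SignalSpec",
    "DetectorTrace",
    "divider",
    "gain_condition",
    "charging_current",
    "simulate",
    "steady_state_error",
    "tracking_lag",
    "downward_lag_estimate",
    "NotConvergedError",
    "DEFAULT_COMPONENTS",
]


class NotConvergedError(RuntimeError):
    """Raised when a trace has not reached steady state where one is required."""


@dataclass(frozen=True)
class DetectorComponents:
    """Component values of the peak-detector board.

    None of the board values are published; these defaults are plausible for
    the comparator class used (fast, ~15 ns propagation delay) and an
    envelope time constant ``R4 C = 47 us`` that tracks amplitude changes
    well inside 0.1 s while keeping per-cycle ripple small at MHz carriers.
    """

    attenuation: float = 3.0
    r3: float = 1e3
    r4: float = 1e5
    r5: float = 1e3
    c: float = 470e-12
    gain: float = 2.0
    diode_drop: float = 0.6
    rail_low: float = 0.0
    rail_high: float = 5.0
    prop_delay: float = 15e-9
    variant: str = "classic"

    def __post_init__(self) -> None:
        for name in ("r3", "r4", "r5", "c", "diode_drop"):
            if not getattr(self, name) > 0:
                raise ValueError(f"DetectorComponents.{name} must be positive")
        if not self.gain >= 1:
            raise ValueError(f"gain must be >= 1, got {self.gain!r}")
        if not self.rail_high > self.rail_low:
            raise ValueError("rail_high must exceed rail_low")
        if self.prop_delay < 0:
            raise ValueError("prop_delay must be non-negative")
        if self.variant not in ("classic", "wideband"):
            raise ValueError(f"variant must be 'classic' or 'wideband', got {self.variant!r}")


DEFAULT_COMPONENTS = DetectorComponents()


def divider(v_in: float, attenuation: float = 3.0) -> float:
    """Voltage-divider attenuation: ``V_a = V_in / attenuation`` (same unit in/out)."""
    if not attenuation >= 1:
        raise ValueError(f"attenuation must be >= 1, got {attenuation!r}")
    return v_in / attenuation


def gain_condition(r3: float, r5: float) -> float:
    """The amplifier gain ``G = 1 + R5/R3`` nulling the held-voltage term.

    Solves ``-1/R3 + (G - 1)/R5 = 0``, the unique gain for which the
    wideband charging current is independent of the capacitor voltage.
    """
    if not (r3 > 0 and r5 > 0):
        raise ValueError("resistances must be positive")
    return 1.0 + r5 / r3


def charging_current(v_cap: float, comp: DetectorComponents) -> float:
    """Capacitor charging current (A) while the comparator output is high.

    The diode blocks reverse flow, so the returned current is clamped at
    zero once the drive can no longer forward-bias it.
    """
    rail = comp.rail_high
    vd = comp.diode_drop
    if comp.variant == "classic":
        current = (rail - 2.0 * vd - v_cap) / comp.r3
    else:
        current = (rail - 2.0 * vd) / comp.r3 - 2.0 * vd / comp.r5 + v_cap * (
            -1.0 / comp.r3 + (comp.gain - 1.0) / comp.r5
        )
    return max(current, 0.0)


@dataclass(frozen=True)
class SignalSpec:
    """Amplitude-modulated sinusoid: ``A(t) sin(2 pi f t)``.

    ``amplitude`` is the peak voltage after the divider (6 Vpp input means
    ``amplitude = 3``). An optional step changes the peak to
    ``amplitude_after`` at ``step_time``.
    """

    frequency: float
    amplitude: float
    step_time: float | None = None
    amplitude_after: float | None = None

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError("carrier frequency must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if (self.step_time is None) != (self.amplitude_after is None):
            raise ValueError("step_time and amplitude_after must be given together")

    def envelope(self, t: np.ndarray) -> np.ndarray:
        if self.step_time is None:
            return np.full_like(t, self.amplitude)
        return np.where(t < self.step_time, self.amplitude, self.amplitude_after)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.envelope(t) * np.sin(2.0 * math.pi * self.frequency * t)


@dataclass(frozen=True)
class DetectorTrace:
    """Simulated time series: input, held capacitor voltage, comparator state."""

    time: np.ndarray
    v_in: np.ndarray
    v_cap: np.ndarray
    comp_state: np.ndarray
    dt: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.time,
                "v_a": self.v_in,
                "v_c": self.v_cap,
                "comp_state": self.comp_state.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False, float_format="%.8g")


def simulate(
    signal: SignalSpec | Callable[[np.ndarray], np.ndarray],
    comp: DetectorComponents = DEFAULT_COMPONENTS,
    duration: float = 200e-6,
    dt: float | None = None,
    v_cap0: float = 0.0,
) -> DetectorTrace:
    """Fixed-step simulation of the detector.

    The comparator output follows the sign of ``V_a - V_c`` with inertial
    propagation delay ``t_pd`` (states shorter than ``t_pd`` are swallowed;
    see module docstring). While the output is high the capacitor charges
    with :func:`charging_current` and always bleeds through ``R4``; while
    low, the diode blocks any discharge path except ``R4``.

    ``dt`` defaults to 1/(100 * carrier) for a :class:`SignalSpec`; an
    explicit ``dt`` coarser than 1/(50 * carrier) is rejected. Arbitrary
    callables (e.g. DC levels) may be passed with an explicit ``dt``.
    """
    if isinstance(signal, SignalSpec):
        limit = 1.0 / (50.0 * signal.frequency)
        if dt is None:
            dt = 1.0 / (100.0 * signal.frequency)
        elif dt > limit:
            raise ValueError(
                f"dt = {dt:.3e} s is too coarse for a {signal.frequency:.3e} Hz carrier "
                f"(need dt <= {limit:.3e} s)"
            )
    elif dt is None:
        raise ValueError("an explicit dt is required for a callable signal")

    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    v_in = np.asarray(signal(t), dtype=float)

    v_cap = np.empty(n + 1)
    state_arr = np.zeros(n + 1, dtype=bool)
    v_cap[0] = v_cap0

    hold = int(math.ceil(comp.prop_delay / dt)) if comp.prop_delay > 0 else 0
    leak_rate = 1.0 / (comp.r4 * comp.c)
    inv_c = 1.0 / comp.c
    rail_high = comp.rail_high
    rail_low = comp.rail_low
    vd = comp.diode_drop
    classic = comp.variant == "classic"
    if not classic:
        base_current = (rail_high - 2.0 * vd) / comp.r3 - 2.0 * vd / comp.r5
        slope = -1.0 / comp.r3 + (comp.gain - 1.0) / comp.r5

    state = False
    run = 0
    vc = v_cap0
    vi = v_in  # local alias for speed
    for i in range(n):
        raw = vi[i] > vc
        if raw != state:
            run += 1
            if run >= hold or hold == 0:
                state = raw
                run = 0
        else:
            run = 0
        if state:
            if classic:
                current = (rail_high - 2.0 * vd - vc) / comp.r3
            else:
                current = base_current + slope * vc
            if current < 0.0:
                current = 0.0
            dv = current * inv_c - vc * leak_rate
        else:
            dv = -vc * leak_rate
        vc += dv * dt
        if vc > rail_high:
            vc = rail_high
        elif vc < rail_low:
            vc = rail_low
        v_cap[i + 1] = vc
        state_arr[i + 1] = state

    return DetectorTrace(time=t, v_in=v_in, v_cap=v_cap, comp_state=state_arr, dt=dt)


def steady_state_error(
    trace: DetectorTrace,
    true_amplitude: float,
    tail_fraction: float = 0.10,
    drift_tolerance: float = 1e-3,
) -> float:
    """Relative envelope-tracking error at steady state (percent).

    ``(true_amplitude - mean V_c over the last tail_fraction) / true_amplitude * 100``.
    Raises :class:`NotConvergedError` if the means of the last two
    half-tails differ by more than ``drift_tolerance`` relative to the
    amplitude (the trace is still slewing).
    """
    if not true_amplitude > 0:
        raise ValueError("true_amplitude must be positive")
    n = trace.v_cap.size
    tail = int(n * tail_fraction)
    if tail < 4:
        raise NotConvergedError("trace too short to assess steady state")
    recent = trace.v_cap[-tail:]
    half = tail // 2
    drift = abs(float(recent[:half].mean()) - float(recent[half:].mean())) / true_amplitude
    if drift > drift_tolerance:
        raise NotConvergedError(
            f"trace still drifting: tail means differ by {drift:.2e} (> {drift_tolerance:.0e}) "
            "relative to the amplitude"
        )
    return (true_amplitude - float(recent.mean())) / true_amplitude * 100.0


def downward_lag_estimate(
    comp: DetectorComponents, old_peak: float, new_peak: float, settle_fraction: float = 0.05
) -> float:
    """Closed-form downward tracking lag, ``R4 C ln(old / ((1+frac) new))``.

    After a downward amplitude step the comparator stays low and ``V_c``
    decays through ``R4`` alone, so the time to come within
    ``settle_fraction`` of the new peak is a pure RC expression.
    """
    if not (old_peak > new_peak > 0):
        raise ValueError("need old_peak > new_peak > 0 for a downward step")
    return comp.r4 * comp.c * math.log(old_peak / ((1.0 + settle_fraction) * new_peak))


def tracking_lag(
    comp: DetectorComponents,
    step: SignalSpec,
    settle_fraction: float = 0.05,
    settle_duration: float | None = None,
    dt: float | None = None,
) -> float:
    """Simulated time for ``V_c`` to settle within ``settle_fraction`` of a new peak.

    ``step`` must carry an amplitude step. The lag is the time from the step
    instant to the first sample with
    ``|V_c - A_new| <= settle_fraction * A_new``. For downward steps this is
    the ``R4``-limited case and agrees with :func:`downward_lag_estimate`.
    """
    if step.step_time is None:
        raise ValueError("step signal must define step_time / amplitude_after")
    new_peak = step.amplitude_after
    if settle_duration is None:
        # generous window: several R4C constants past the closed-form estimate
        settle_duration = 4.0 * comp.r4 * comp.c + 20e-6
    duration = step.step_time + settle_duration
    trace = simulate(step, comp, duration=duration, dt=dt)
    candidates = (trace.time >= step.step_time) & (
        np.abs(trace.v_cap - new_peak) <= settle_fraction * new_peak
    )
    if not candidates.any():
        raise NotConvergedError("capacitor voltage never reached the settle band")
    idx = int(np.argmax(candidates))
    return float(trace.time[idx] - step.step_time)
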