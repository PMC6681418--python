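"""Layered resonant cavity and the piezo's electrical voltage response.

The half-wave resonance condition ties the cavity height ``h`` to the drive:
``f_res = n * v / (2 h)`` for harmonic order ``n``. Detuning away from
``f_res`` costs pressure amplitude through a Lorentzian set by the quality
factor ``Q``:

    p0(f) = p0_max / sqrt(1 + (2 Q (f - f_res) / f_res)^2)

so the half-power points sit at ``f_res * (1 +/- 1/(2Q))``.

The piezo's measured output voltage is modelled phenomenologically as a dip
riding on a baseline, the dip tracking the stored acoustic energy
(``p0^2``):

    V(f) = V_base - dV * (p0(f)/p0_max)^2 + noise

This is deliberately not a Butterworth-Van Dyke equivalent circuit: the
voltage minimum is used only as a resonance marker, and the dip location is
the only feature the instrument data constrain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .media import Medium, sound_speed

__all__ = [
    "ResonatorCavity",
    "PiezoResponse",
    "ScanTrace",
    "resonant_frequency",
    "tune_height",
    "pressure_amplitude",
    "output_voltage",
    "scan",
    "make_instrument",
    "DipFit",
    "fit_dip",
]

#: Number of independent voltage samples averaged per second of dwell.
SAMPLES_PER_SECOND = 100.0


@dataclass(frozen=True)
class ResonatorCavity:
    """Fluid-layer cavity: height, harmonic order, quality factor, peak pressure.

    ``height`` is the fluid layer thickness (m); the half-wave condition
    places the ``n``-th resonance at ``n v / (2 h)``. ``quality_factor``
    sets the sharpness of the Lorentzian response; glass-clad cavities are
    high-Q (default 1000). ``peak_pressure`` is the standing-wave pressure
    amplitude attained exactly on resonance (Pa).
    """

    height: float
    harmonic: int = 1
    quality_factor: float = 1000.0
    peak_pressure: float = 0.5e6

    def __post_init__(self) -> None:
        if not (self.height > 0 and math.isfinite(self.height)):
            raise ValueError(f"cavity height must be positive, got {self.height!r}")
        if not (isinstance(self.harmonic, int) and self.harmonic >= 1):
            raise ValueError(f"harmonic order must be a positive integer, got {self.harmonic!r}")
        if not self.quality_factor >= 1:
            raise ValueError(f"quality factor must be >= 1, got {self.quality_factor!r}")
        if not self.peak_pressure > 0:
            raise ValueError(f"peak pressure must be positive, got {self.peak_pressure!r}")


@dataclass(frozen=True)
class PiezoResponse:
    """Electrical response of the transducer around resonance.

    ``baseline`` is the off-resonance output voltage (Vpp); ``dip_depth`` the
    depth of the minimum at resonance (Vpp); ``noise_sigma`` the standard
    deviation of a single voltage sample (V). The dip centre is locked to the
    fluid-cavity resonance (the instrument cannot separate the piezo's own
    series resonance from the cavity's, so the model equates them).
    """

    baseline: float = 2.0
    dip_depth: float = 0.5
    noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.dip_depth < self.baseline):
            raise ValueError(
                f"need 0 < dip_depth < baseline, got dip_depth={self.dip_depth!r}, baseline={self.baseline!r}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be non-negative, got {self.noise_sigma!r}")


def resonant_frequency(cavity: ResonatorCavity, medium: Medium) -> float:
    """Half-wave resonance ``f_res = n v / (2 h)`` (Hz)."""
    return cavity.harmonic * sound_speed(medium) / (2.0 * cavity.height)


def tune_height(target_frequency: float, medium: Medium, harmonic: int = 1) -> float:
    """Cavity height (m) placing the ``harmonic``-th resonance at ``target_frequency``."""
    if not target_frequency > 0:
        raise ValueError(f"target frequency must be positive, got {target_frequency!r}")
    return harmonic * sound_speed(medium) / (2.0 * target_frequency)


def pressure_amplitude(cavity: ResonatorCavity, medium: Medium, frequency: float) -> float:
    """Standing-wave pressure amplitude at drive ``frequency`` (Pa).

    Lorentzian in the detuning: maximal (``peak_pressure``) exactly at
    resonance, and even in ``f - f_res``.
    """
    if not frequency > 0:
        raise ValueError(f"frequency must be positive, got {frequency!r}")
    f_res = resonant_frequency(cavity, medium)
    detune = 2.0 * cavity.quality_factor * (frequency - f_res) / f_res
    return cavity.peak_pressure / math.sqrt(1.0 + detune * detune)


def output_voltage(
    piezo: PiezoResponse,
    cavity: ResonatorCavity,
    medium: Medium,
    frequency: float,
    rng: np.random.Generator | int | None = None,
    n_samples: int = 1,
) -> float:
    """One dwell-averaged piezo output-voltage reading at ``frequency`` (Vpp).

    ``n_samples`` independent Gaussian-noise samples are averaged (the mean
    of the additive noise over a dwell), so longer dwells give quieter
    readings. ``rng=None`` with a nonzero ``noise_sigma`` draws from a fresh
    generator; pass a seeded generator for reproducibility.
    """
    p_rel = pressure_amplitude(cavity, medium, frequency) / cavity.peak_pressure
    clean = piezo.baseline - piezo.dip_depth * p_rel * p_rel
    if piezo.noise_sigma == 0:
        return clean
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return clean + float(np.mean(gen.normal(0.0, piezo.noise_sigma, size=max(1, n_samples))))


@dataclass(frozen=True)
class ScanTrace:
    """Ordered (frequency, mean output voltage) pairs from one scan."""

    frequencies: tuple
    voltages: tuple
    dwell: float
    medium_label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        if f.size == 0 or f.size != v.size:
            raise ValueError("frequencies and voltages must be equal-length and non-empty")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(v > 0):
            raise ValueError("voltages must be positive")

    @property
    def argmin_frequency(self) -> float:
        """Frequency of the lowest voltage; ties resolve to the lower frequency."""
        return float(self.frequencies[int(np.argmin(self.voltages))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": np.asarray(self.frequencies, dtype=float),
                "voltage_vpp": np.asarray(self.voltages, dtype=float),
                "dwell_s": self.dwell,
            }
        )

    def to_csv(self, path) -> None:
        """Write the trace as CSV with a JSON metadata sidecar (<path>.meta.json)."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps({"medium_label": self.medium_label, "seed": self.seed, "dwell_s": self.dwell})
            + "\n"
        )

    @classmethod
    def from_csv(cls, path) -> "ScanTrace":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            frequencies=tuple(frame["frequency_hz"]),
            voltages=tuple(frame["voltage_vpp"]),
            dwell=float(frame["dwell_s"].iloc[0]),
            medium_label=meta.get("medium_label", ""),
            seed=meta.get("seed"),
        )


def scan(
    piezo: PiezoResponse,
    cavity: ResonatorCavity,
    medium: Medium,
    grid: Sequence[float],
    dwell: float = 0.1,
    seed: int | None = None,
) -> ScanTrace:
    """Sweep the drive over ``grid``, one dwell-averaged voltage per point.

    The dwell sets how many noise samples are averaged
    (``SAMPLES_PER_SECOND * dwell``); identical seeds give identical traces.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("scan grid must be non-empty")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("scan grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    n_samples = max(1, int(round(SAMPLES_PER_SECOND * dwell)))
    voltages = [
        output_voltage(piezo, cavity, medium, f, rng=rng, n_samples=n_samples) for f in grid
    ]
    return ScanTrace(
        frequencies=tuple(grid),
        voltages=tuple(voltages),
        dwell=dwell,
        medium_label=medium.label,
        seed=seed,
    )


def make_instrument(
    piezo: PiezoResponse,
    cavity: ResonatorCavity,
    medium: Medium,
    dwell: float = 0.1,
    seed: int | None = None,
) -> Callable[[float], float]:
    """A callable ``frequency -> dwell-averaged voltage`` closing over one RNG.

    This is the interface the feedback controller drives; successive calls
    consume the same seeded random stream, so a whole session is reproducible
    from its seed.
    """
    rng = np.random.default_rng(seed)
    n_samples = max(1, int(round(SAMPLES_PER_SECOND * dwell)))

    def instrument(frequency: float) -> float:
        return output_voltage(piezo, cavity, medium, frequency, rng=rng, n_samples=n_samples)

    return instrument


@dataclass(frozen=True)
class DipFit:
    """Result of fitting the Lorentzian voltage dip to a scan."""

    resonant_frequency: float
    quality_factor: float
    baseline: float
    dip_depth: float


def fit_dip(trace: ScanTrace) -> DipFit:
    """Least-squares fit of ``V(f) = V_base - dV / (1 + (2Q (f-f0)/f0)^2)``.

    Initialised from the trace's argmin and span; used to recover ``Q`` and
    the dip centre from measured (or simulated) scans.
    """
    f = np.asarray(trace.frequencies, dtype=float)
    v = np.asarray(trace.voltages, dtype=float)

    def model(freq, f0, q, base, depth):
        d = 2.0 * q * (freq - f0) / f0
        return base - depth / (1.0 + d * d)

    f0_guess = trace.argmin_frequency
    base_guess = float(np.max(v))
    depth_guess = float(np.max(v) - np.min(v))
    q_guess = 2.0 * f0_guess / max(f[-1] - f[0], 1.0)
    popt, _ = curve_fit(
        model,
        f,
        v,
        p0=[f0_guess, q_guess, base_guess, max(depth_guess, 1e-6)],
        maxfev=20000,
    )
    return DipFit(
        resonant_frequency=float(popt[0]),
        quality_factor=abs(float(popt[1])),
        baseline=float(popt[2]),
        dip_depth=float(popt[3]),
    )
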