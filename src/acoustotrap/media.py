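"""Fluids, particles and the acoustic material properties that set resonance.

The standing-wave trap is governed by three material relations:

* the speed of sound in the suspending fluid, ``v = 1/sqrt(beta * rho)``
  (``beta`` is the isothermal compressibility in 1/Pa, i.e. the reciprocal
  of the bulk modulus);
* the wavelength of the drive, ``lambda = v / f``;
* the acoustic contrast factor ``phi`` of a particle relative to the fluid,

  ``phi = (5 rho_c - 2 rho_w) / (2 rho_c + rho_w) - beta_c / beta_w``

  whose sign decides whether particles migrate to pressure nodes
  (``phi > 0``, the case for cells and polystyrene beads in water) or to
  antinodes (``phi < 0``).

Everything here is in SI units; frequencies appear in MHz only at the
reporting/CLI boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "Medium",
    "ParticleSpec",
    "WATER",
    "SERUM",
    "POLYSTYRENE_BEAD",
    "sound_speed",
    "wavelength",
    "wavenumber",
    "contrast_factor",
    "glycerol_medium",
    "lysate_medium",
    "fit_lysate_sensitivity",
    "DEFAULT_LYSATE_SENSITIVITY",
    "scaled_sound_speed",
    "resolve_medium",
]


@dataclass(frozen=True)
class Medium:
    """A Newtonian fluid phase characterised by density, compressibility, viscosity.

    Parameters
    ----------
    density : float
        Mass density ``rho`` in kg/m^3.
    compressibility : float
        Isothermal compressibility ``beta`` in 1/Pa (reciprocal bulk modulus).
    viscosity : float
        Dynamic viscosity ``mu`` in Pa*s (used for Stokes drag).
    label : str
        Free-text tag carried into traces and logs.
    """

    density: float
    compressibility: float
    viscosity: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("density", "compressibility", "viscosity"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"Medium.{name} must be positive and finite, got {value!r}")

    @property
    def sound_speed(self) -> float:
        """Speed of sound ``1/sqrt(beta * rho)`` in m/s."""
        return 1.0 / math.sqrt(self.compressibility * self.density)


@dataclass(frozen=True)
class ParticleSpec:
    """A trapped object: sphere of given radius, density and compressibility."""

    radius: float
    density: float
    compressibility: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("radius", "density", "compressibility"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"ParticleSpec.{name} must be positive and finite, got {value!r}")

    @property
    def volume(self) -> float:
        """Sphere volume ``(4/3) pi a^3`` in m^3."""
        return 4.0 / 3.0 * math.pi * self.radius**3


def sound_speed(medium: Medium) -> float:
    """Speed of sound in a fluid, ``v = 1/sqrt(beta * rho)`` (m/s)."""
    return medium.sound_speed


def wavelength(speed: float, frequency: float) -> float:
    """Acoustic wavelength ``lambda = c / f`` (m)."""
    if not (speed > 0 and math.isfinite(speed)):
        raise ValueError(f"speed must be positive, got {speed!r}")
    if not (frequency > 0 and math.isfinite(frequency)):
        raise ValueError(f"frequency must be positive, got {frequency!r}")
    return speed / frequency


def wavenumber(speed: float, frequency: float) -> float:
    """Angular wavenumber ``k = 2 pi / lambda`` (rad/m)."""
    return 2.0 * math.pi / wavelength(speed, frequency)


def contrast_factor(particle: ParticleSpec, medium: Medium) -> float:
    """Acoustic contrast factor ``phi`` (dimensionless).

    ``phi = (5 rho_c - 2 rho_w)/(2 rho_c + rho_w) - beta_c/beta_w``.
    Positive for dense, stiff particles (cells, polystyrene) which migrate to
    pressure nodes; negative for bubble-like particles.
    """
    rho_c, rho_w = particle.density, medium.density
    monopole = particle.compressibility / medium.compressibility
    dipole = (5.0 * rho_c - 2.0 * rho_w) / (2.0 * rho_c + rho_w)
    return dipole - monopole


# Reference presets at 25 degC. Compressibility is back-computed from the
# tabulated sound speed as beta = 1/(rho v^2) so the preset reproduces the
# tabulated speed exactly.
def _medium_from_speed(density: float, speed: float, viscosity: float, label: str) -> Medium:
    return Medium(
        density=density,
        compressibility=1.0 / (density * speed**2),
        viscosity=viscosity,
        label=label,
    )


WATER = _medium_from_speed(997.0, 1497.0, 8.9e-4, "water25C")

#: Serum surrogate: sound speed set so a chip tuned to 7.58 MHz in water
#: shifts its voltage minimum to 7.70 MHz (1497.0 * 7.70 / 7.58 m/s).
SERUM = _medium_from_speed(1024.0, 1520.70, 1.4e-3, "serum")

#: 10 um-diameter polystyrene bead (the fluorescent scanning-solution beads).
POLYSTYRENE_BEAD = ParticleSpec(radius=5e-6, density=1050.0, compressibility=2.16e-10, label="ps10um")

# Glycerol-water mixtures at 25 degC, by glycerol mass fraction.
# Columns: density (kg/m^3), sound speed (m/s), viscosity (Pa*s).
_GLYCEROL_FRACTIONS = np.array([0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30])
_GLYCEROL_DENSITY = np.array([997.0, 1008.7, 1020.8, 1033.0, 1045.4, 1058.0, 1070.5])
_GLYCEROL_SPEED = np.array([1497.0, 1508.5, 1521.0, 1534.0, 1547.5, 1561.5, 1576.0])
_GLYCEROL_VISCOSITY = np.array([0.89e-3, 1.01e-3, 1.15e-3, 1.33e-3, 1.54e-3, 1.81e-3, 2.16e-3])

_glycerol_density = PchipInterpolator(_GLYCEROL_FRACTIONS, _GLYCEROL_DENSITY)
_glycerol_speed = PchipInterpolator(_GLYCEROL_FRACTIONS, _GLYCEROL_SPEED)
_glycerol_viscosity = PchipInterpolator(_GLYCEROL_FRACTIONS, _GLYCEROL_VISCOSITY)


def glycerol_medium(mass_fraction: float) -> Medium:
    """Glycerol-water mixture by glycerol mass fraction in [0, 0.3].

    Interpolates a 25 degC literature table with a monotone (PCHIP) scheme, so
    the sound speed is strictly increasing in the fraction. Beyond 30%
    glycerol the acoustic trap no longer holds particles, so the range stops
    there.
    """
    if not (0.0 <= mass_fraction <= 0.30):
        raise ValueError(
            f"glycerol mass fraction must lie in [0, 0.3] (trapping fails beyond 30%), got {mass_fraction!r}"
        )
    if mass_fraction == 0.0:
        return WATER
    return _medium_from_speed(
        float(_glycerol_density(mass_fraction)),
        float(_glycerol_speed(mass_fraction)),
        float(_glycerol_viscosity(mass_fraction)),
        f"glycerol:{mass_fraction:g}",
    )


#: Default fractional sound-speed shift per lysed cell, calibrated by
#: least squares to the epithelial-lysate series (7.76 MHz baseline;
#: 75k and 100k cells -> 7.78 MHz, 150k cells -> 7.80 MHz).
DEFAULT_LYSATE_SENSITIVITY = 3.211086699340871e-08


def lysate_medium(
    cell_count: float,
    base: Medium = WATER,
    sensitivity: float = DEFAULT_LYSATE_SENSITIVITY,
) -> Medium:
    """Surrogate for a lysed-cell suspension of ``cell_count`` ruptured cells.

    Cell lysis releases cytoplasmic content that stiffens the medium; here
    this is a one-parameter linear model on the sound speed,
    ``v -> v * (1 + s * cells)``, realised by scaling the compressibility.
    ``sensitivity`` defaults to the constant calibrated against the observed
    resonance shifts of the epithelial-cell series; use
    :func:`fit_lysate_sensitivity` to recalibrate from new
    (count, resonance) observations.
    """
    if cell_count < 0:
        raise ValueError(f"cell_count must be non-negative, got {cell_count!r}")
    if cell_count == 0:
        return base
    factor = 1.0 + sensitivity * cell_count
    return replace(
        base,
        compressibility=base.compressibility / factor**2,
        label=f"lysate:{cell_count:g}",
    )


def fit_lysate_sensitivity(
    pairs: "list[tuple[float, float]]", baseline_frequency: float
) -> float:
    """Least-squares fit of the lysate sensitivity constant.

    Parameters
    ----------
    pairs
        Observed ``(cell_count, resonance_frequency)`` pairs (any consistent
        frequency unit).
    baseline_frequency
        Resonance of the unperturbed base medium in the same unit.

    Returns
    -------
    float
        ``s`` such that ``f(cells) = baseline * (1 + s * cells)``, fit through
        the origin: resonance scales with sound speed at fixed cavity height,
        so the fractional frequency shift equals the fractional speed shift.
    """
    counts = np.asarray([c for c, _ in pairs], dtype=float)
    shifts = np.asarray([f for _, f in pairs], dtype=float) / baseline_frequency - 1.0
    if counts.size == 0 or not np.any(counts > 0):
        raise ValueError("need at least one pair with a positive cell count")
    return float(counts @ shifts / (counts @ counts))


def scaled_sound_speed(base: Medium, factor: float, label: str | None = None) -> Medium:
    """Return ``base`` with its sound speed multiplied by ``factor``.

    Density and viscosity are kept; the compressibility is divided by
    ``factor**2``. This is the generic surrogate for a sample whose only
    characterised effect is a fractional resonance shift.
    """
    if not (factor > 0 and math.isfinite(factor)):
        raise ValueError(f"factor must be positive, got {factor!r}")
    return replace(
        base,
        compressibility=base.compressibility / factor**2,
        label=label if label is not None else f"{base.label}*{factor:g}",
    )


def resolve_medium(spec) -> Medium:
    """Resolve a medium given as a :class:`Medium`, preset name, or mapping.

    Accepted strings: ``"water25C"``, ``"serum"``, ``"glycerol:<fraction>"``,
    ``"lysate:<cells>"``. Mappings may give ``{preset: ..., sound_speed_scale: ...}``
    or explicit ``{density, compressibility, viscosity}``.
    """
    if isinstance(spec, Medium):
        return spec
    if isinstance(spec, str):
        if spec == "water25C":
            return WATER
        if spec == "serum":
            return SERUM
        if spec.startswith("glycerol:"):
            return glycerol_medium(float(spec.split(":", 1)[1]))
        if spec.startswith("lysate:"):
            return lysate_medium(float(spec.split(":", 1)[1]))
        raise ValueError(f"unknown medium preset {spec!r}")
    if isinstance(spec, dict):
        spec = dict(spec)
        if "preset" in spec:
            medium = resolve_medium(spec.pop("preset"))
            if "cell_count" in spec:
                medium = lysate_medium(float(spec.pop("cell_count")), base=medium)
            if "sound_speed_scale" in spec:
                medium = scaled_sound_speed(medium, float(spec.pop("sound_speed_scale")))
            if spec:
                raise ValueError(f"unrecognised medium keys: {sorted(spec)}")
            return medium
        return Medium(
            density=float(spec["density"]),
            compressibility=float(spec["compressibility"]),
            viscosity=float(spec["viscosity"]),
            label=str(spec.get("label", "")),
        )
    raise TypeError(f"cannot interpret {spec!r} as a medium")
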