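"""Scan-and-lock feedback controller for the trapping frequency.

Protocol, mirroring how the instrument is operated:

1. **Chip scan** — with the bead/water scanning solution flowing, sweep a
   short grid (eight points covering 0.14 MHz by default) and take the
   voltage argmin as the chip-specific optimal frequency (set by the cavity
   height of that particular chip).
2. **Sample tracking** — with the sample flowing, step the drive *upward*
   from the chip frequency by 0.01 MHz every 2 s. Each dwell-averaged
   voltage is compared to the running minimum; the first step whose voltage
   rises above the running minimum by more than ``eta * sigma`` solidifies
   the minimum, the scan is abandoned, and the running-minimum frequency is
   locked for the rest of the trapping.
3. **Hold** — the lock is held while the wash buffer clears debris.

``sigma`` is the dwell-averaged voltage noise, estimated from repeated
samples at the start frequency; ``eta = 2`` keeps a single noise excursion
from aborting the scan early while still stopping one step past a genuine
minimum in the noiseless limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .media import Medium
from .resonator import (
    PiezoResponse,
    ResonatorCavity,
    ScanTrace,
    make_instrument,
)

__all__ = [
    "ScanConfig",
    "TrackConfig",
    "LockResult",
    "SessionReport",
    "InstrumentError",
    "chip_scan",
    "track_sample",
    "run_protocol",
]


class InstrumentError(RuntimeError):
    """Raised when the instrument returns a non-finite voltage."""


@dataclass(frozen=True)
class ScanConfig:
    """Chip-scan grid: ``points`` frequencies from ``start`` covering ``span``."""

    start: float
    points: int = 8
    span: float = 0.14e6
    step: float | None = None
    dwell: float = 0.1

    def __post_init__(self) -> None:
        if self.points < 2:
            raise ValueError("a scan needs at least 2 points")
        if self.step is None and not self.span > 0:
            raise ValueError("span must be positive")
        if self.step is not None and not self.step > 0:
            raise ValueError("step must be positive")
        if not self.dwell > 0:
            raise ValueError("dwell must be positive")

    @property
    def grid_step(self) -> float:
        return self.step if self.step is not None else self.span / (self.points - 1)

    @property
    def grid(self) -> np.ndarray:
        return self.start + self.grid_step * np.arange(self.points)


@dataclass(frozen=True)
class TrackConfig:
    """Upward-tracking parameters: step, dwell, rise threshold, step budget."""

    step: float = 0.01e6
    dwell: float = 2.0
    rise_threshold: float = 2.0  # eta, in multiples of the voltage noise sigma
    max_steps: int = 50
    sigma_samples: int = 5
    consecutive_rises: int = 1
    bidirectional: bool = False

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError("tracking step must be positive")
        if not self.dwell > 0:
            raise ValueError("dwell must be positive")
        if self.rise_threshold < 0:
            raise ValueError("rise threshold must be non-negative")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.consecutive_rises < 1:
            raise ValueError("consecutive_rises must be >= 1")


@dataclass(frozen=True)
class LockResult:
    """Outcome of a tracking run: the locked frequency and the decision log."""

    locked_frequency: float
    visited: tuple  # ordered (frequency, voltage) pairs
    stop_reason: str  # "rise-detected" | "max-steps" | "scan-exhausted"
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        freqs = [f for f, _ in self.visited]
        if self.locked_frequency not in freqs:
            raise ValueError("locked frequency must be one of the visited frequencies")


def _read(instrument: Callable[[float], float], frequency: float) -> float:
    voltage = float(instrument(frequency))
    if not math.isfinite(voltage):
        raise InstrumentError(f"instrument returned non-finite voltage at {frequency!r} Hz")
    return voltage


def chip_scan(
    scan: ScanConfig, instrument: Callable[[float], float]
) -> tuple[float, ScanTrace]:
    """Sweep the scan grid and return (argmin frequency, full trace).

    Ties resolve toward the lower frequency. The instrument is any callable
    ``frequency -> dwell-averaged voltage`` (see
    :func:`acoustotrap.resonator.make_instrument`).
    """
    grid = scan.grid
    voltages = [_read(instrument, f) for f in grid]
    trace = ScanTrace(
        frequencies=tuple(grid), voltages=tuple(voltages), dwell=scan.dwell
    )
    return trace.argmin_frequency, trace


def track_sample(
    start: float, track: TrackConfig, instrument: Callable[[float], float]
) -> LockResult:
    """Step upward from ``start``, lock the running minimum at the first rise.

    At each new frequency the dwell-averaged voltage is compared to the
    running minimum; a reading exceeding it by more than
    ``rise_threshold * sigma`` (for ``consecutive_rises`` steps in a row)
    stops the scan and locks the running-minimum frequency. If the very
    first step rises, the start frequency itself is locked. If ``max_steps``
    is exhausted the best frequency so far is returned with stop reason
    ``"max-steps"``.
    """
    if not start > 0:
        raise ValueError("start frequency must be positive")

    # Estimate the dwell-averaged noise from repeated samples at the start.
    samples = [_read(instrument, start) for _ in range(max(1, track.sigma_samples))]
    sigma = float(np.std(samples)) if len(samples) > 1 else 0.0
    threshold = track.rise_threshold * sigma

    best_f, best_v = start, float(np.mean(samples))
    visited = [(start, best_v)]
    rises = 0
    for i in range(1, track.max_steps + 1):
        frequency = start + i * track.step
        voltage = _read(instrument, frequency)
        visited.append((frequency, voltage))
        if voltage > best_v + threshold:
            rises += 1
            if rises >= track.consecutive_rises:
                return LockResult(best_f, tuple(visited), "rise-detected", sigma)
        else:
            rises = 0
            if voltage < best_v:
                best_f, best_v = frequency, voltage
    return LockResult(best_f, tuple(visited), "max-steps", sigma)


@dataclass(frozen=True)
class SessionReport:
    """Full log of one chip-scan + sample-track + hold session."""

    chip_frequency: float
    locked_frequency: float
    hold_frequency: float
    scan_trace: ScanTrace
    lock_result: LockResult
    log: tuple  # ordered human-readable event strings

    def summary(self) -> dict:
        return {
            "chip_frequency_hz": self.chip_frequency,
            "locked_frequency_hz": self.locked_frequency,
            "hold_frequency_hz": self.hold_frequency,
            "stop_reason": self.lock_result.stop_reason,
        }


def run_protocol(
    scan: ScanConfig,
    track: TrackConfig,
    media_phases: Sequence[tuple[str, Medium]],
    cavity: ResonatorCavity,
    piezo: PiezoResponse,
    seed: int | None = None,
) -> SessionReport:
    """Execute the full session over an ordered sequence of media phases.

    ``media_phases`` lists ``(phase_name, medium)`` in order; the first
    phase is the bead/water chip scan, the second the sample to track, any
    further phases (wash) hold the lock. Per-phase instruments derive their
    seeds from ``seed`` so the whole session is reproducible.
    """
    if len(media_phases) < 2:
        raise ValueError("protocol needs at least a scan phase and a sample phase")
    log: list[str] = []

    def phase_seed(index: int) -> int | None:
        return None if seed is None else (seed + 1009 * index) % (2**31)

    scan_name, scan_medium = media_phases[0]
    instrument = make_instrument(piezo, cavity, scan_medium, dwell=scan.dwell, seed=phase_seed(0))
    chip_f, trace = chip_scan(scan, instrument)
    log.append(f"phase={scan_name} chip_scan argmin={chip_f / 1e6:.4f} MHz")

    sample_name, sample_medium = media_phases[1]
    instrument = make_instrument(piezo, cavity, sample_medium, dwell=track.dwell, seed=phase_seed(1))
    lock = track_sample(chip_f, track, instrument)
    log.append(
        f"phase={sample_name} track lock={lock.locked_frequency / 1e6:.4f} MHz "
        f"stop={lock.stop_reason}"
    )

    for name, _medium in media_phases[2:]:
        log.append(f"phase={name} holding {lock.locked_frequency / 1e6:.4f} MHz")

    return SessionReport(
        chip_frequency=chip_f,
        locked_frequency=lock.locked_frequency,
        hold_frequency=lock.locked_frequency,
        scan_trace=trace,
        lock_result=lock,
        log=tuple(log),
    )
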