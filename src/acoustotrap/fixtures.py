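"""Seeded scenario generator: every bench experiment as a runnable config.

Each scenario is a YAML file shipped as package data (so users can copy and
edit them) describing a cavity tuned to a target resonance in a named
medium, a piezo response, scan/track settings, and an ordered list of media
phases. :func:`run_scenario` executes the phases against the resonator and
controller modules, optionally writing CSV/JSON/PNG artifacts; with a fixed
seed, re-running reproduces every CSV byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .imaging import best_frequency_by_image, synth_trap_frame, yellow_pixel_count
from .media import Medium, resolve_medium
from .resfinder import LockResult, ScanConfig, TrackConfig, chip_scan, track_sample
from .resonator import (
    PiezoResponse,
    ResonatorCavity,
    ScanTrace,
    make_instrument,
    pressure_amplitude,
    tune_height,
)

__all__ = ["Scenario", "PhaseSpec", "SCENARIO_NAMES", "make_scenario", "run_scenario"]

SCENARIO_NAMES = ("glycerol_series", "ecell_series", "mock_sample", "chip_scan_754")

_MHZ = 1e6


@dataclass(frozen=True)
class PhaseSpec:
    name: str
    medium: Medium
    mode: str  # "scan" | "track" | "hold"
    expected_mhz: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("scan", "track", "hold"):
            raise ValueError(f"unknown phase mode {self.mode!r}")


@dataclass(frozen=True)
class Scenario:
    """A fully-specified session: rig, controller settings and media phases."""

    name: str
    seed: int
    cavity: ResonatorCavity
    piezo: PiezoResponse
    scan: ScanConfig
    track: TrackConfig
    phases: tuple
    imaging: dict | None = None

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("scenario needs at least one phase")

    def phase_seed(self, index: int) -> int:
        return (self.seed + 1009 * index) % (2**31)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "seed": self.seed,
            "cavity": {
                "height_m": self.cavity.height,
                "harmonic": self.cavity.harmonic,
                "quality_factor": self.cavity.quality_factor,
                "peak_pressure_pa": self.cavity.peak_pressure,
            },
            "phases": [
                {"name": p.name, "medium": p.medium.label, "mode": p.mode} for p in self.phases
            ],
        }


def _load_yaml(name: str) -> dict:
    path = resources.files("acoustotrap.scenarios").joinpath(f"{name}.yaml")
    with path.open("r") as handle:
        return yaml.safe_load(handle)


def make_scenario(name: str, seed: int | None = None) -> Scenario:
    """Build a named scenario; ``seed`` overrides the file's default seed.

    Known names: ``glycerol_series`` (water / 5% / 10% glycerol scans on a
    7.58 MHz chip), ``ecell_series`` (lysate surrogates on a 7.76 MHz chip),
    ``mock_sample`` (chip scan at 7.59 MHz then sample tracking to 7.61 MHz),
    ``chip_scan_754`` (single 8-point scan on a 7.54 MHz chip).
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    raw = _load_yaml(name)

    tune = raw["cavity"]["tune"]
    tune_medium = resolve_medium(tune["medium"])
    cavity = ResonatorCavity(
        height=tune_height(float(tune["frequency_mhz"]) * _MHZ, tune_medium),
        quality_factor=float(raw["cavity"].get("quality_factor", 1000.0)),
        peak_pressure=float(raw["cavity"].get("peak_pressure_pa", 0.5e6)),
    )
    piezo = PiezoResponse(
        baseline=float(raw["piezo"]["baseline_vpp"]),
        dip_depth=float(raw["piezo"]["dip_depth_vpp"]),
        noise_sigma=float(raw["piezo"]["noise_sigma_v"]),
    )
    scan = ScanConfig(
        start=float(raw["scan"]["start_mhz"]) * _MHZ,
        points=int(raw["scan"]["points"]),
        span=float(raw["scan"]["span_mhz"]) * _MHZ,
        dwell=float(raw["scan"]["dwell_s"]),
    )
    track = TrackConfig(
        step=float(raw["track"]["step_mhz"]) * _MHZ,
        dwell=float(raw["track"]["dwell_s"]),
        rise_threshold=float(raw["track"]["rise_threshold"]),
        max_steps=int(raw["track"]["max_steps"]),
    )
    phases = tuple(
        PhaseSpec(
            name=p["name"],
            medium=resolve_medium(p["medium"]),
            mode=p["mode"],
            expected_mhz=p.get("expected_mhz"),
        )
        for p in raw["phases"]
    )
    return Scenario(
        name=name,
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        cavity=cavity,
        piezo=piezo,
        scan=scan,
        track=track,
        phases=phases,
        imaging=raw.get("imaging"),
    )


def _render_phase_frames(scenario: Scenario, phase: PhaseSpec, grid, phase_index: int) -> dict:
    """Synthetic trap-site stills keyed by frequency, aggregate area ~ p0^2."""
    cfg = scenario.imaging
    max_area = int(cfg.get("max_area_px", 1600))
    shape = tuple(cfg.get("frame_shape", (160, 160)))
    frames = {}
    for j, frequency in enumerate(grid):
        p_rel = pressure_amplitude(scenario.cavity, phase.medium, frequency) / (
            scenario.cavity.peak_pressure
        )
        area = int(round(max_area * p_rel * p_rel))
        frames[float(frequency)] = synth_trap_frame(
            area, shape=shape, seed=scenario.phase_seed(phase_index) + j
        )
    return frames


def run_scenario(scenario: Scenario, out_dir=None) -> dict:
    """Execute every phase; return (and optionally write) the session artifacts.

    Phase modes: ``scan`` runs a chip scan on the phase medium and reports
    the argmin; ``track`` steps upward from the most recent result;
    ``hold`` keeps the current lock. When the scenario carries an imaging
    block, scan phases also render synthetic trap-site stills and score them
    with the yellow-pixel counter.

    With ``out_dir`` set, writes per-phase ``scan_<phase>.csv`` (+ metadata
    sidecars), ``lock_result.json``, frames as PNG, and ``session.log``.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"scenario": scenario.name, "seed": scenario.seed, "phases": []}
    log: list[str] = [f"scenario={scenario.name} seed={scenario.seed}"]
    current_frequency: float | None = None
    last_lock: LockResult | None = None

    for i, phase in enumerate(scenario.phases):
        entry: dict = {"name": phase.name, "mode": phase.mode, "medium": phase.medium.label}
        seed_i = scenario.phase_seed(i)
        if phase.mode == "scan":
            instrument = make_instrument(
                scenario.piezo, scenario.cavity, phase.medium,
                dwell=scenario.scan.dwell, seed=seed_i,
            )
            frequency, trace = chip_scan(scenario.scan, instrument)
            trace = ScanTrace(
                frequencies=trace.frequencies, voltages=trace.voltages,
                dwell=trace.dwell, medium_label=phase.medium.label, seed=seed_i,
            )
            current_frequency = frequency
            entry["result_frequency_hz"] = frequency
            log.append(f"[{phase.name}] scan argmin {frequency / _MHZ:.4f} MHz")
            if out is not None:
                trace.to_csv(out / f"scan_{phase.name}.csv")
            if scenario.imaging is not None:
                frames = _render_phase_frames(scenario, phase, trace.frequencies, i)
                image_best = best_frequency_by_image(frames)
                entry["image_best_frequency_hz"] = image_best
                entry["yellow_counts"] = {
                    f"{f / _MHZ:.2f}": yellow_pixel_count(frame) for f, frame in frames.items()
                }
                log.append(f"[{phase.name}] image argmax {image_best / _MHZ:.4f} MHz")
                if out is not None:
                    from PIL import Image

                    frame_dir = out / "frames" / phase.name
                    frame_dir.mkdir(parents=True, exist_ok=True)
                    for f, frame in frames.items():
                        Image.fromarray(frame).save(frame_dir / f"{f / _MHZ:.2f}MHz.png")
        elif phase.mode == "track":
            if current_frequency is None:
                raise ValueError(f"phase {phase.name!r}: nothing to track from (no prior scan)")
            instrument = make_instrument(
                scenario.piezo, scenario.cavity, phase.medium,
                dwell=scenario.track.dwell, seed=seed_i,
            )
            last_lock = track_sample(current_frequency, scenario.track, instrument)
            current_frequency = last_lock.locked_frequency
            entry["result_frequency_hz"] = current_frequency
            entry["stop_reason"] = last_lock.stop_reason
            log.append(
                f"[{phase.name}] lock {current_frequency / _MHZ:.4f} MHz"
                f" ({last_lock.stop_reason})"
            )
        else:  # hold
            if current_frequency is None:
                raise ValueError(f"phase {phase.name!r}: nothing to hold (no prior result)")
            entry["result_frequency_hz"] = current_frequency
            log.append(f"[{phase.name}] holding {current_frequency / _MHZ:.4f} MHz")
        report["phases"].append(entry)

    report["final_frequency_hz"] = current_frequency
    if out is not None:
        if last_lock is not None:
            (out / "lock_result.json").write_text(
                json.dumps(
                    {
                        "locked_frequency_hz": last_lock.locked_frequency,
                        "stop_reason": last_lock.stop_reason,
                        "visited": list(map(list, last_lock.visited)),
                    },
                    indent=2,
                )
                + "\n"
            )
        (out / "summary.json").write_text(json.dumps(report, indent=2, default=float) + "\n")
        import datetime

        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        (out / "session.log").write_text(
            "".join(f"{stamp} INFO {line}\n" for line in log)
        )
    return report
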