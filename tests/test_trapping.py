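import math

import numpy as np
import pytest

from acoustotrap import (
    DEFAULT_GEOMETRY,
    ParticleSpec,
    TrapGeometry,
    WATER,
    contrast_factor,
    lateral_trajectory,
    radiation_force,
    sound_speed,
    trapping_efficiency,
    wavelength,
)
from conftest import cavity_at


def hand_force(particle, medium, p0, f, x):
    """Independent literal evaluation of the primary radiation force."""
    lam = sound_speed(medium) / f
    k = 2 * math.pi / lam
    v_p = 4 / 3 * math.pi * particle.radius**3
    phi = (5 * particle.density - 2 * medium.density) / (
        2 * particle.density + medium.density
    ) - particle.compressibility / medium.compressibility
    return -(math.pi * p0**2 * v_p * medium.compressibility / (2 * lam)) * phi * math.sin(2 * k * x)


class TestRadiationForce:
    def test_zero_at_node_and_antinode(self, bead, water):
        lam = wavelength(sound_speed(water), 7.58e6)
        assert radiation_force(bead, water, 0.5e6, 7.58e6, 0.0) == 0.0
        assert radiation_force(bead, water, 0.5e6, 7.58e6, lam / 4) == pytest.approx(0.0, abs=1e-18)

    def test_neutral_particle_feels_nothing(self, water):
        neutral = ParticleSpec(
            radius=5e-6, density=water.density, compressibility=water.compressibility
        )
        xs = np.linspace(-4e-5, 4e-5, 11)
        assert np.allclose(radiation_force(neutral, water, 0.5e6, 7.58e6, xs), 0.0, atol=1e-16)

    def test_matches_independent_hand_evaluation_at_lambda_eighth(self, bead, water):
        lam = wavelength(sound_speed(water), 7.58e6)
        got = float(radiation_force(bead, water, 0.5e6, 7.58e6, lam / 8))
        assert got == pytest.approx(hand_force(bead, water, 0.5e6, 7.58e6, lam / 8), rel=1e-12)
        # regression pin: ~0.27 nN restoring force for a 10 um bead at 0.5 MPa
        assert got == pytest.approx(-2.650e-10, rel=1e-3)

    def test_restores_toward_node_for_positive_contrast(self, bead, water):
        assert contrast_factor(bead, water) > 0
        assert radiation_force(bead, water, 0.5e6, 7.58e6, 1e-5) < 0
        assert radiation_force(bead, water, 0.5e6, 7.58e6, -1e-5) > 0

    def test_periodic_with_half_wavelength(self, bead, water):
        lam = wavelength(sound_speed(water), 7.58e6)
        xs = np.linspace(-lam / 4, lam / 4, 17)
        assert np.allclose(
            radiation_force(bead, water, 0.5e6, 7.58e6, xs),
            radiation_force(bead, water, 0.5e6, 7.58e6, xs + lam / 2),
            rtol=1e-9,
            atol=1e-18,
        )


class TestLateralTrajectory:
    def test_node_is_an_equilibrium(self, bead, water):
        _, x = lateral_trajectory(bead, water, 0.5e6, 7.6e6, 0.0, 0.01)
        assert np.all(x == 0.0)

    def test_positive_contrast_monotonically_approaches_node(self, bead, water):
        _, x = lateral_trajectory(bead, water, 0.5e6, 7.6e6, 3e-5, 0.05)
        assert np.all(np.diff(np.abs(x)) <= 1e-18)
        assert abs(x[-1]) < 1e-7

    def test_negative_contrast_moves_away_from_node(self, water):
        bubble_like = ParticleSpec(radius=5e-6, density=950.0, compressibility=4.5e-9)
        assert contrast_factor(bubble_like, water) < 0
        _, x = lateral_trajectory(bubble_like, water, 0.5e6, 7.6e6, 5e-6, 0.002)
        assert x[-1] > 5e-6

    def test_halving_dt_changes_endpoint_by_under_a_tenth_percent(self, bead, water):
        _, x1 = lateral_trajectory(bead, water, 0.5e6, 7.6e6, 3e-5, 0.01, dt=2e-4)
        _, x2 = lateral_trajectory(bead, water, 0.5e6, 7.6e6, 3e-5, 0.01, dt=1e-4)
        assert abs(x1[-1] - x2[-1]) <= 1e-3 * max(abs(x2[-1]), 1e-9)

    def test_migration_time_scales_inverse_p0_squared(self, bead, water):
        def time_to_1um(p0):
            t, x = lateral_trajectory(bead, water, p0, 7.6e6, 3e-5, 0.2)
            idx = np.argmax(np.abs(x) < 1e-6)
            assert idx > 0
            return t[idx]

        ratio = time_to_1um(0.25e6) / time_to_1um(0.5e6)
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_start_beyond_quarter_wavelength_rejected(self, bead, water):
        lam = wavelength(sound_speed(water), 7.6e6)
        with pytest.raises(ValueError):
            lateral_trajectory(bead, water, 0.5e6, 7.6e6, 0.3 * lam, 0.01)

    def test_tiny_step_euler_oracle_agreement(self, bead, water):
        """RK4 endpoint vs a brute-force explicit-Euler integrator, 10 cases."""
        from acoustotrap.trapping import radiation_force as force

        rng = np.random.default_rng(42)
        lam = wavelength(sound_speed(water), 7.6e6)
        drag = 6 * math.pi * water.viscosity * bead.radius
        for _ in range(10):
            x0 = rng.uniform(-0.9, 0.9) * lam / 4
            p0 = rng.uniform(0.1e6, 0.6e6)
            duration = 0.01
            _, x = lateral_trajectory(bead, water, p0, 7.6e6, x0, duration)
            n = 40000
            dt = duration / n
            xe = x0
            for _ in range(n):
                xe += dt * float(force(bead, water, p0, 7.6e6, xe)) / drag
            scale = max(abs(xe), lam / 4 * 1e-3)
            assert abs(x[-1] - xe) <= 5e-3 * scale


class TestTrapGeometry:
    def test_mean_speed_and_residence(self):
        geom = DEFAULT_GEOMETRY
        # 45 uL/min through 1 mm x 98.75 um -> 7.59 mm/s; 2 mm zone -> 0.263 s
        assert geom.mean_speed == pytest.approx(7.595e-3, rel=1e-3)
        assert geom.residence_time == pytest.approx(0.2633, rel=1e-3)

    def test_volume_per_100ms_step_at_45ul_min(self):
        # flow * dwell arithmetic: 45 uL/min * 0.1 s = 75 nL
        assert DEFAULT_GEOMETRY.volume_per_step(0.1) == pytest.approx(75e-12, rel=1e-9)


class TestTrappingEfficiency:
    def test_negligible_pressure_traps_nothing(self, bead, water):
        cavity = cavity_at(7.6e6, water, pressure=1.0)
        res = trapping_efficiency(bead, 200, DEFAULT_GEOMETRY, cavity, water, 7.6e6, seed=0)
        assert res.efficiency == 0.0

    def test_strong_field_slow_flow_traps_everything(self, bead, water):
        cavity = cavity_at(7.6e6, water, pressure=5e6)
        slow = TrapGeometry(flow_rate=4.5e-9 / 60.0)
        res = trapping_efficiency(bead, 200, slow, cavity, water, 7.6e6, seed=0)
        assert res.efficiency == 1.0

    def test_tenfold_loss_at_50khz_detuning(self, bead, water):
        cavity = cavity_at(7.6e6, water, quality=1000, pressure=0.5e6)
        on = trapping_efficiency(bead, 500, DEFAULT_GEOMETRY, cavity, water, 7.6e6, seed=1)
        off = trapping_efficiency(bead, 500, DEFAULT_GEOMETRY, cavity, water, 7.65e6, seed=1)
        assert off.efficiency > 0
        assert on.efficiency / off.efficiency >= 10.0

    def test_efficiency_even_and_non_increasing_in_detuning(self, bead, water):
        cavity = cavity_at(7.6e6, water)
        detunings = np.linspace(-0.05e6, 0.05e6, 21)
        effs = [
            trapping_efficiency(
                bead, 300, DEFAULT_GEOMETRY, cavity, water, 7.6e6 + d, seed=5
            ).efficiency
            for d in detunings
        ]
        effs = np.array(effs)
        # even up to O(delta/f): the wavelength itself shifts with the drive
        assert np.allclose(effs, effs[::-1], atol=0.02)
        upper = effs[10:]  # delta >= 0
        assert np.all(np.diff(upper) <= 1e-12)

    def test_deterministic_under_fixed_seed(self, bead, water):
        cavity = cavity_at(7.6e6, water)
        a = trapping_efficiency(bead, 100, DEFAULT_GEOMETRY, cavity, water, 7.62e6, seed=9)
        b = trapping_efficiency(bead, 100, DEFAULT_GEOMETRY, cavity, water, 7.62e6, seed=9)
        assert a.efficiency == b.efficiency
        assert np.array_equal(a.x0, b.x0)

    def test_result_frame_and_summary(self, tmp_path, bead, water):
        cavity = cavity_at(7.6e6, water)
        res = trapping_efficiency(bead, 50, DEFAULT_GEOMETRY, cavity, water, 7.6e6, seed=2)
        frame = res.to_frame()
        assert set(frame.columns) == {"particle_id", "x0_m", "outcome", "t_trap_s"}
        assert (frame["outcome"] == "trapped").mean() == res.efficiency
        res.to_csv(tmp_path / "trap.csv")
        assert (tmp_path / "trap.csv").exists()
        assert (tmp_path / "trap.csv.summary.json").exists()
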