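"""Lattice clot: geometry, transport, binding, front measurement."""

import numpy as np
import pytest

from fibrolysis.distributions import EmpiricalDistribution, MicroSummaryPack
from fibrolysis.geometry import BolusSpec
from fibrolysis.kinetics import KineticParameters
from fibrolysis.macroscale import (
    FrontTrace,
    build_clot,
    crossover_ratio,
    front_depth,
    front_velocity,
    place_bolus,
    run_experiment,
    run_single,
    seed_rng,
    step,
)

BASE = KineticParameters()


def _toy_pack(p_lyse=0.5, residence=(100.0, 200.0), delay=(30.0, 60.0)):
    return MicroSummaryPack(
        tpa_residence=EmpiricalDistribution(np.array(residence)),
        forced_probability=0.5,
        lysis_probability=p_lyse,
        lysis_delay=EmpiricalDistribution(np.array(delay if p_lyse else [])),
    )


class TestBuildClot:
    def test_fine_clot_dimensions(self):
        lat = build_clot(1.37, 97.5, width=100.0, clot_height=100.0)
        assert lat.nx == 73
        assert lat.nzc == 73

    def test_coarse_clot_has_fewer_fibers(self):
        fine = build_clot(1.37, 97.5, 100.0, 100.0)
        coarse = build_clot(2.74, 195.0, 100.0, 100.0)
        assert coarse.nx == 36
        assert coarse.n_fibers < fine.n_fibers

    def test_single_layer_clot(self):
        lat = build_clot(1.37, 97.5, width=10.0, clot_height=1.37)
        assert lat.nzc == 1
        assert lat.lez.size == 0
        assert lat.n_fibers == 2 * lat.nx

    def test_zero_domain_rejected(self):
        with pytest.raises(ValueError):
            build_clot(1.37, 97.5, width=0.1, clot_height=0.1)
        with pytest.raises(ValueError):
            build_clot(0.0, 97.5)


class TestPlaceBolus:
    def test_reference_count(self):
        lat = build_clot(1.37, 97.5, width=100.0, clot_height=10.0, free_height=2.935)
        parts = place_bolus(lat, BolusSpec(5.0, 2.935), seed=0)
        assert parts.n == 1211

    def test_zero_concentration_warns(self):
        lat = build_clot(1.37, 97.5, width=10.0, clot_height=10.0)
        with pytest.warns(UserWarning):
            parts = place_bolus(lat, BolusSpec(0.0, 2.935), seed=0)
        assert parts.n == 0

    def test_equivalent_boluses_have_equal_counts(self):
        lat = build_clot(1.37, 97.5, width=100.0, clot_height=10.0, free_height=50.0)
        n_high = place_bolus(lat, BolusSpec(85.0, 2.94), seed=0).n
        n_low = place_bolus(lat, BolusSpec(5.0, 49.9), seed=0).n
        assert abs(n_high - n_low) <= 0.005 * n_high

    def test_particles_start_in_free_region(self):
        lat = build_clot(1.37, 97.5, width=20.0, clot_height=20.0, free_height=10.0)
        parts = place_bolus(lat, BolusSpec(50.0, 10.0), seed=3)
        assert (parts.pz >= lat.nzc).all()
        assert (parts.pz < lat.nz_total).all()


class TestStepDynamics:
    def test_no_binding_without_affinity(self):
        params = BASE.replace(k_on_tpa=0.0)
        lat = build_clot(1.37, 97.5, width=15.0, clot_height=15.0, free_height=5.0)
        parts = place_bolus(lat, BolusSpec(100.0, 5.0), seed=2)
        seed_rng(2)
        dt = lat.pore_size**2 / (6 * 25.0)
        step(lat, parts, params, _toy_pack(), 0.0, dt, n_steps=2000)
        assert parts.n_bound == 0
        assert lat.n_degraded(1e9) == 0

    def test_degenerate_pack_degrades_on_first_binding(self):
        # certain lysis with zero delay: every binding kills its edge
        pack = _toy_pack(p_lyse=1.0, delay=(0.0,))
        lat = build_clot(1.37, 97.5, width=10.0, clot_height=5.0, free_height=3.0)
        parts = place_bolus(lat, BolusSpec(200.0, 3.0), seed=7)
        trace = run_single(lat, parts, BASE, pack, seed=7, t_max=600.0, out_dt=5.0)
        assert trace.front_depth[-1] == pytest.approx(lat.clot_height)

    def test_particle_conservation_and_monotonicity(self, baseline_fine_pack):
        lat = build_clot(1.37, 97.5, width=20.0, clot_height=15.0, free_height=2.935)
        parts = place_bolus(lat, BolusSpec(20.0, 2.935), seed=11)
        n0 = parts.n
        trace = run_single(
            lat, parts, BASE, baseline_fine_pack, seed=11, t_max=1500.0
        )
        np.testing.assert_array_equal(trace.n_free + trace.n_bound, n0)
        assert (np.diff(trace.front_depth) >= -1e-12).all()
        assert (np.diff(trace.n_degraded) >= 0).all()


class TestDiffusionOracle:
    def test_msd_matches_lattice_walk(self):
        """With binding disabled, mean squared displacement equals 6 D t."""
        params = BASE.replace(k_on_tpa=0.0)
        lat = build_clot(1.0, 97.5, width=30.0, clot_height=1.0, free_height=200.0)
        parts = place_bolus(lat, BolusSpec(30.0, 200.0), seed=13)
        parts.pz[:] = 100  # mid-column, far from both reflecting walls
        d_tpa = 25.0
        dt = lat.pore_size**2 / (6 * d_tpa)
        n_steps = 300
        seed_rng(13)
        step(lat, parts, params, _toy_pack(), 0.0, dt, n_steps=n_steps, d_tpa=d_tpa)
        t = n_steps * dt
        expected = 6 * d_tpa * t  # = n_steps * pore^2
        rel_se = np.sqrt(6) / 3 / np.sqrt(parts.n)
        assert parts.msd() == pytest.approx(expected, rel=max(3 * rel_se, 0.05))


class TestFrontMeasurement:
    def test_front_depth_reference_states(self):
        lat = build_clot(1.37, 97.5, width=10.0, clot_height=10.0)
        assert front_depth(lat, 0.0) == 0.0
        lat.lex[:] = 0.0
        lat.ley[:] = 0.0
        lat.lez[:] = 0.0
        assert front_depth(lat, 1.0) == pytest.approx(lat.clot_height)

    def test_front_depth_top_layer_only(self):
        lat = build_clot(1.37, 97.5, width=10.0, clot_height=10.0)
        lat.lex[:, -1] = 0.0
        lat.ley[:, -1] = 0.0
        assert front_depth(lat, 1.0) == pytest.approx(lat.pore_size)

    def _trace(self, times, depths, n_deg=None):
        times = np.asarray(times, dtype=float)
        depths = np.asarray(depths, dtype=float)
        if n_deg is None:
            n_deg = (depths > 0).astype(int)
        return FrontTrace(
            times=times,
            front_depth=depths,
            n_degraded=np.asarray(n_deg),
            n_degraded_below_front=np.zeros_like(times),
            n_free=np.zeros_like(times),
            n_bound=np.zeros_like(times),
            seed=0,
            clot_height=1e9,
            n_fibers=100,
        )

    def test_velocity_of_exact_line(self):
        t = np.arange(0, 601, 60.0)
        trace = self._trace(t, 2.0 * t / 60.0)  # 2 um per minute
        v, flag = front_velocity(trace)
        assert flag == "ok"
        assert v == pytest.approx(2.0)

    def test_flat_trace_flags_no_lysis(self):
        trace = self._trace([0, 60, 120], [0, 0, 0], n_deg=[0, 0, 0])
        v, flag = front_velocity(trace)
        assert v == 0.0 and flag == "no-lysis"


class TestCrossover:
    def test_hand_fitted_line(self):
        r = crossover_ratio(
            np.array([100.0, 500.0]), np.array([0.8, 1.8]), np.array([1.0, 1.0])
        )
        assert r == pytest.approx(180.0)

    def test_no_crossing_rejected(self):
        with pytest.raises(ValueError, match="never crosses"):
            crossover_ratio(
                np.array([10.0, 20.0]), np.array([1.0, 2.0]), np.array([0.5, 0.5])
            )

    def test_single_exact_point(self):
        assert crossover_ratio(np.array([250.0]), np.array([3.0]), np.array([3.0])) == 250.0


class TestVelocityIntensivity:
    def test_halving_slab_width(self, baseline_fine_pack):
        """Front velocity is intensive: independent of slab width."""
        bolus = BolusSpec(5.0, 2.935)
        results = []
        for width, seed in ((50.0, 61), (25.0, 62)):
            exp = run_experiment(
                baseline_fine_pack, BASE, bolus,
                pore_size=1.37, fiber_diameter=97.5,
                width=width, clot_height=25.0,
                n_replicates=10, base_seed=seed, t_max=3000.0,
            )
            results.append(exp)
        a, b = results
        pooled = np.sqrt((a.sd_velocity**2 + b.sd_velocity**2) / 2)
        assert abs(a.mean_velocity - b.mean_velocity) <= 2 * pooled
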