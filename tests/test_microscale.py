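"""Single-fiber Gillespie engine: construction, propensities, dynamics."""

import numpy as np
import pytest

from fibrolysis import _micro_kernel as mk
from fibrolysis.kinetics import KineticParameters
from fibrolysis.microscale import (
    MicroRules,
    build_cross_section,
    enumerate_reactions,
    gillespie_run,
    run_ensemble,
)

BASE = KineticParameters()


class TestConstruction:
    def test_grid_dimensions(self):
        assert build_cross_section(97.5).n == 9
        assert build_cross_section(195.0).n == 18

    def test_minimal_fiber_is_two_by_two(self):
        # thinnest fiber spanning two protofibril pitch cells
        assert build_cross_section(22.0).n == 2
        with pytest.raises(ValueError):
            build_cross_section(8.0)

    def test_initial_exposure_pattern(self):
        state = build_cross_section(97.5, seed=1)
        assert (state.exposed.sum(axis=1) == 1).all()  # 1 exposed, 5 cryptic
        assert state.accessible.sum() == 4 * 9 - 4  # perimeter only
        loc, dbl = state.tpa
        assert state.accessible[loc] == 1 and dbl == 0


class TestEnumerateReactions:
    def test_initial_propensities(self):
        state = build_cross_section(97.5, seed=3)
        events = enumerate_reactions(state, BASE)
        kinds = {}
        for kind, _, _, a in events:
            kinds.setdefault(kind, []).append(a)
        # one tPA unbinding event at the bare-doublet rate
        assert kinds["tpa_unbind"] == [pytest.approx(0.0036)]
        # one PLG binding event per accessible exposed doublet, k_on * [PLG]
        assert len(kinds["plg_bind"]) == 4 * 9 - 4
        assert all(a == pytest.approx(0.2) for a in kinds["plg_bind"])
        assert set(kinds) == {"tpa_unbind", "plg_bind"}

    def test_dead_state_has_no_events(self):
        state = build_cross_section(97.5, place_tpa=False)
        state.exposed[:] = 0  # nothing exposed, nothing bound
        assert enumerate_reactions(state, BASE) == []

    def test_ternary_complex_slows_tpa_unbinding(self):
        state = build_cross_section(97.5, seed=3)
        loc, dbl = state.tpa
        state.plg[loc, dbl] = 1
        events = dict(
            (kind, a) for kind, _, _, a in enumerate_reactions(state, BASE)
            if kind in ("tpa_unbind", "activate")
        )
        assert events["tpa_unbind"] == pytest.approx(0.0002)
        assert events["activate"] == pytest.approx(0.1)


class TestDynamics:
    def test_pure_kinetic_unbinding_is_exponential(self):
        # no plasminogen, no activation: the leave time is Exp(k_off)
        params = BASE.replace(k_cat_ap=0.0, plg_concentration=0.0)
        results, summary = run_ensemble(params, 97.5, 4000, 71)
        times = np.array([r.tpa_leave_time for r in results])
        assert summary.n_forced == 0 and summary.n_censored == 0
        mean = 1.0 / params.k_off_tpa_without_plg
        se = mean / np.sqrt(len(times))
        assert abs(times.mean() - mean) < 3 * se

    def test_no_degradation_means_no_forced_unbinding(self):
        params = BASE.replace(k_deg=0.0)
        _, summary = run_ensemble(params, 97.5, 200, 11)
        assert summary.n_forced == 0
        assert summary.n_lysed == 0

    def test_single_run_summary_consistency(self):
        results, summary = run_ensemble(BASE, 97.5, 1, 5)
        assert summary.n_runs == 1
        assert summary.n_forced + summary.n_kinetic + summary.n_censored == 1

    def test_mode_partition(self, baseline_fine):
        results, summary = baseline_fine
        assert (
            summary.n_forced + summary.n_kinetic
            == summary.n_runs - summary.n_censored
        )
        forced = [r for r in results if r.leave_mode == "forced"]
        assert all(r.plasmin_created >= 1 for r in forced)

    def test_censoring_horizon(self):
        r = gillespie_run(BASE, 97.5, seed=4, t_max=1e-3)
        assert r.censored and r.leave_mode == "censored"
        assert r.tpa_leave_time < 0

    def test_final_state_invariants(self):
        params = BASE
        _, state = gillespie_run(params, 97.5, seed=42, return_state=True)
        degraded = state.fstate == 2
        assert not (state.plg[degraded]).any()
        assert not (state.pli[degraded]).any()
        # perimeter is always accessible
        n = state.n
        rows, cols = np.divmod(np.arange(n * n), n)
        perim = (rows == 0) | (rows == n - 1) | (cols == 0) | (cols == n - 1)
        assert state.accessible[perim].all()


class TestDeterminism:
    def test_same_seed_identical_event_log(self):
        a = gillespie_run(BASE, 97.5, seed=123)
        b = gillespie_run(BASE, 97.5, seed=123)
        assert a == b
        assert a.checksum == b.checksum

    def test_different_seeds_diverge(self):
        a = gillespie_run(BASE, 97.5, seed=123)
        b = gillespie_run(BASE, 97.5, seed=124)
        assert a.checksum != b.checksum

    def test_ensemble_reproducible(self):
        r1, s1 = run_ensemble(BASE, 97.5, 50, 17)
        r2, s2 = run_ensemble(BASE, 97.5, 50, 17)
        assert s1 == s2
        assert [r.checksum for r in r1] == [r.checksum for r in r2]


class TestOccupancyOracle:
    def test_two_state_plg_occupancy(self):
        """On a 2x2 grid with only PLG binding/unbinding enabled, the
        time-averaged occupancy matches k_on C / (k_on C + k_off)."""
        params = BASE.replace(
            k_cat_ap=0.0,
            k_cat_n=0.0,
            k_deg=0.0,
            k_off_tpa_with_plg=0.0,
            k_off_tpa_without_plg=0.0,
        )
        t_max = 3000.0
        n = 2
        ws = mk.make_workspace(n)
        mk.micro_ssa(
            n, params.as_array(), 7, t_max, False, True, 1, True, True, False, **ws
        )
        out = ws["out"]
        assert out[mk.RES_OK] == 1.0
        n_sites = 4 * n - 4  # one exposed doublet per (all-perimeter) location
        occupancy = out[mk.RES_PLG_INTEG] / (t_max * n_sites)
        k_on_c = params.k_on_plg_intact * params.plg_concentration
        expected = k_on_c / (k_on_c + params.k_off_plg)
        n_cycles = k_on_c * n_sites * t_max
        se = expected / np.sqrt(n_cycles)
        assert abs(occupancy - expected) < max(3 * se, 0.005)


class TestForcedFractionMonotonicity:
    def test_forced_fraction_nondecreasing_in_k_deg(self):
        # Monotone in the degradation-limited regime (k_deg below ~2 s^-1).
        # At much higher k_deg the trend inverts: degradation consumes the
        # cryptic doublets at the tPA's location before they are exposed,
        # leaving no seat from which a plasmin could cut the tPA's doublet.
        fractions = []
        for k_deg in (0.02, 0.2, 2.0):
            _, summary = run_ensemble(BASE.replace(k_deg=k_deg), 97.5, 2000, 911)
            fractions.append(summary.forced_fraction)
        assert fractions[0] <= fractions[1] <= fractions[2]


class TestRules:
    def test_invalid_cut_threshold(self):
        with pytest.raises(ValueError):
            MicroRules(cut_threshold=0)

    def test_full_grid_criterion_is_stricter(self):
        # requiring the whole grid to degrade can only reduce lysis calls
        res_a, s_a = run_ensemble(BASE, 97.5, 300, 55)
        res_b, s_b = run_ensemble(
            BASE, 97.5, 300, 55, require_full_grid=True
        )
        assert s_b.n_lysed <= s_a.n_lysed
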