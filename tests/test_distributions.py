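"""Empirical distribution packs: construction, sampling, serialization."""

import json

import numpy as np
import pytest

from fibrolysis.distributions import (
    EmpiricalDistribution,
    build_pack,
    load_pack,
    save_pack,
)
from fibrolysis.microscale import MicroRunResult


def _run(leave, mode="kinetic", lysed=False, lysis_time=None, censored=False, seed=0):
    return MicroRunResult(
        tpa_leave_time=leave,
        leave_mode=mode,
        plasmin_created=1 if (lysed or mode == "forced") else 0,
        lysis_occurred=lysed,
        lysis_time=lysis_time,
        seed=seed,
        censored=censored,
    )


class TestBuildPack:
    def test_three_unlysed_runs(self):
        pack = build_pack([_run(10.0), _run(20.0), _run(30.0)])
        assert pack.tpa_residence.quantile(0.5) == 20.0
        assert pack.lysis_probability == 0.0
        assert len(pack.lysis_delay) == 0

    def test_single_lysed_run(self):
        pack = build_pack([_run(8.0, "forced", True, 5.0)])
        assert pack.lysis_probability == 1.0
        assert pack.forced_probability == 1.0
        assert pack.lysis_delay.values.tolist() == [5.0]

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            build_pack([_run(-1.0, "censored", censored=True)])

    def test_censored_runs_excluded(self):
        pack = build_pack([_run(10.0), _run(-1.0, "censored", censored=True)])
        assert len(pack.tpa_residence) == 1
        assert pack.metadata["censored"] == 1

    def test_mode_probabilities_sum_to_one(self, baseline_fine, baseline_fine_pack):
        results, summary = baseline_fine
        p_forced = baseline_fine_pack.forced_probability
        non_censored = summary.n_runs - summary.n_censored
        assert p_forced == pytest.approx(summary.n_forced / non_censored)
        assert summary.n_kinetic / non_censored == pytest.approx(1.0 - p_forced)

    def test_lysis_probability_near_reference_value(self, baseline_fine_pack):
        # roughly the 0.586 of baseline single-fiber lysis
        assert 0.50 <= baseline_fine_pack.lysis_probability <= 0.65


class TestSampling:
    def test_quantile_lookup(self):
        d = EmpiricalDistribution(np.array([1.0, 2.0, 3.0]))
        assert d.sample(0.99) == 3.0
        assert d.sample(0.0) == 1.0
        assert d.sample(1.0) == 3.0

    def test_degenerate_distribution(self):
        d = EmpiricalDistribution(np.array([5.0]))
        for u in (0.0, 0.3, 1.0):
            assert d.sample(u) == 5.0

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            EmpiricalDistribution(np.array([])).sample(0.5)

    def test_u_out_of_range_rejected(self):
        d = EmpiricalDistribution(np.array([1.0]))
        with pytest.raises(ValueError):
            d.sample(1.5)

    def test_resampled_mean_matches(self):
        rng = np.random.default_rng(4)
        values = rng.gamma(2.0, 50.0, size=500)
        d = EmpiricalDistribution(values)
        draws = d.sample(rng.random(100_000))
        se = values.std() / np.sqrt(100_000) + values.std() / np.sqrt(500)
        assert abs(draws.mean() - values.mean()) < 3 * se

    def test_dkw_resampling_bound(self, baseline_fine_pack):
        """KS distance between a pack's distribution and its own large
        resample stays under the DKW bound."""
        d = baseline_fine_pack.tpa_residence
        rng = np.random.default_rng(9)
        n = 100_000
        draws = np.sort(d.sample(rng.random(n)))
        # empirical CDF of the resample evaluated against the pack's own CDF
        f_pack = np.searchsorted(d.values, draws, side="right") / len(d)
        f_resample = np.arange(1, n + 1) / n
        ks = np.abs(f_resample - f_pack).max()
        assert ks < 0.01


class TestSerialization:
    def test_round_trip(self, baseline_fine_pack, tmp_path):
        p = tmp_path / "pack.json"
        save_pack(baseline_fine_pack, p)
        loaded = load_pack(p)
        np.testing.assert_array_equal(
            loaded.tpa_residence.values, baseline_fine_pack.tpa_residence.values
        )
        np.testing.assert_array_equal(
            loaded.lysis_delay.values, baseline_fine_pack.lysis_delay.values
        )
        assert loaded.forced_probability == baseline_fine_pack.forced_probability
        assert loaded.lysis_probability == baseline_fine_pack.lysis_probability
        assert loaded.metadata == baseline_fine_pack.metadata

    def test_empty_delay_round_trip(self, tmp_path):
        pack = build_pack([_run(10.0), _run(12.0)])
        p = tmp_path / "pack.json"
        save_pack(pack, p)
        loaded = load_pack(p)
        assert len(loaded.lysis_delay) == 0
        assert loaded.lysis_probability == 0.0

    def test_version_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(
            json.dumps({"format": "fibrolysis-micro-pack", "version": 99})
        )
        with pytest.raises(ValueError, match="version"):
            load_pack(p)

    def test_truncated_file_rejected(self, baseline_fine_pack, tmp_path):
        p = tmp_path / "trunc.json"
        save_pack(baseline_fine_pack, p)
        p.write_text(p.read_text()[:100])
        with pytest.raises(ValueError):
            load_pack(p)

    def test_wrong_format_rejected(self, tmp_path):
        p = tmp_path / "other.json"
        p.write_text(json.dumps({"format": "something-else", "version": 1}))
        with pytest.raises(ValueError, match="not a fibrolysis"):
            load_pack(p)
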