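"""Resampling, aggregation and per-position comparison tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from seedmorph import (
    InvalidArgumentError,
    TIER_ALPHAS,
    aggregate_group,
    compare_profiles,
    region_compare,
    resample_profile,
)


class TestResample:
    def test_constant_preserved(self):
        s = np.linspace(0, 1, 13)
        out = resample_profile(s, np.full(13, 7.0), 67)
        np.testing.assert_array_equal(out, np.full(67, 7.0))

    def test_two_cells_distal_inclusive(self):
        out = resample_profile([0.0, 1.0], [10.0, 20.0], 3)
        np.testing.assert_array_equal(out, [10.0, 20.0, 20.0])

    def test_matches_nearest_cell_oracle(self):
        rng = np.random.default_rng(1)
        s = np.sort(rng.uniform(0, 1, 40))
        s[0], s[-1] = 0.0, 1.0
        vals = rng.normal(size=40)
        out = resample_profile(s, vals, 201)
        pos = np.linspace(0, 1, 201)
        # oracle: nearest cell in s, ties to the distal cell
        for p, got in zip(pos, out):
            d = np.abs(s - p)
            idx = np.nonzero(d == d.min())[0].max()
            assert got == vals[idx]

    def test_gap_positions_nan(self):
        out = resample_profile([0.0, 1.0], [1.0, 2.0], 11, gaps=[(0.35, 0.65)])
        pos = np.linspace(0, 1, 11)
        inside = (pos > 0.35) & (pos < 0.65)
        assert np.all(np.isnan(out[inside]))
        assert not np.any(np.isnan(out[~inside]))

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            resample_profile([], [], 10)

    def test_unsorted_input_sorted(self):
        out = resample_profile([1.0, 0.0], [20.0, 10.0], 3)
        np.testing.assert_array_equal(out, [10.0, 20.0, 20.0])


class TestAggregate:
    def test_duplicated_specimen_zero_sd(self):
        row = np.random.default_rng(0).normal(size=67)
        prof = aggregate_group(np.array([row, row, row]), "g", "area")
        np.testing.assert_allclose(prof.sd, 0.0, atol=1e-12)
        assert np.all(prof.n == 3)

    def test_two_specimen_closed_form(self):
        prof = aggregate_group(np.array([[10.0, 10.0], [20.0, 20.0]]), "g", "area")
        assert prof.mean[0] == pytest.approx(15.0)
        assert prof.sd[0] == pytest.approx(np.sqrt(50.0))  # ~7.071

    def test_single_specimen_sd_missing(self):
        prof = aggregate_group(np.array([[1.0, np.nan], [np.nan, np.nan]]), "g", "x")
        assert np.isnan(prof.sd[0]) and np.isnan(prof.sd[1])
        assert prof.n.tolist() == [1, 0]

    def test_monte_carlo_mean_concentration(self):
        rng = np.random.default_rng(7)
        samples = rng.normal(100.0, 10.0, size=(33, 67))
        prof = aggregate_group(samples, "g", "area")
        within = np.abs(prof.mean - 100.0) <= 3 * 10.0 / np.sqrt(33)
        assert within.mean() >= 0.99


class TestCompare:
    def test_identical_groups_all_ns(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 31))
        res = compare_profiles(a, a.copy())
        assert np.all(res.tier == "ns")
        assert all(len(v) == 0 for v in res.runs.values())

    def test_strong_separation_all_p00001(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (33, 201))
        b = rng.normal(10, 1, (20, 201))
        res = compare_profiles(a, b)
        assert np.all(res.p < 1e-5)
        assert np.all(res.tier == "p00001")
        # closed-form check of the expected t magnitude
        expect_t = 10.0 / np.sqrt(1.0 / 33 + 1.0 / 20)
        assert np.abs(np.nanmean(res.t) + expect_t) < 0.15 * expect_t

    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, (12, 40))
        b = rng.normal(0.5, 2, (9, 40))
        res = compare_profiles(a, b)
        ref = stats.ttest_ind(a, b, axis=0)
        np.testing.assert_allclose(res.t, ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res.p, ref.pvalue, rtol=1e-10)
        welch = compare_profiles(a, b, welch=True)
        refw = stats.ttest_ind(a, b, axis=0, equal_var=False)
        np.testing.assert_allclose(welch.t, refw.statistic, rtol=1e-10)
        np.testing.assert_allclose(welch.p, refw.pvalue, rtol=1e-10)

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, (6, 20))
        b = rng.normal(1, 1, (7, 20))
        ab = compare_profiles(a, b)
        ba = compare_profiles(b, a)
        np.testing.assert_allclose(ab.t, -ba.t, rtol=1e-12)
        np.testing.assert_allclose(ab.p, ba.p, rtol=1e-12)

    def test_zero_variance_degenerate_rules(self):
        a = np.full((3, 2), 5.0)
        b = np.column_stack([np.full(3, 5.0), np.full(3, 6.0)])
        res = compare_profiles(a, b)
        assert res.p[0] == 1.0 and res.t[0] == 0.0
        assert res.p[1] == 0.0 and np.isinf(res.t[1])
        assert res.degenerate.tolist() == [True, True]

    def test_mismatched_n_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compare_profiles(np.zeros((3, 10)), np.zeros((3, 11)))

    @given(seed=st.integers(0, 2_000))
    def test_tier_nesting(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (8, 50))
        b = rng.normal(rng.uniform(0, 1.5), 1, (6, 50))
        res = compare_profiles(a, b)
        p5 = set(res.tier_positions("p00001").tolist())
        p3 = set(res.tier_positions("p001").tolist())
        p05 = set(res.tier_positions("p05").tolist())
        assert p5 <= p3 <= p05

    def test_runs_are_maximal_contiguous(self):
        # construct p-values by separation pattern
        a = np.zeros((5, 6))
        b = np.zeros((5, 6))
        b[:, [1, 2, 4]] += 100.0
        b += np.random.default_rng(0).normal(0, 0.1, b.shape)
        a += np.random.default_rng(1).normal(0, 0.1, a.shape)
        res = compare_profiles(a, b)
        runs = [(i0, i1) for (i0, i1, _, _) in res.runs["p00001"]]
        assert runs == [(1, 2), (4, 4)]

    def test_bh_adjustment_weaker(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, (10, 50))
        b = rng.normal(0.8, 1, (10, 50))
        raw = compare_profiles(a, b)
        adj = compare_profiles(a, b, adjust="bh")
        assert np.all(adj.p >= raw.p - 1e-15)


class TestRegionCompare:
    @staticmethod
    def _records(effect: float, seed: int) -> pd.DataFrame:
        """Synthetic per-cell records: chalazal areas shifted by `effect`."""
        rng = np.random.default_rng(seed)
        rows = []
        for spec in range(10):
            s = np.sort(rng.uniform(0, 1, 30))
            area = rng.normal(100, 5, 30)
            region = np.where(s < 1 / 3, "chalazal",
                              np.where(s < 2 / 3, "curving_zone", "micropylar"))
            area[region == "chalazal"] += effect
            for si, ai, ri in zip(s, area, region):
                rows.append({"specimen_id": f"sp{spec}", "s": si, "area": ai,
                             "region": ri})
        return pd.DataFrame(rows)

    def test_identical_regions_ns(self):
        res = region_compare(self._records(0.0, 0), n_points=67)
        for cmp_res in res.values():
            assert np.mean(np.nan_to_num(cmp_res.p, nan=1.0) < 0.05) <= 0.12

    def test_shifted_chalazal_detected(self):
        res = region_compare(self._records(-40.0, 1), n_points=67)
        cm = res[("chalazal", "micropylar")]
        assert np.mean(cm.p < 0.05) >= 0.9
        cc = res[("chalazal", "curving_zone")]
        assert np.mean(cc.p < 0.05) >= 0.9

    def test_pair_swap_flips_t(self):
        recs = self._records(-40.0, 2)
        res = region_compare(recs, n_points=33)
        cm = res[("chalazal", "micropylar")]
        assert np.nanmean(cm.t) < 0  # chalazal smaller
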