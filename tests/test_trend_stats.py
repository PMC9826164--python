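"""Statistical core: trends, paired tests, Chow breaks, BACI windows, species contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ifmaudit.trend_stats import (
    TimeSeries,
    before_after,
    chow,
    difference_series,
    paired_across_years,
    paired_test,
    portfolio_aggregate,
    species_contrast,
    trend,
)


def ts(values, start=2000, **kw):
    values = np.asarray(values, dtype=float)
    return TimeSeries(np.arange(start, start + values.size), values, **kw)


# ---------------------------------------------------------------------------
# trend


class TestTrend:
    def test_exact_line_recovers_slope_with_zero_se(self):
        r = trend(ts(5.0 + 2.0 * np.arange(10)))
        assert r.slope == pytest.approx(2.0)
        assert r.slope_se == pytest.approx(0.0, abs=1e-9)

    def test_constant_series_has_zero_slope_and_percent_rate(self):
        r = trend(ts(np.full(8, 3.5)))
        assert r.slope == pytest.approx(0.0, abs=1e-12)
        assert r.percent_rate == pytest.approx(0.0, abs=1e-10)

    def test_percent_rate_is_slope_over_period_mean(self):
        # slope 1.30 on a mean stock of 123.0 -> about 1.06 %/yr
        years = np.arange(1986, 2013)
        vals = 123.0 + 1.30 * (years - years.mean())
        r = trend(TimeSeries(years, vals))
        assert r.mean == pytest.approx(123.0)
        assert r.percent_rate == pytest.approx(100 * 1.30 / 123.0, rel=1e-9)
        assert 1.0 <= r.percent_rate <= 1.1

    def test_initial_denominator_option(self):
        series = ts([100.0, 102.0, 104.0, 106.0])
        r = trend(series, percent_denominator="initial")
        assert r.percent_rate == pytest.approx(2.0)

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            trend(ts([1.0, 2.0]))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(shift=st.floats(-1e3, 1e3), seed=st.integers(0, 100))
    def test_constant_shift_moves_intercept_only(self, shift, seed):
        rng = np.random.default_rng(seed)
        base = ts(rng.normal(50, 5, size=12))
        r0 = trend(base)
        r1 = trend(TimeSeries(base.years, base.values + shift))
        assert r1.slope == pytest.approx(r0.slope, abs=1e-8)


# ---------------------------------------------------------------------------
# paired tests


class TestPaired:
    def test_identical_series_is_flagged_with_t_zero_p_one(self):
        a = ts([1.0, 2.0, 3.0, 4.0])
        r = paired_across_years(a, a)
        assert (r.t, r.p, r.degenerate) == (0.0, 1.0, True)

    def test_constant_nonzero_difference_is_degenerate(self):
        a = ts([1.0, 2.0, 3.0])
        b = ts([2.0, 3.0, 4.0])
        r = paired_across_years(a, b)
        assert r.degenerate and np.isnan(r.t)
        assert r.mean_difference == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_toy_differences(self):
        # differences d = a - b = [1, 2, 0, 1, 1]: mean 1, sd sqrt(0.5)
        a = np.array([3.0, 5.0, 2.0, 4.0, 6.0])
        b = a - np.array([1.0, 2.0, 0.0, 1.0, 1.0])
        r = paired_test(a, b)
        expected_t = 1.0 / (np.sqrt(0.5) / np.sqrt(5))
        assert r.t == pytest.approx(expected_t)
        assert r.p == pytest.approx(2 * sps.t.sf(expected_t, 4))
        ref = sps.ttest_rel(a, b)
        assert r.t == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)

    def test_relative_difference_uses_control_mean(self):
        r = paired_test(np.array([2.0, 4.0, 3.3]), np.array([1.0, 2.0, 3.0]))
        assert r.relative_difference == pytest.approx(100 * r.mean_difference / 2.0)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="no years"):
            paired_across_years(ts([1.0, 2.0], start=2000), ts([1.0, 2.0], start=2010))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 1000))
    def test_antisymmetry_in_arguments(self, seed):
        rng = np.random.default_rng(seed)
        a, b = ts(rng.normal(size=9)), ts(rng.normal(size=9))
        r_ab, r_ba = paired_across_years(a, b), paired_across_years(b, a)
        assert r_ab.mean_difference == pytest.approx(-r_ba.mean_difference)
        assert r_ab.p == pytest.approx(r_ba.p)


# ---------------------------------------------------------------------------
# Chow structural break


def chow_oracle(years, values, bp):
    """Brute-force three-regression Chow F."""

    def rss(y, v):
        if len(y) == 0:
            return 0.0
        c = np.polyfit(y, v, 1)
        return float(np.sum((v - np.polyval(c, y)) ** 2))

    m = years <= bp
    r_p = rss(years, values)
    r1, r2 = rss(years[m], values[m]), rss(years[~m], values[~m])
    n1, n2 = m.sum(), (~m).sum()
    return ((r_p - r1 - r2) / 2) / ((r1 + r2) / (n1 + n2 - 4))


class TestChow:
    def test_single_line_gives_small_f_large_p(self):
        rng = np.random.default_rng(0)
        series = ts(10 + 0.5 * np.arange(20) + rng.normal(0, 0.3, 20))
        r = chow(series, int(series.years[9]))
        assert r.p > 0.05

    def test_exact_two_segment_break_gives_p_zero(self):
        years = np.arange(2000, 2012)
        vals = np.where(years <= 2005, years - 2000.0, 6.0 + 3.0 * (years - 2005))
        r = chow(TimeSeries(years, vals), 2005)
        assert np.isinf(r.F) and r.p == 0.0
        assert r.slope_before == pytest.approx(1.0)
        assert r.slope_after == pytest.approx(3.0)

    def test_f_statistic_matches_three_regression_oracle(self):
        rng = np.random.default_rng(3)
        years = np.arange(2000, 2012)
        vals = 5 + 0.4 * (years - 2000) + rng.normal(0, 1.0, 12)
        vals[6:] += 2.0
        r = chow(TimeSeries(years, vals), 2005)
        assert r.F == pytest.approx(chow_oracle(years, vals, 2005), rel=1e-10)
        assert r.df == (2, 8)
        assert r.p == pytest.approx(sps.f.sf(r.F, 2, 8), rel=1e-12)

    def test_too_few_points_on_either_side_rejected(self):
        with pytest.raises(ValueError, match="each side"):
            chow(ts(np.arange(8.0)), 2001)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(shift=st.floats(-100, 100), seed=st.integers(0, 500))
    def test_invariant_to_constant_shift(self, shift, seed):
        rng = np.random.default_rng(seed)
        series = ts(rng.normal(10, 2, 14))
        r0 = chow(series, 2006)
        r1 = chow(TimeSeries(series.years, series.values + shift), 2006)
        assert r1.F == pytest.approx(r0.F, rel=1e-6, abs=1e-8)


# ---------------------------------------------------------------------------
# before/after windows


class TestBeforeAfter:
    @staticmethod
    def _series(first, last, kind):
        years = np.arange(first, last + 1)
        rng = np.random.default_rng(1)
        return TimeSeries(years, rng.normal(100 if kind == "carbon" else 0.02, 1e-3, years.size),
                          variable=kind)

    def test_carbon_window_is_three_years_for_2014_start(self):
        res = before_after({"carbon": self._series(1986, 2017, "carbon")},
                           2014, {"carbon": 2017})
        r = res["carbon"]
        assert r.window == 3
        assert r.before_years == (2012, 2014)
        assert r.after_years == (2015, 2017)
        assert not r.excluded and r.chow is not None

    def test_harvest_window_is_seven_years_for_2014_start(self):
        res = before_after({"harvest": self._series(1986, 2021, "harvest")},
                           2014, {"harvest": 2021})
        r = res["harvest"]
        assert r.window == 7
        assert r.after_years == (2015, 2021)
        assert r.paired is not None and r.paired.n_pairs == 7

    def test_insufficient_post_period_is_excluded_with_reason(self):
        res = before_after({"carbon": self._series(1986, 2017, "carbon")},
                           2016, {"carbon": 2017})
        assert res["carbon"].excluded
        assert "post-carbon" in res["carbon"].excluded_reason

    def test_null_series_chow_p_is_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(300):
            s = TimeSeries(np.arange(2000, 2018),
                           1.0 * np.arange(18) + rng.normal(0, 1, 18), variable="carbon")
            ps.append(before_after({"carbon": s}, 2008, {"carbon": 2017})["carbon"].chow.p)
        assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.12


# ---------------------------------------------------------------------------
# species contrasts


class TestSpeciesContrast:
    def test_single_species_landscape_is_all_one_hundred_percent(self):
        layer = np.full((6, 6), 2.0)
        masks = [np.zeros((6, 6), bool)]
        masks[0][:3, :3] = True
        ctrl = [~masks[0]]
        comp = species_contrast({"redwood": layer}, masks, ctrl, "redwood")
        assert comp.project_fraction == pytest.approx(100.0)
        assert comp.control_fraction == pytest.approx(100.0)

    def test_planted_patch_contrast_matches_counting_oracle(self):
        total = np.full((10, 10), 100.0)
        tan = np.where(np.arange(100).reshape(10, 10) < 50, 35.0, 20.0)
        layers = {"tanoak": tan, "rest": total - tan}
        pmask = np.zeros((10, 10), bool)
        pmask[:5] = True                    # fully inside the 35% patch
        cmask = ~pmask                      # background at 20%
        comp = species_contrast(layers, [pmask], [cmask], "tanoak")
        assert comp.project_fraction - comp.control_fraction == pytest.approx(15.0)

    def test_zero_carbon_mask_drops_project_with_warning(self):
        layers = {"a": np.zeros((4, 4))}
        m = np.ones((4, 4), bool)
        with pytest.warns(UserWarning, match="zero total carbon"):
            comp = species_contrast(layers, [m], [m], "a")
        assert comp.n_projects == 0


# ---------------------------------------------------------------------------
# portfolio aggregation


class TestPortfolio:
    def test_single_project_is_identity(self):
        s = ts([1.0, 2.0, 3.0])
        agg, summary = portfolio_aggregate({"p": s})
        np.testing.assert_allclose(agg.values, s.values)
        assert summary["n_projects"] == 1

    def test_equal_weights_average(self):
        agg, _ = portfolio_aggregate({"a": ts([1.0, 1.0]), "b": ts([3.0, 3.0])})
        np.testing.assert_allclose(agg.values, [2.0, 2.0])

    def test_area_weighted_mean(self):
        agg, _ = portfolio_aggregate({"a": ts([3.0]* 3), "b": ts([6.0] * 3)},
                                     weights={"a": 1.0, "b": 2.0})
        np.testing.assert_allclose(agg.values, 5.0)

    def test_disjoint_years_restricted_with_warning(self):
        a = ts(np.arange(6.0), start=2000)
        b = ts(np.arange(6.0), start=2003)
        with pytest.warns(UserWarning, match="common years"):
            agg, _ = portfolio_aggregate({"a": a, "b": b})
        assert agg.years.tolist() == [2003, 2004, 2005]

    def test_split_mask_weighting_recovers_whole(self):
        rng = np.random.default_rng(4)
        part1, part2 = rng.normal(size=10), rng.normal(size=10)
        whole = 0.3 * part1 + 0.7 * part2
        agg, _ = portfolio_aggregate({"p1": ts(part1), "p2": ts(part2)},
                                     weights={"p1": 3.0, "p2": 7.0})
        np.testing.assert_allclose(agg.values, whole, atol=1e-12)


def test_difference_series_subtracts_on_common_years():
    a = ts([5.0, 6.0, 7.0], start=2000)
    b = ts([1.0, 1.0, 1.0, 1.0], start=1999)
    d = difference_series(a, b)
    assert d.years.tolist() == [2000, 2001, 2002]
    np.testing.assert_allclose(d.values, [4.0, 5.0, 6.0])
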