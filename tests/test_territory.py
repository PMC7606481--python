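"""Territory distribution statistics and pre/post comparison machinery."""

import numpy as np
import pytest
from scipy import stats

from dsaperf.model import Metric, PerfusionMapSet, ROIMask, View
from dsaperf.territory_analysis import (
    aggregate_cases,
    compare_pre_post,
    summarize_roi,
)


def mapset_from(at_map, valid=None, **others):
    """Build a PerfusionMapSet where every metric defaults to the AT map."""
    at_map = np.asarray(at_map, float)
    valid = np.isfinite(at_map) if valid is None else valid
    maps = {}
    for m in Metric:
        arr = np.asarray(others.get(m.value, at_map), float).copy()
        arr[~valid] = np.nan
        maps[m] = arr
    return PerfusionMapSet(
        maps=maps, validity_mask=valid, times_window=(0.0, 10.0), view=View.AP
    )


def test_constant_region_summary():
    maps = mapset_from(np.full((8, 8), 3.0))
    roi = ROIMask(mask=np.ones((8, 8), bool), view=View.AP)
    s = {x.metric: x for x in summarize_roi(maps, roi)}[Metric.AT]
    assert (s.mean, s.median, s.sd, s.skew, s.kurtosis) == (3.0, 3.0, 0.0, 0.0, 0.0)
    assert s.n_valid_px == 64


def test_two_equal_subregions_brute_force_moments():
    mtt = np.full((20, 20), 2.0)
    mtt[10:, :] = 6.0
    maps = mapset_from(np.zeros((20, 20)), MTT=mtt)
    roi = ROIMask(mask=np.ones((20, 20), bool))
    s = {x.metric: x for x in summarize_roi(maps, roi)}[Metric.MTT]
    vals = mtt.ravel()
    assert s.mean == pytest.approx(vals.mean())  # 4.0
    assert s.median == pytest.approx(np.median(vals))  # 4.0
    assert s.sd == pytest.approx(np.std(vals, ddof=1))  # ~2.0 (sample conv.)
    assert s.sd == pytest.approx(2.0, rel=2e-3)


def test_pooled_mean_is_count_weighted_mean_of_subrois():
    rng = np.random.default_rng(0)
    field = rng.normal(5, 1, (16, 16))
    maps = mapset_from(field)
    top_mask = np.zeros((16, 16), bool)
    top_mask[:10] = True
    top = ROIMask(mask=top_mask)
    bottom = ROIMask(mask=~top_mask)
    full = ROIMask(mask=np.ones((16, 16), bool))
    s_top = summarize_roi(maps, top)[0]
    s_bot = summarize_roi(maps, bottom)[0]
    s_full = summarize_roi(maps, full)[0]
    pooled = (
        s_top.mean * s_top.n_valid_px + s_bot.mean * s_bot.n_valid_px
    ) / (s_top.n_valid_px + s_bot.n_valid_px)
    assert s_full.mean == pytest.approx(pooled)


def test_summary_errors_when_no_valid_pixels():
    maps = mapset_from(np.full((4, 4), np.nan))
    roi = ROIMask(mask=np.ones((4, 4), bool), name="MCA")
    with pytest.raises(ValueError, match="MCA"):
        summarize_roi(maps, roi)


class TestComparePrePost:
    def _pair(self, pre_field, post_field):
        return mapset_from(pre_field), mapset_from(post_field)

    def test_constructed_shift_recovered_and_significant(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(6.0, 0.8, (40, 40))
        pre_m, post_m = self._pair(pre, pre - 1.2)
        roi = ROIMask(mask=np.ones((40, 40), bool))
        comp = compare_pre_post(pre_m, post_m, roi).metrics[Metric.AT]
        assert comp.delta_mean == pytest.approx(-1.2, abs=1e-9)
        assert comp.significant and comp.p_value < 1e-10

    def test_identical_distributions_give_null_delta(self):
        rng = np.random.default_rng(2)
        pre = rng.normal(4, 1, (30, 30))
        pre_m, post_m = self._pair(pre, pre)
        roi = ROIMask(mask=np.ones((30, 30), bool))
        comp = compare_pre_post(pre_m, post_m, roi).metrics[Metric.TTP]
        assert comp.delta_mean == 0.0
        assert comp.p_value == pytest.approx(1.0)
        assert not comp.significant

    def test_delta_antisymmetry_under_pre_post_swap(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(5, 1, (25, 25))
        post = rng.normal(4.4, 1.3, (25, 25))
        pre_m, post_m = self._pair(pre, post)
        roi = ROIMask(mask=np.ones((25, 25), bool))
        fwd = compare_pre_post(pre_m, post_m, roi)
        rev = compare_pre_post(post_m, pre_m, roi)
        for m in Metric:
            assert fwd.metrics[m].delta_mean == pytest.approx(
                -rev.metrics[m].delta_mean
            )
            assert fwd.metrics[m].p_value == pytest.approx(rev.metrics[m].p_value)

    def test_welch_ci_halfwidth_matches_closed_form(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (20, 20))
        b = rng.normal(0.5, 2, (20, 20))
        pre_m, post_m = self._pair(a, b)
        roi = ROIMask(mask=np.ones((20, 20), bool))
        comp = compare_pre_post(pre_m, post_m, roi).metrics[Metric.AT]
        x, y = b.ravel(), a.ravel()
        se2 = x.var(ddof=1) / x.size + y.var(ddof=1) / y.size
        df = se2**2 / (
            (x.var(ddof=1) / x.size) ** 2 / (x.size - 1)
            + (y.var(ddof=1) / y.size) ** 2 / (y.size - 1)
        )
        assert comp.ci95_halfwidth == pytest.approx(
            stats.t.ppf(0.975, df) * np.sqrt(se2)
        )
        t_sp, p_sp = stats.ttest_ind(x, y, equal_var=False)
        assert comp.p_value == pytest.approx(p_sp)

    def test_welch_p_uniform_under_null(self):
        """p-values on null normal samples pass a KS uniformity check."""
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            a = rng.standard_normal(10_000)
            b = rng.standard_normal(10_000)
            ps.append(stats.ttest_ind(a, b, equal_var=False).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestAggregateCases:
    def _comp(self, delta):
        pre = np.full((6, 6), 5.0)
        rng = np.random.default_rng(int(abs(delta * 1000)) + 1)
        pre = pre + rng.normal(0, 0.1, pre.shape)
        pre_m = mapset_from(pre)
        post_m = mapset_from(pre + delta)
        roi = ROIMask(mask=np.ones((6, 6), bool), name="MCA", view=View.AP)
        return compare_pre_post(pre_m, post_m, roi)

    def test_three_cases_closed_form_t_ci(self):
        comps = [self._comp(d) for d in (-1.0, 0.0, 1.0)]
        agg = aggregate_cases(comps, "MCA", View.AP)[Metric.AT]
        deltas = np.array([c.metrics[Metric.AT].delta_mean for c in comps])
        assert agg["mean_delta"] == pytest.approx(deltas.mean())
        expected_hw = stats.t.ppf(0.975, 2) * deltas.std(ddof=1) / np.sqrt(3)
        assert agg["ci95_halfwidth"] == pytest.approx(expected_hw)

    def test_single_case_ci_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="single case"):
            agg = aggregate_cases([self._comp(-0.5)], "MCA", View.AP)
        assert np.isnan(agg[Metric.AT]["ci95_halfwidth"])

    def test_identical_deltas_give_zero_halfwidth(self):
        comps = [self._comp(0.7) for _ in range(3)]
        agg = aggregate_cases(comps, "MCA", View.AP)[Metric.AT]
        assert agg["ci95_halfwidth"] == pytest.approx(0.0, abs=1e-12)
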