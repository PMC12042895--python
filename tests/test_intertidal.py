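"""Gompertz fits, smoothing splines, Welch t tests, pre/post summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from otterforage import (
    census_prepost,
    fit_gompertz,
    fit_trend_spline,
    prepost_summary,
    simulate_census,
    simulate_intertidal,
    welch_t_test,
)
from otterforage.synthetic import CensusConfig, CensusSeries, IntertidalConfig


def _gompertz(t, A, b, k):
    return A * np.exp(-b * np.exp(-k * t))


class TestGompertz:
    def test_noiseless_parameter_recovery(self):
        years = np.arange(2001, 2011)
        y = _gompertz(years - 2001, 5.0, 2.0, 0.8)
        fit = fit_gompertz(years, y)
        assert abs(fit.A - 5.0) / 5.0 < 1e-4
        assert abs(fit.b - 2.0) / 2.0 < 1e-4
        assert abs(fit.k - 0.8) / 0.8 < 1e-4
        assert np.max(np.abs(fit.fitted_values - y)) < 1e-6

    def test_prediction_approaches_asymptote(self):
        years = np.arange(2001, 2011)
        fit = fit_gompertz(years, _gompertz(years - 2001, 5.0, 2.0, 0.8))
        assert fit.predict([4000])[0] == pytest.approx(fit.A, rel=1e-9)

    def test_extrapolation_monotone_for_growth(self):
        years = np.arange(2001, 2008)
        y = _gompertz(years - 2001, 6.0, 3.0, 0.45)
        fit = fit_gompertz(years, y)
        ext = fit.extrapolate(2008, 2012)["value"].to_numpy()
        assert np.all(np.diff(ext) >= 0)

    def test_noise_recovery_degrades_gracefully(self, rng):
        years = np.arange(2001, 2016)
        clean = _gompertz(years - 2001, 5.0, 2.0, 0.8)
        err = {}
        for sd in (0.5, 0.01):
            errs = [
                abs(fit_gompertz(
                    years,
                    np.clip(clean + rng.normal(0, sd, years.size), 0, None),
                ).A - 5.0)
                for _ in range(10)
            ]
            err[sd] = np.mean(errs)
        assert err[0.01] < err[0.5]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_gompertz([2001, 2002, 2003], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_gompertz(np.arange(2001, 2011), np.full(10, 3.0))


class TestTrendSpline:
    def test_reproduces_linear_data(self):
        x = np.arange(2000, 2020)
        y = 2.0 * (x - 2000) + 5.0
        trend = fit_trend_spline(x, y, stderr_band=False)
        assert np.max(np.abs(trend.fitted - y)) < 1e-8

    def test_infinite_smoothing_approaches_least_squares_line(self, rng):
        # the cubic-spline roughness penalty drives the fit to the straight
        # line that minimizes squared error, not to the series mean
        x = np.arange(2000, 2021).astype(float)
        y = np.sin(0.7 * (x - 2000)) + 0.1 * (x - 2000)
        trend = fit_trend_spline(x, y, lam=1e12, stderr_band=False)
        line = np.polyval(np.polyfit(x, y, 1), x)
        assert np.max(np.abs(trend.fitted - line)) < 1e-3

    def test_detects_step_increase(self, rng):
        x = np.arange(2000, 2025).astype(float)
        y = np.where(x >= 2014, 535.0, 373.0) + rng.normal(0, 30, x.size)
        trend = fit_trend_spline(x, y, seed=0)
        assert trend.fitted[x >= 2014].mean() > trend.fitted[x < 2014].mean()
        assert trend.stderr is not None and np.all(trend.stderr > 0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_trend_spline([1, 2, 3], [1, 2, 3])


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_textbook_pair_matches_reference(self):
        a, b = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        res = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert abs(res.t - ref.statistic) < 1e-10
        assert abs(res.p - ref.pvalue) < 1e-10
        assert abs(res.df - ref.df) < 1e-10

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_reference_on_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(r.uniform(-2, 2), r.uniform(0.5, 3), r.integers(2, 40))
        b = r.normal(r.uniform(-2, 2), r.uniform(0.5, 3), r.integers(2, 40))
        res = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert abs(res.t - ref.statistic) < 1e-10
        assert abs(res.p - ref.pvalue) < 1e-10

    def test_sign_follows_mean_difference(self, rng):
        res = welch_t_test(rng.normal(0, 1, 50), rng.normal(2, 1, 50))
        assert res.t < 0 and res.mean_pre < res.mean_post

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestPrePostSummary:
    @pytest.fixture(scope="class")
    def surveys(self):
        return simulate_intertidal(seed=12)

    def test_encoded_downshore_shift_detected(self, surveys):
        out = prepost_summary(surveys)
        d = out.comparisons["distance"]
        assert d.mean_post > d.mean_pre
        assert d.t < 0 and d.p < 0.001
        s = out.comparisons["size"]
        assert s.mean_post > s.mean_pre

    def test_null_configuration_mostly_insignificant(self):
        cfg = IntertidalConfig(
            distance_post=(9.59, 4.60), size_post=(37.5, 13.8),
            cover_post=(5.36, 2.5), presence_scale_post=0.30,
        )
        out = prepost_summary(simulate_intertidal(cfg, seed=4))
        ps = [c.p for c in out.comparisons.values()]
        assert sum(p > 0.05 for p in ps) >= 2

    def test_welch_df_below_pooled_df(self, surveys):
        c = prepost_summary(surveys).comparisons["cover"]
        assert c.df < c.n_pre + c.n_post - 2

    def test_invariant_to_order_and_site_labels(self, surveys):
        base = prepost_summary(surveys).comparisons
        relabeled = []
        import dataclasses

        for s in reversed(surveys):
            relabeled.append(dataclasses.replace(s, site_id="x_" + s.site_id))
        alt = prepost_summary(relabeled).comparisons
        for k in base:
            assert base[k].t == pytest.approx(alt[k].t, rel=1e-12)

    def test_frequency_tables_conserve_counts(self, surveys):
        out = prepost_summary(surveys)
        n_sizes = sum(
            len(s.mussel_sizes_mm) for s in surveys if 2009 <= s.year <= 2021
        )
        assert out.tables["size"]["count"].sum() == n_sizes

    def test_empty_period_rejected(self, surveys):
        late = [s for s in surveys if s.year >= 2013]
        with pytest.raises(ValueError):
            prepost_summary(late)


class TestCensusPrePost:
    def test_constant_series_zero_sd(self):
        c = simulate_census(CensusConfig(pre_sd=0.0, post_sd=0.0), seed=0)
        out = census_prepost(c)
        assert np.all(out["sd"] == 0.0)

    def test_default_growth_detected(self):
        out = census_prepost(simulate_census(seed=3))
        pre = out.loc[out.period == "pre"].iloc[0]
        post = out.loc[out.period == "post"].iloc[0]
        assert post["mean"] > pre["mean"]

    def test_missing_years_excluded_from_n(self):
        out = census_prepost(simulate_census(seed=3), cutoff=2013)
        # 2000-2012 minus the 2011 gap; 2014-2024 minus the 2020 gap
        assert int(out.loc[out.period == "pre", "n"].iloc[0]) == 12
        assert int(out.loc[out.period == "post", "n"].iloc[0]) == 10

    def test_empty_period_rejected(self):
        c = CensusSeries(years=np.arange(2014, 2020), counts=np.full(6, 500))
        with pytest.raises(ValueError):
            census_prepost(c, cutoff=2013)
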