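"""Excess deaths, log relative risk, regressions, classical comparator."""

import numpy as np
import pandas as pd
import pytest

from hhtexcess.emd import IMFSet, emd
from hhtexcess.excess import (
    EventWindow,
    RegressionSpec,
    classical_decompose,
    excess_deaths,
    fit_excess_regression,
    log_relative_risk,
    match_temperature_partition,
    partition_series,
    run_excess_pipeline,
)
from hhtexcess.significance import TrendPartition, classify_trend
from hhtexcess.synthetic import MortalityScenario, gen_mortality
from hhtexcess.timeseries import TimeSeries


@pytest.fixture(scope="module")
def subtropical_city():
    mort, maxT, pm10, o3, truth = gen_mortality(MortalityScenario(seed=0))
    return mort, maxT, truth


class TestPartition:
    def test_m_equals_n_minus_one(self):
        rng = np.random.default_rng(0)
        d = emd(rng.standard_normal(512))
        p = TrendPartition(m=d.n_imfs - 1, n_imfs=d.n_imfs, mode="white", level=95)
        non_trend, trend = partition_series(d, p)
        assert np.allclose(trend, d.imfs[-1] + d.residual)
        assert np.allclose(non_trend, d.imfs[:-1].sum(axis=0))

    def test_conservation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1024)
        d = emd(x)
        p, _ = classify_trend(d)
        non_trend, trend = partition_series(d, p)
        assert np.abs(non_trend + trend - x).max() <= 1e-8 * np.abs(x).max()

    def test_spike_lands_in_detail(self, subtropical_city):
        mort, _, truth = subtropical_city
        d = emd(mort)
        p, _ = classify_trend(d)
        non_trend, _ = partition_series(d, p)
        hw = truth["heatwaves"][0]
        sl = mort.window_slice(hw["start"], hw["end"])
        # the detail series is mean-zero off-window; the spike dominates inside
        assert non_trend[sl].mean() > 5.0
        assert abs(np.delete(non_trend, sl).mean()) < 0.5

    def test_mismatched_partition_rejected(self):
        d = emd(np.random.default_rng(2).standard_normal(512))
        p = TrendPartition(m=1, n_imfs=d.n_imfs + 1, mode="white", level=95)
        with pytest.raises(ValueError):
            partition_series(d, p)


class TestExcessDeaths:
    def test_six_day_heatwave_worked_example(self):
        # the six peak-heatwave days: detail values sum to 51.8, rounding 52
        daily = [5.7, 6.7, 7.6, -0.4, 20.6, 11.6]
        values = np.zeros(30)
        values[10:16] = daily
        ts = TimeSeries.from_start("2004-02-08", values)
        total, rounded = excess_deaths(ts, EventWindow("2004-02-18", "2004-02-23"))
        assert total == pytest.approx(51.8)
        assert rounded == 52

    @pytest.mark.parametrize(
        "total, rounded", [(0.5, 1), (-0.5, -1), (2.49, 2), (-2.51, -3)]
    )
    def test_rounding_half_away_from_zero(self, total, rounded):
        values = np.zeros(10)
        values[3] = total
        ts = TimeSeries.from_start("2000-01-01", values)
        t, r = excess_deaths(ts, EventWindow("2000-01-04", "2000-01-04"))
        assert (t, r) == (pytest.approx(total), rounded)

    def test_window_outside_range_rejected(self):
        ts = TimeSeries.from_start("2000-01-01", np.zeros(10))
        with pytest.raises(ValueError):
            excess_deaths(ts, EventWindow("1999-12-01", "1999-12-05"))

    def test_detail_series_integrates_to_near_zero(self, subtropical_city):
        mort, _, _ = subtropical_city
        d = emd(mort)
        p, _ = classify_trend(d)
        non_trend, _ = partition_series(d, p)
        ts = TimeSeries(mort.dates, non_trend)
        total, _ = excess_deaths(
            ts, EventWindow(mort.dates[0], mort.dates[-1])
        )
        assert abs(total) <= 0.02 * np.abs(mort.values).sum()


class TestLogRelativeRisk:
    def test_equal_series_gives_zeros(self):
        trend = np.full(20, 30.0)
        assert np.allclose(log_relative_risk(trend, trend), 0.0)

    def test_e_fold_gives_ones(self):
        trend = np.full(20, 10.0)
        assert np.allclose(log_relative_risk(np.e * trend, trend), 1.0)

    def test_zero_count_propagates_neg_inf_with_warning(self):
        x = np.array([10.0, 0.0, 10.0])
        trend = np.full(3, 10.0)
        with pytest.warns(UserWarning):
            rr = log_relative_risk(x, trend)
        assert rr[1] == -np.inf

    def test_zero_count_continuity_correction(self):
        x = np.array([10.0, 0.0, 10.0])
        trend = np.full(3, 10.0)
        rr = log_relative_risk(x, trend, zero_correction=True)
        assert rr[1] == pytest.approx(np.log(0.5 / 10.0))

    def test_nonpositive_trend_names_position(self):
        with pytest.raises(ValueError, match="index 1"):
            log_relative_risk(np.ones(3), np.array([1.0, 0.0, 1.0]))


class TestRegression:
    @staticmethod
    def _spec(n=91):
        start = pd.Timestamp("2003-12-01")
        return RegressionSpec(
            covariates=("maxT",),
            window=EventWindow(start, start + pd.Timedelta(days=n - 1)),
        )

    def test_noiseless_exact_fit(self):
        x = np.linspace(20, 40, 91)
        y = 0.05 * x
        ts_y = TimeSeries.from_start("2003-12-01", y)
        ts_x = TimeSeries.from_start("2003-12-01", x)
        res = fit_excess_regression(self._spec(), ts_y, {"maxT": ts_x})
        assert res.coefficients["maxT"] == pytest.approx(0.05)
        assert res.adjusted_r_squared == pytest.approx(1.0)

    def test_null_association(self):
        rng = np.random.default_rng(0)
        r2 = []
        for _ in range(20):
            y = rng.standard_normal(91)
            x = rng.normal(28, 4, 91)
            res = fit_excess_regression(
                self._spec(),
                TimeSeries.from_start("2003-12-01", y),
                {"maxT": TimeSeries.from_start("2003-12-01", x)},
            )
            r2.append(res.adjusted_r_squared)
        assert abs(np.mean(r2)) <= 0.1

    def test_slope_recovery_within_two_se(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(50):
            anomaly = rng.normal(0, 3, 91)
            y = 0.06 * anomaly + rng.normal(0, 0.15, 91)
            res = fit_excess_regression(
                RegressionSpec(
                    covariates=("maxT_non_trend",), window=self._spec().window
                ),
                TimeSeries.from_start("2003-12-01", y),
                {"maxT_non_trend": TimeSeries.from_start("2003-12-01", anomaly)},
            )
            se = res.std_errors["maxT_non_trend"]
            hits += abs(res.coefficients["maxT_non_trend"] - 0.06) <= 2 * se
        assert hits >= 45

    def test_rank_deficient_design_rejected(self):
        x = np.linspace(0, 1, 91)
        spec = RegressionSpec(covariates=("maxT", "PM10"), window=self._spec().window)
        with pytest.raises(ValueError, match="rank"):
            fit_excess_regression(
                spec,
                TimeSeries.from_start("2003-12-01", x),
                {
                    "maxT": TimeSeries.from_start("2003-12-01", x),
                    "PM10": TimeSeries.from_start("2003-12-01", 2 * x),
                },
            )

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError):
            RegressionSpec(covariates=("humidity",), window=self._spec().window)


class TestClassicalDecompose:
    def test_end_window_geometry(self):
        x = np.random.default_rng(0).standard_normal(900)
        trend, _, random = classical_decompose(x, 365)
        assert np.isnan(trend[:182]).all() and np.isfinite(trend[182])
        assert np.isnan(trend[-182:]).all() and np.isfinite(trend[-183])

    def test_periodic_signal_recovered_as_seasonal(self):
        t = np.arange(365 * 4)
        signal = 3 * np.sin(2 * np.pi * t / 365)
        trend, seasonal, random = classical_decompose(signal, 365)
        ok = np.isfinite(trend)
        assert np.corrcoef(seasonal[ok], signal[ok])[0, 1] >= 0.99
        assert np.abs(random[ok]).max() <= 0.05

    def test_conservation_where_defined(self):
        x = np.random.default_rng(1).standard_normal(800) + 10
        trend, seasonal, random = classical_decompose(x, 365)
        ok = np.isfinite(trend)
        assert np.allclose((trend + seasonal + random)[ok], x[ok])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            classical_decompose(np.zeros(700), 365)


class TestPipeline:
    def test_recovers_spike_mass_roughly(self, subtropical_city):
        mort, _, truth = subtropical_city
        hw = truth["heatwaves"][0]
        res = run_excess_pipeline(mort, EventWindow(hw["start"], hw["end"]))
        assert 20 <= res.total_excess <= 80
        assert res.total_excess_rounded == round(res.total_excess)

    def test_mean_preservation(self, subtropical_city):
        # trend side carries the mean level; the detail is mean-zero
        mort, _, _ = subtropical_city
        res = run_excess_pipeline(
            mort, EventWindow(mort.dates[100], mort.dates[120])
        )
        assert abs(res.trend.mean() - mort.values.mean()) <= 0.02 * mort.values.mean()
        assert abs(res.non_trend.mean()) <= 0.02 * mort.values.mean()

    def test_hht_detail_defined_where_classical_random_is_not(self, subtropical_city):
        # spike sits in the final 134 days: inside the classical comparator's
        # undefined end window, but fully covered by the adaptive detail
        mort, _, truth = subtropical_city
        hw = truth["heatwaves"][0]
        sl = mort.window_slice(hw["start"], hw["end"])
        _, _, random = classical_decompose(mort.values, 365)
        assert np.isnan(random[sl]).all()
        res = run_excess_pipeline(mort, EventWindow(hw["start"], hw["end"]))
        assert np.isfinite(res.non_trend).all()

    def test_temperature_partition_matches_mortality_band(self, subtropical_city):
        mort, maxT, _ = subtropical_city
        d_m = emd(mort)
        p_m, _ = classify_trend(d_m)
        d_t = emd(maxT)
        m_t = match_temperature_partition(d_t, d_m, p_m)
        assert 1 <= m_t <= d_t.n_imfs
        assert abs(m_t - p_m.m) <= 2  # same frequency band, similar order count
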