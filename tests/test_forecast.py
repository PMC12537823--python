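"""Snapshot series building, AICc, ARIMA fitting/forecasting, validation."""

import numpy as np
import pandas as pd
import pytest

from specimentrends import forecast as fc
from specimentrends.errors import ConfigurationError, DataError


def obs_table(rows):
    df = pd.DataFrame(rows, columns=["snapshot_time", "collection_year", "count"])
    df["institution"] = pd.NA
    return df


def make_series(counts, first_time=2007, year=1980):
    counts = np.asarray(counts, dtype=float)
    return fc.SnapshotSeries(
        collection_year=year,
        times=np.arange(first_time, first_time + len(counts)),
        counts=counts,
    )


class TestBuildSnapshotSeries:
    def test_one_series_per_collection_year(self):
        obs = obs_table(
            [(2007, 1950, 100), (2008, 1950, 120), (2007, 1951, 90), (2008, 1951, 95)]
        )
        out = fc.build_snapshot_series(obs, (1950, 1951))
        assert sorted(out) == [1950, 1951]

    def test_institutions_are_summed(self):
        obs = pd.DataFrame(
            {
                "snapshot_time": [2007, 2007, 2008],
                "collection_year": [1950, 1950, 1950],
                "institution": ["I1", "I2", "I1"],
                "count": [120, 180, 300],
            }
        )
        out = fc.build_snapshot_series(obs, (1950, 1950))
        assert out[1950].counts[0] == 300.0

    def test_seventeen_annual_snapshots_make_length_17(self):
        obs = obs_table([(t, 1950, 100 + t - 2007) for t in range(2007, 2024)])
        out = fc.build_snapshot_series(obs, (1950, 1950))
        assert len(out[1950].counts) == 17

    def test_missing_leading_snapshots_are_zero_then_interpolated(self):
        # year absent until 2010, missing 2011, observed 2012
        obs = obs_table(
            [(t, 1950, c) for t, c in [(2010, 50), (2012, 70)]]
            + [(t, 1951, 10) for t in range(2007, 2013)]
        )
        out = fc.build_snapshot_series(obs, (1950, 1951))
        s = out[1950]
        assert list(s.counts[:3]) == [0.0, 0.0, 0.0]  # 2007-2009 pre-appearance
        assert s.counts[4] == 60.0  # 2011 linearly interpolated
        assert s.interpolated[4]

    def test_empty_range_rejected(self):
        with pytest.raises(ConfigurationError):
            fc.build_snapshot_series(obs_table([(2007, 1950, 1), (2008, 1950, 1)]), (1960, 1950))


class TestAicc:
    def test_hand_computed_value(self):
        assert fc.aicc(-10.0, 2, 10) == pytest.approx(24 + 12 / 7)

    def test_zero_params_is_minus_two_loglike(self):
        assert fc.aicc(-10.0, 0, 10) == 20.0

    def test_converges_to_aic_for_large_n(self):
        aic = -2 * (-10.0) + 2 * 3
        assert fc.aicc(-10.0, 3, 10_000_000) == pytest.approx(aic, abs=1e-4)

    def test_undefined_when_overparameterised(self):
        assert np.isnan(fc.aicc(-10.0, 9, 10))


class TestFitArima:
    def test_constant_series_forecasts_the_constant(self):
        fit = fc.fit_arima(make_series([50.0] * 10), d=1, max_p=1, max_q=1)
        out = fc.forecast(fit, 5)
        assert np.allclose(out.mean, 50.0, atol=1e-6)

    def test_short_series_low_order_without_error(self):
        fit = fc.fit_arima(make_series([10, 12, 13, 15]), d=1, max_p=2, max_q=2)
        assert fit.spec.d == 1

    def test_grid_winner_never_worse_than_random_walk(self, rng):
        for _ in range(10):
            y = 100 + np.cumsum(rng.normal(2, 5, 17))
            series = make_series(y)
            best = fc.fit_arima(series, d=1, max_p=2, max_q=2)
            baseline = fc.fit_arima(series, d=1, orders=[(0, 1, 0)])
            assert best.aicc <= baseline.aicc + 1e-9

    def test_too_short_for_differencing_rejected(self):
        with pytest.raises(DataError):
            fc.fit_arima(make_series([1, 2, 3]), d=1)


class TestForecast:
    def test_random_walk_closed_forms(self, rng):
        y = 100 + np.cumsum(rng.normal(0, 3, 25))
        fit = fc.fit_arima(make_series(y), d=1, orders=[(0, 1, 0)])
        out = fc.forecast(fit, 8)
        sigma = np.sqrt(fit.result.params[-1])
        assert np.max(np.abs(out.mean - y[-1])) < 1e-8
        assert np.max(np.abs(out.se - sigma * np.sqrt(np.arange(1, 9)))) < 1e-8

    def test_white_noise_with_d0_forecasts_near_sample_mean(self, rng):
        y = 10 + rng.normal(0, 1, 40)
        fit = fc.fit_arima(make_series(y), d=0, orders=[(0, 0, 0)])
        out = fc.forecast(fit, 3)
        assert np.allclose(out.mean, y.mean(), atol=1e-3)

    def test_intervals_bracket_mean_and_widen(self, rng):
        y = 100 + np.cumsum(rng.normal(1, 4, 17))
        fit = fc.fit_arima(make_series(y), d=1, max_p=2, max_q=2)
        out = fc.forecast(fit, 10)
        assert (out.lower95 <= out.mean + 1e-12).all()
        assert (out.mean <= out.upper95 + 1e-12).all()
        widths = out.upper95 - out.lower95
        assert (np.diff(widths) >= -1e-9).all()

    def test_negative_means_reported_and_floored_separately(self):
        y = np.array([100, 80, 60, 40, 20, 10, 5, 2, 1, 0.5])
        fit = fc.fit_arima(make_series(y), d=1, max_p=1, max_q=0)
        out = fc.forecast(fit, 10)
        assert (out.mean_floored >= 0).all()


class TestRmspe:
    def test_zero_iff_identical(self):
        assert fc.rmspe([1, 2, 3], [1, 2, 3]) == 0.0
        assert fc.rmspe([1, 2], [2, 4]) == pytest.approx(np.sqrt(2.5))

    def test_constant_offset(self):
        assert fc.rmspe([5] * 7, [8] * 7) == pytest.approx(3.0)

    def test_symmetry_and_mismatch(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=9)
        assert fc.rmspe(a, b) == pytest.approx(fc.rmspe(b, a))
        with pytest.raises(DataError):
            fc.rmspe([1, 2], [1, 2, 3])


class TestValidation:
    def test_single_heldout_point_equals_absolute_error(self):
        # deterministic staircase: training part flat, so the d=1 forecast
        # stays at the cutoff value and the error is the later jump
        counts = [100.0] * 8 + [130.0] * 9
        series_map = {1950: make_series(counts)}
        report = fc.validate_in_sample(
            series_map, train_cutoff=2013, horizons=[5], d_options=(1,),
            max_p=0, max_q=0,
        )
        row = report.table.iloc[0]
        assert row["rmspe"] == pytest.approx(30.0)
        assert row["n_series"] == 1

    def test_noise_free_flat_series_scores_zero(self):
        series_map = {1950: make_series([200.0] * 17)}
        report = fc.validate_in_sample(
            series_map, train_cutoff=2013, horizons=[5, 10], d_options=(1,),
            max_p=0, max_q=0,
        )
        assert (report.table["rmspe"] == 0.0).all()

    def test_short_series_counted_as_skipped(self):
        series_map = {
            1950: make_series([1.0, 2.0, 3.0], first_time=2011),
            1951: make_series([100.0] * 17),
        }
        report = fc.validate_in_sample(
            series_map, train_cutoff=2013, horizons=[5], d_options=(1,),
            max_p=0, max_q=0,
        )
        assert report.n_skipped == 1


class TestForecastDecline:
    def _flat_forecasts(self, values):
        out = {}
        for year, v in values.items():
            out[year] = fc.ForecastResult(
                collection_year=year,
                times=np.array([2033]),
                mean=np.array([v], dtype=float),
                se=np.zeros(1),
                lower95=np.array([v], dtype=float),
                upper95=np.array([v], dtype=float),
                spec=fc.ArimaSpec(0, 1, 0),
                aicc=0.0,
            )
        return out

    def test_identity_propagation(self):
        from specimentrends.trends import PeakWindow, decline_percent

        observed = {y: 1000.0 for y in range(1964, 1969)}
        observed.update({y: 530.0 for y in range(2010, 2020)})
        forecasts = self._flat_forecasts(observed)
        peak = PeakWindow(1964, 1968, 1000.0)
        got = fc.forecast_decline(forecasts, peak, (2010, 2019), 2033)
        assert got == pytest.approx(decline_percent(530.0, 1000.0))

    def test_uniform_growth_shrinks_decline_algebraically(self):
        from specimentrends.trends import PeakWindow

        base = {y: 1000.0 for y in range(1964, 1969)}
        base.update({y: 500.0 for y in range(2010, 2020)})
        peak = PeakWindow(1964, 1968, 1000.0)
        d0 = fc.forecast_decline(self._flat_forecasts(base), peak, (2010, 2019), 2033)
        grown = dict(base)
        for y in range(2010, 2020):
            grown[y] = base[y] * 1.1
        d1 = fc.forecast_decline(self._flat_forecasts(grown), peak, (2010, 2019), 2033)
        assert 100 - d1 == pytest.approx((100 - d0) * 1.1)

    def test_missing_years_listed(self):
        from specimentrends.trends import PeakWindow

        forecasts = self._flat_forecasts({y: 1.0 for y in range(1964, 1969)})
        with pytest.raises(DataError, match="2010"):
            fc.forecast_decline(forecasts, PeakWindow(1964, 1968, 1.0), (2010, 2019), 2033)
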