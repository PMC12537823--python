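"""Yearly metrics, peak windows, declines, grid change map and LOESS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from specimentrends import trends as tr
from specimentrends.errors import ConfigurationError, DataError


def series(d):
    return pd.Series(d).sort_index()


class TestYearlyCounts:
    def test_counts_by_year(self, records_factory):
        df = records_factory([("A b", 1950, 0, 0, "I")] * 2 + [("A b", 1951, 0, 0, "I")])
        assert tr.yearly_counts(df).to_dict() == {1950: 2, 1951: 1}

    def test_zero_fill_on_span(self, records_factory):
        df = records_factory([])
        out = tr.yearly_counts(df, span=(1950, 1952))
        assert out.to_dict() == {1950: 0, 1951: 0, 1952: 0}

    def test_conservation(self, records_factory, rng):
        rows = [(f"S {i}", int(rng.integers(1950, 1955)), 0, 0, "I") for i in range(100)]
        assert tr.yearly_counts(records_factory(rows)).sum() == 100


class TestUniqueSpecies:
    def test_distinct_count(self, records_factory):
        df = records_factory(
            [("A", 1950, 0, 0, "I"), ("A", 1950, 0, 0, "I"), ("B", 1950, 0, 0, "I")]
        )
        assert tr.unique_species_per_year(df).loc[1950] == 2

    def test_upper_bound_attained_when_all_distinct(self, records_factory):
        df = records_factory([(f"S {i}", 1950, 0, 0, "I") for i in range(7)])
        assert tr.unique_species_per_year(df).loc[1950] == 7

    def test_matches_set_cardinality_oracle(self, records_factory, rng):
        pool = [f"Sp {i}" for i in range(50)]
        chosen = [pool[i] for i in rng.integers(0, 50, 200)]
        df = records_factory([(s, 1950, 0, 0, "I") for s in chosen])
        assert tr.unique_species_per_year(df).loc[1950] == len(set(chosen))


class TestGridIndex:
    @pytest.mark.parametrize(
        "lat,lon,expected",
        [
            (0.5, 0.5, (0, 0)),
            (-35.3, 149.1, (-36, 149)),
            (90.0, 180.0, (89, 179)),
            (-90.0, -180.0, (-90, -180)),
        ],
    )
    def test_floor_cells_with_boundary_clamp(self, lat, lon, expected):
        assert tr.grid_index(lat, lon) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            tr.grid_index(91.0, 0.0)

    @given(
        lat=hst.floats(-90, 90, allow_nan=False),
        lon=hst.floats(-180, 180, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_every_valid_point_maps_to_one_cell(self, lat, lon):
        li, lo = tr.grid_index(lat, lon)
        assert -90 <= li <= 89 and -180 <= lo <= 179
        # the point lies in the half-open cell, modulo boundary clamping
        assert li <= lat <= li + 1 and lo <= lon <= lo + 1


class TestSpatialExtent:
    def test_same_cell_counted_once(self, records_factory):
        df = records_factory([("A", 1950, 10.2, 20.7, "I")] * 3)
        assert tr.spatial_extent_per_year(df).loc[1950] == 1

    def test_half_open_cells(self, records_factory):
        df = records_factory(
            [("A", 1950, 0.1, 0.1, "I"), ("B", 1950, 0.9, 0.9, "I")]
        )
        assert tr.spatial_extent_per_year(df).loc[1950] == 1

    def test_matches_floor_pair_oracle(self, records_factory, rng):
        lat = rng.uniform(-10, 10, 500)
        lon = rng.uniform(-10, 10, 500)
        df = records_factory(
            [("A", 1950, la, lo, "I") for la, lo in zip(lat, lon)]
        )
        oracle = len({(int(np.floor(a)), int(np.floor(b))) for a, b in zip(lat, lon)})
        assert tr.spatial_extent_per_year(df).loc[1950] == oracle


class TestMovingAverageAndPeak:
    def test_constant_series_every_window_equal(self):
        s = series({y: 7.0 for y in range(2000, 2010)})
        ma = tr.moving_average(s, 5)
        assert np.allclose(ma["window_mean"], 7.0)
        assert len(ma) == 6

    def test_single_window_mean(self):
        s = series(dict(zip(range(2000, 2005), [0, 0, 5, 0, 0])))
        ma = tr.moving_average(s, 5)
        assert len(ma) == 1
        assert ma.loc[0, "window_mean"] == 1.0

    def test_window_arithmetic(self):
        s = series(dict(zip(range(2000, 2006), [1, 2, 3, 4, 5, 6])))
        ma = tr.moving_average(s, 5)
        assert list(ma["window_mean"]) == [3.0, 4.0]
        assert list(ma["start_year"]) == [2000, 2001]

    def test_short_series_empty(self):
        assert len(tr.moving_average(series({2000: 1, 2001: 2}), 5)) == 0

    def test_tie_breaks_to_earliest(self):
        s = series(dict(zip(range(2000, 2006), [1, 1, 9, 1, 1, 1])))
        peak = tr.find_peak_window(s, 5)
        assert (peak.start_year, peak.end_year) == (2000, 2004)
        assert peak.window_mean == pytest.approx(2.6)

    def test_constant_series_earliest_window(self):
        peak = tr.find_peak_window(series({y: 3.0 for y in range(2000, 2010)}), 5)
        assert peak.start_year == 2000

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            vals = rng.integers(0, 100, n).astype(float)
            years = np.arange(1900, 1900 + n)
            s = pd.Series(vals, index=years)
            best = max(
                (
                    (vals[i : i + 5].sum() / 5, -i)
                    for i in range(n - 4)
                ),
            )
            peak = tr.find_peak_window(s, 5)
            assert peak.start_year == 1900 - best[1]
            assert peak.window_mean == pytest.approx(best[0])

    def test_invariant_to_appending_smaller_years(self):
        s = series(dict(zip(range(2000, 2010), [5, 6, 9, 9, 9, 9, 9, 2, 1, 1])))
        before = tr.find_peak_window(s, 5)
        extended = pd.concat([s, series({2010: 0, 2011: 0})])
        after = tr.find_peak_window(extended, 5)
        assert (before.start_year, before.window_mean) == (
            after.start_year,
            after.window_mean,
        )


class TestPeriodMeanAndDecline:
    def test_flat_period(self):
        s = series({y: 10 for y in range(2010, 2020)})
        assert tr.period_mean(s, 2010, 2019) == 10.0

    def test_zero_fill_inside_period(self):
        assert tr.period_mean(series({2010: 20}), 2010, 2011) == 10.0

    def test_direct_arithmetic(self, rng):
        vals = rng.integers(0, 100, 10)
        s = series(dict(zip(range(2010, 2020), vals)))
        assert tr.period_mean(s, 2010, 2019) == pytest.approx(vals.sum() / 10)

    @pytest.mark.parametrize(
        "recent,peak,expected",
        [
            (206_588, 389_900, 47.0),
            (661_760, 1_161_296, 43.0),
            (672_344, 924_910, 27.3),
            (5.0, 5.0, 0.0),
        ],
    )
    def test_one_decimal_values(self, recent, peak, expected):
        assert round(tr.decline_percent(recent, peak), 1) == expected

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(DataError):
            tr.decline_percent(1.0, 0.0)

    @given(
        a=hst.floats(0, 1e7, allow_nan=False),
        b=hst.floats(0.1, 1e7, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_decline_algebra(self, a, b):
        assert tr.decline_percent(a, b) + 100.0 * a / b == pytest.approx(100.0)


class TestGridChangeMap:
    def test_reference_heavy_cell(self, records_factory):
        rows = [("A", 1970 + (i % 40), 10.5, 20.5, "I") for i in range(40)]
        rows.append(("A", 2015, 10.5, 20.5, "I"))
        out = tr.grid_change_map(records_factory(rows))
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.lat_index, row.lon_index) == (10, 20)
        assert row.mean_reference == pytest.approx(1.0)
        assert row.mean_recent == pytest.approx(0.1)
        assert row.delta == pytest.approx(-0.9)

    def test_recent_only_cell(self, records_factory):
        rows = [("A", 2012, -5.5, 3.5, "I") for _ in range(10)]
        out = tr.grid_change_map(records_factory(rows))
        assert out.iloc[0].delta == pytest.approx(1.0)

    def test_overlapping_periods_rejected(self, records_factory):
        df = records_factory([("A", 2000, 0, 0, "I")])
        with pytest.raises(ConfigurationError):
            tr.grid_change_map(df, (2000, 2010), (2005, 2015))

    def test_two_cell_tally_oracle(self, records_factory, rng):
        rows = []
        for _ in range(200):
            cell = (10.5, 20.5) if rng.random() < 0.5 else (-3.5, 7.5)
            year = int(rng.integers(1970, 2020))
            rows.append(("A", year, cell[0], cell[1], "I"))
        df = records_factory(rows)
        out = tr.grid_change_map(df).set_index(["lat_index", "lon_index"])
        for cell_idx, lat in [((10, 20), 10.5), ((-4, 7), -3.5)]:
            sub = [r for r in rows if r[2] == lat]
            recent = sum(1 for r in sub if 2010 <= r[1] <= 2019) / 10
            refer = sum(1 for r in sub if 1970 <= r[1] <= 2009) / 40
            assert out.loc[cell_idx, "delta"] == pytest.approx(recent - refer)

    def test_weighted_delta_sum_matches_count_difference(self, records_factory, rng):
        rows = [
            ("A", int(rng.integers(1970, 2020)), float(rng.uniform(-20, 20)),
             float(rng.uniform(-20, 20)), "I")
            for _ in range(300)
        ]
        df = records_factory(rows)
        out = tr.grid_change_map(df)
        n_recent = sum(1 for r in rows if 2010 <= r[1] <= 2019)
        n_refer = sum(1 for r in rows if 1970 <= r[1] <= 2009)
        assert out["mean_recent"].sum() * 10 == pytest.approx(n_recent)
        assert out["mean_reference"].sum() * 40 == pytest.approx(n_refer)


class TestLoess:
    def test_reproduces_exact_line(self):
        s = series({y: 2.0 * y - 3500 for y in range(2000, 2030)})
        sm = tr.loess_smooth(s, span=0.5)
        assert np.allclose(sm, s, atol=1e-6)

    def test_constant_stays_constant(self):
        s = series({y: 42.0 for y in range(2000, 2020)})
        assert np.allclose(tr.loess_smooth(s, span=0.4), 42.0, atol=1e-8)

    def test_bad_span_rejected(self):
        s = series({y: 1.0 for y in range(2000, 2010)})
        with pytest.raises(ConfigurationError):
            tr.loess_smooth(s, span=0.0)

    def test_noisy_unimodal_peak_recovered_near_truth(self, rng):
        years = np.arange(1950, 2020)
        truth = 1000 * np.exp(-0.5 * ((years - 1984) / 12.0) ** 2)
        noisy = truth + rng.normal(0, 40, len(years))
        sm = tr.loess_smooth(pd.Series(noisy, index=years), span=0.3)
        assert abs(int(sm.idxmax()) - 1984) <= 4


class TestTrendModel:
    def test_metrics_invariants_on_synthetic_scenario(self, rng):
        from specimentrends.simulate import ScenarioConfig, simulate_records
        from specimentrends import io as sio

        records, _ = simulate_records(ScenarioConfig(n_institutions=5), rng)
        valid = sio.filter_valid(records)
        results = tr.CollectingTrendModel(valid, span=(1950, 2019)).fit()
        m = results.yearly_metrics
        assert m["specimen_count"].sum() == len(valid)
        assert (m["unique_species"] <= m["specimen_count"]).all()
        assert (m["grid_extent"] <= m["specimen_count"]).all()
        assert "decline" in results.summary().lower() or "%" in results.summary()
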