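"""Stocks, spans, CO2 equivalents, trends, area fractions, envelopes."""
import numpy as np
import pandas as pd
import pytest

from forestcarbon.accounting import (
    CO2_PER_PGC,
    EARTH_RADIUS_M,
    area_fraction,
    cell_areas,
    co2_equivalent,
    scenario_envelope,
    span_table,
    stock_series,
    total_stock,
    trend_slope_map,
)
from forestcarbon.grids import GridCube, GridGeometry


class TestCellAreas:
    def test_equatorial_cell_closed_form(self):
        # 0.01 deg x 0.01 deg straddling the equator on a R=6371 km sphere
        geom = GridGeometry(0.005, 0.0, 0.01, 1, 1)
        dlam = np.deg2rad(0.01)
        expected = EARTH_RADIUS_M**2 * dlam * 2 * np.sin(np.deg2rad(0.005)) / 1e4
        areas = cell_areas(geom)
        assert areas[0, 0] == pytest.approx(expected, rel=1e-12)
        assert areas[0, 0] == pytest.approx(123.6, abs=0.1)  # ~123.6 ha

    def test_area_shrinks_with_latitude(self):
        geom = GridGeometry(60.0, 0.0, 0.5, 100, 3)
        areas = cell_areas(geom)
        col = areas[:, 0]
        # rows run north (60N) to south (10N): area grows toward the equator
        assert np.all(np.diff(col) > 0)
        assert np.all(areas == areas[:, :1])  # no longitude dependence

    def test_band_sum_matches_analytic_band_area(self):
        # all cells between two latitudes must tile the spherical band
        geom = GridGeometry(30.0, 0.0, 0.25, 40, 1440)  # 30N..20N, full circle
        total = cell_areas(geom).sum()
        band = (2 * np.pi * EARTH_RADIUS_M**2
                * (np.sin(np.deg2rad(30)) - np.sin(np.deg2rad(20)))) / 1e4
        assert total == pytest.approx(band, rel=1e-9)


class TestTotalStock:
    def test_uniform_density_closed_form(self):
        # 100 Mg/ha over 1e6 ha = 1e8 Mg = 0.1 Pg C
        density = np.full((10, 10), 100.0)
        areas = np.full((10, 10), 1e4)  # 1e6 ha total
        assert total_stock(density, areas) == pytest.approx(0.1, rel=1e-12)

    def test_linearity_and_zero(self, rng):
        density = rng.uniform(0, 200, (5, 5))
        areas = rng.uniform(50, 150, (5, 5))
        s = total_stock(density, areas)
        assert total_stock(2 * density, areas) == pytest.approx(2 * s, rel=1e-12)
        assert total_stock(np.zeros((5, 5)), areas) == 0.0

    def test_masked_pixels_excluded(self):
        density = np.array([[100.0, np.nan]])
        areas = np.array([[1e4, 1e4]])
        assert total_stock(density, areas) == pytest.approx(1e-3)


class TestSpanTable:
    def _series(self, values, start=1982):
        values = np.asarray(values, dtype=float)
        return pd.Series(values, index=np.arange(start, start + values.size))

    def test_constant_series_all_increments_zero(self):
        tbl = span_table(self._series(np.full(20, 33.0)))
        assert (tbl.increment_pgc == 0).all()
        assert (tbl.cumulative_increment_pgc == 0).all()
        assert (tbl.sd_pgc == 0).all()

    def test_printed_span_logic(self):
        # span means 32.89 and 32.95 three spans apart -> cumulative 0.06
        means = [32.89, 32.84, 32.87, 32.95]
        vals = np.repeat(means, 5)
        tbl = span_table(self._series(vals))
        assert tbl.loc[3, "period"] == "1997-2001"
        assert tbl.loc[3, "cumulative_increment_pgc"] == pytest.approx(0.06, abs=1e-12)
        assert tbl.loc[1, "increment_pgc"] == pytest.approx(-0.05, abs=1e-12)

    def test_linear_series_increment_is_span_times_slope(self):
        s = 0.033
        vals = 30.0 + s * np.arange(20)
        tbl = span_table(self._series(vals))
        np.testing.assert_allclose(tbl.increment_pgc[1:], 5 * s, rtol=1e-10)

    def test_telescoping_increments(self, rng):
        vals = rng.uniform(30, 35, 40)
        tbl = span_table(self._series(vals))
        assert tbl.increment_pgc.sum() == pytest.approx(
            tbl.cumulative_increment_pgc.iloc[-1], abs=1e-12
        )

    def test_explicit_baseline_for_future_spans(self, rng):
        vals = rng.uniform(33, 36, 10)
        hist_mean = 33.3
        tbl = span_table(self._series(vals, start=2022), baseline=hist_mean)
        expected = tbl.mean_stock_pgc - hist_mean
        np.testing.assert_allclose(tbl.cumulative_increment_pgc, expected, rtol=1e-12)
        np.testing.assert_allclose(
            tbl.cumulative_co2_bt, expected * CO2_PER_PGC, rtol=1e-12
        )

    def test_partial_span_rejected(self, rng):
        with pytest.raises(ValueError):
            span_table(self._series(rng.uniform(30, 35, 23)))


class TestCo2Equivalent:
    def test_printed_factor_pairs(self):
        # source-table convention: 1 Pg C -> 36.67 Bt CO2
        assert co2_equivalent(1.0) == pytest.approx(36.67)
        assert co2_equivalent(1.126) == pytest.approx(41.294, rel=0.005)
        assert co2_equivalent(0.0) == 0.0

    def test_round_trip_linearity(self, rng):
        x = rng.uniform(-5, 5, 20)
        np.testing.assert_allclose(co2_equivalent(x) / CO2_PER_PGC, x, rtol=1e-15)


class TestTrendSlopeMap:
    def _cube(self, data, start=2000):
        n = data.shape[0]
        geom = GridGeometry(40.0, 100.0, 0.01, *data.shape[1:])
        return GridCube(np.arange(start, start + n), data, geom)

    def test_exact_on_linear_series(self):
        t = np.arange(10, dtype=float)
        data = (5.0 + 0.07 * t)[:, None, None] * np.ones((1, 3, 3))
        slopes = trend_slope_map(self._cube(data))
        np.testing.assert_allclose(slopes, 0.07, rtol=1e-10)

    def test_closed_form_small_series(self):
        # x=(1,2,2,4) over 4 years: cov/var = 4.5/5 = 0.9
        data = np.array([1.0, 2.0, 2.0, 4.0])[:, None, None]
        assert trend_slope_map(self._cube(data))[0, 0] == pytest.approx(0.9, rel=1e-12)

    def test_constant_series_zero_and_short_series_masked(self):
        data = np.ones((5, 2, 2))
        np.testing.assert_allclose(trend_slope_map(self._cube(data)), 0.0, atol=1e-12)
        gappy = np.ones((5, 1, 1))
        gappy[2:, 0, 0] = np.nan  # only 2 valid years at this pixel
        assert np.isnan(trend_slope_map(self._cube(gappy))[0, 0])


class TestAreaFraction:
    def test_partition_sums_to_hundred(self, rng):
        grid = rng.uniform(0, 300, (20, 20))
        areas = rng.uniform(50, 150, (20, 20))
        above = area_fraction(grid, lambda g: g > 150, areas)
        below = area_fraction(grid, lambda g: ~(g > 150), areas)
        assert above + below == pytest.approx(100.0, rel=1e-12)

    def test_trivial_predicates(self, rng):
        grid = rng.uniform(0, 1, (5, 5))
        areas = np.ones((5, 5))
        assert area_fraction(grid, lambda g: g >= 0, areas) == pytest.approx(100.0)
        assert area_fraction(grid, lambda g: g < 0, areas) == 0.0

    def test_area_weighted_median_splits_in_half(self, rng):
        # equal areas: threshold at the empirical median -> ~50%
        grid = rng.normal(size=(40, 40))
        areas = np.ones((40, 40))
        med = np.median(grid)
        frac = area_fraction(grid, lambda g: g > med, areas)
        assert frac == pytest.approx(50.0, abs=0.5)


class TestScenarioEnvelope:
    def test_identical_scenarios_zero_amplitude(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        env = scenario_envelope(s, s.copy())
        assert (env.amplitude_pgc == 0).all()
        assert not env.exceeds_half.any()

    def test_amplitude_and_half_ratio_flag(self):
        lo = pd.Series([1.0, 1.0], index=["a", "b"])
        hi = pd.Series([1.4, 1.6], index=["a", "b"])
        env = scenario_envelope(lo, hi)
        np.testing.assert_allclose(env.ratio_pct, [40.0, 60.0], rtol=1e-12)
        assert list(env.exceeds_half) == [False, True]
        np.testing.assert_allclose(
            env.amplitude_co2_bt, env.amplitude_pgc * CO2_PER_PGC, rtol=1e-12
        )

    def test_period_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scenario_envelope(pd.Series([1.0], index=["a"]),
                              pd.Series([1.0], index=["b"]))
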