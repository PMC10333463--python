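"""Fusion operators checked against hand formulas and loop oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forestcarbon.fusion import (
    FusionInputs,
    annual_mean_ndvi,
    bilinear_resample,
    climatology,
    fuse_ndvi,
    fuse_series,
    mvc_composite,
)
from forestcarbon.grids import GridCube, GridGeometry
from forestcarbon.synthetic import TruthConfig, gen_ndvi, gen_truth


def _unit_geom(nrows, ncols, cell=1.0, lat0=10.0, lon0=100.0):
    return GridGeometry(lat0, lon0, cell, nrows, ncols)


class TestMvcComposite:
    def test_pixelwise_maximum_and_missing_rules(self):
        a = np.array([[0.3, np.nan], [np.nan, 0.1]])
        b = np.array([[0.5, 0.2], [np.nan, np.nan]])
        out = mvc_composite([a, b])
        assert out[0, 0] == 0.5          # plain max
        assert out[0, 1] == 0.2          # one layer missing -> the other
        assert np.isnan(out[1, 0])       # all missing -> missing
        assert out[1, 1] == 0.1

    def test_matches_per_pixel_loop_oracle(self, rng):
        layers = [rng.uniform(-0.2, 1.0, (6, 7)) for _ in range(5)]
        for l in layers:
            l[rng.random((6, 7)) < 0.3] = np.nan
        out = mvc_composite(layers)
        for i in range(6):
            for j in range(7):
                vals = [l[i, j] for l in layers if not np.isnan(l[i, j])]
                if vals:
                    assert out[i, j] == max(vals)
                else:
                    assert np.isnan(out[i, j])

    def test_idempotent(self, rng):
        layers = [rng.uniform(0, 1, (5, 5)) for _ in range(4)]
        once = mvc_composite(layers)
        np.testing.assert_array_equal(mvc_composite([once] + layers), once)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mvc_composite([np.zeros((2, 2)), np.zeros((3, 3))])


class TestBilinearResample:
    def test_constant_field_reproduced(self):
        src = _unit_geom(8, 8)
        tgt = _unit_geom(15, 15, cell=8.0 / 15.0)
        out = bilinear_resample(np.full((8, 8), 3.7), src, tgt)
        np.testing.assert_allclose(out, 3.7, rtol=1e-12)

    def test_exact_at_source_centers(self, rng):
        src = _unit_geom(6, 6)
        grid = rng.normal(size=(6, 6))
        out = bilinear_resample(grid, src, src)  # identical geometry
        np.testing.assert_allclose(out, grid, rtol=1e-12)

    def test_midpoint_of_four_centers_is_plain_average(self):
        # centers valued 0,1,2,3 -> equal 0.25 weights -> 1.5
        src = _unit_geom(2, 2)
        grid = np.array([[0.0, 1.0], [2.0, 3.0]])
        # target: single cell whose center is the midpoint of the 4 centers
        tgt = GridGeometry(src.origin_lat, src.origin_lon, 2.0, 1, 1)
        out = bilinear_resample(grid, src, tgt)
        assert out[0, 0] == pytest.approx(1.5, abs=1e-12)

    def test_planar_field_interpolated_exactly_in_interior(self):
        src = _unit_geom(10, 10)
        tgt = _unit_geom(19, 19, cell=10.0 / 19.0)
        lat, lon = np.meshgrid(src.lat_centers(), src.lon_centers(), indexing="ij")
        plane = 2.0 * lat - 3.0 * lon + 1.0
        out = bilinear_resample(plane, src, tgt)
        tlat, tlon = np.meshgrid(tgt.lat_centers(), tgt.lon_centers(), indexing="ij")
        expected = 2.0 * tlat - 3.0 * tlon + 1.0
        # interior targets only: edge clamping flattens the plane outside
        inner = (tlat <= src.lat_centers()[0]) & (tlat >= src.lat_centers()[-1]) \
            & (tlon >= src.lon_centers()[0]) & (tlon <= src.lon_centers()[-1])
        np.testing.assert_allclose(out[inner], expected[inner], rtol=1e-10)

    def test_matches_hand_four_neighbor_oracle(self, rng):
        # independent loop implementation of the 4-neighbor weighted mean
        src = _unit_geom(8, 8)
        tgt = _unit_geom(15, 15, cell=8.0 / 15.0)
        grid = rng.normal(size=(8, 8))
        out = bilinear_resample(grid, src, tgt)
        slat, slon = src.lat_centers(), src.lon_centers()
        for r in range(15):
            for c in range(15):
                la = tgt.lat_centers()[r]
                lo = tgt.lon_centers()[c]
                fi = min(max((slat[0] - la) / src.cell_size, 0.0), 7.0)
                fj = min(max((lo - slon[0]) / src.cell_size, 0.0), 7.0)
                i0, j0 = int(fi), int(fj)
                i1, j1 = min(i0 + 1, 7), min(j0 + 1, 7)
                di, dj = fi - i0, fj - j0
                exp = ((1 - di) * (1 - dj) * grid[i0, j0]
                       + (1 - di) * dj * grid[i0, j1]
                       + di * (1 - dj) * grid[i1, j0]
                       + di * dj * grid[i1, j1])
                assert out[r, c] == pytest.approx(exp, rel=1e-12)

    def test_missing_neighbors_renormalize(self):
        src = _unit_geom(2, 2)
        grid = np.array([[1.0, np.nan], [3.0, np.nan]])
        tgt = GridGeometry(src.origin_lat, src.origin_lon, 2.0, 1, 1)
        out = bilinear_resample(grid, src, tgt)
        assert out[0, 0] == pytest.approx(2.0)  # mean of the two valid neighbors
        all_nan = bilinear_resample(np.full((2, 2), np.nan), src, tgt)
        assert np.isnan(all_nan[0, 0])


class TestAnnualMeanNdvi:
    def test_mean_over_qualifying_months_only(self):
        months = [np.full((2, 2), 0.2), np.full((2, 2), 0.4)] * 6
        out = annual_mean_ndvi(months)
        np.testing.assert_allclose(out, 0.3)

    def test_subthreshold_year_masked(self):
        out = annual_mean_ndvi([np.full((2, 2), 0.05)] * 12)
        assert np.isnan(out).all()

    def test_divisor_is_qualifying_count(self):
        months = [np.full((1, 1), 0.6)] * 3 + [np.full((1, 1), 0.05)] * 9
        out = annual_mean_ndvi(months)
        assert out[0, 0] == pytest.approx(0.6)  # not 3*0.6/12

    def test_wrong_month_count_rejected(self):
        with pytest.raises(ValueError):
            annual_mean_ndvi([np.zeros((2, 2))] * 11)


class TestClimatology:
    def test_arithmetic_mean_of_years(self):
        grids = [np.full((2, 2), v) for v in (0.2, 0.4, 0.6)]
        np.testing.assert_allclose(climatology(grids), 0.4)

    def test_single_year_is_identity(self, rng):
        g = rng.uniform(0, 1, (3, 3))
        np.testing.assert_array_equal(climatology([g]), g)


class TestFuseNdvi:
    def _inputs(self, g, ag, am, geom=None):
        geom = geom or _unit_geom(*np.shape(g))
        cube = GridCube(np.array([2000]), np.asarray(g, dtype=float)[None],
                        geom, name="g")
        return FusionInputs(cube, np.asarray(ag, dtype=float),
                            np.asarray(am, dtype=float))

    def test_direct_substitution_example(self):
        # g=0.6, AG=0.5, AM=0.4: (1 + 0.5) * 0.6 / 1.25 = 0.72 = 0.6^2/0.5
        out = fuse_ndvi(self._inputs([[0.6]], [[0.5]], [[0.4]]), 2000)
        assert out[0, 0] == pytest.approx(0.72, abs=1e-12)

    def test_year_at_climatology_returns_coarse_value(self):
        out = fuse_ndvi(self._inputs([[0.5]], [[0.5]], [[0.3]]), 2000)
        assert out[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_zero_climatology_masks_pixel(self):
        out = fuse_ndvi(self._inputs([[0.6, 0.6]], [[0.5, 0.5]], [[0.0, 0.4]]), 2000)
        assert np.isnan(out[0, 0]) and not np.isnan(out[0, 1])

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_literal_composition_equals_simplified_form(self, seed):
        # the fine climatology cancels: fused == g^2 / AG on unmasked pixels
        r = np.random.default_rng(seed)
        ag = r.uniform(0.3, 0.9, (5, 5))
        g = ag * r.uniform(0.8, 1.05, (5, 5))
        am = r.uniform(0.2, 0.9, (5, 5))
        out = fuse_ndvi(self._inputs(g, ag, am), 2000)
        np.testing.assert_allclose(out, g * g / ag, rtol=1e-12)


@pytest.fixture(scope="module")
def fused_setup():
    cfg = TruthConfig(seed=21, nrows=16, ncols=16, year_start=2000,
                      year_end=2011, mask_fraction=0.0, interannual_sd=0.2)
    cveg, _ = gen_truth(cfg)
    coarse, fine = gen_ndvi(cveg, 4, noise_sd=0.0, seed=5)
    from forestcarbon.fusion import annual_series_from_biweekly
    ca = annual_series_from_biweekly(coarse)
    fa = annual_series_from_biweekly(fine)
    fused = fuse_series(ca, fa, (2004, 2011))
    return ca, fa, fused


class TestFuseSeries:

    def test_output_on_fine_geometry_and_in_range(self, fused_setup):
        ca, fa, fused = fused_setup
        assert fused.geometry == fa.geometry
        assert np.nanmin(fused.data) >= -0.2 and np.nanmax(fused.data) <= 1.0

    def test_climatology_preserved_over_overlap_window(self, fused_setup):
        # noise-free input: multi-year mean of the fused series over the
        # window stays consistent with the resampled coarse climatology
        ca, fa, fused = fused_setup
        sel = (fused.years >= 2004) & (fused.years <= 2011)
        fused_clim = np.nanmean(fused.data[sel], axis=0)
        coarse_res = np.stack([
            bilinear_resample(ca.data[i], ca.geometry, fa.geometry)
            for i in range(ca.n_years)
        ])
        coarse_clim = np.nanmean(coarse_res[sel], axis=0)
        ok = ~np.isnan(fused_clim) & ~np.isnan(coarse_clim)
        # fused = g^2/AG, so mean(fused) = AG * (1 + var(g)/AG^2); tight here
        np.testing.assert_allclose(fused_clim[ok], coarse_clim[ok], rtol=0.02)

    def test_empty_overlap_rejected(self, fused_setup):
        ca, fa, _ = fused_setup
        with pytest.raises(ValueError):
            fuse_series(ca, fa, (1990, 1991))
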