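"""Raster semantics, variography, ordinary kriging, difference isoscape."""

import numpy as np
import pytest

from isogeoloc import (
    Raster,
    VariogramModel,
    build_tapwater_isoscape,
    empirical_variogram,
    extract_at,
    fit_variogram,
    krige_ordinary,
    read_ascii_grid,
    write_ascii_grid,
)
from isogeoloc.data_model import great_circle_km
from isogeoloc.isoscape import ExtentError, GeometryError


class TestExtract:
    def test_constant_raster(self):
        r = Raster(np.full((3, 3), 5.0), x_min=0, y_max=3, dx=1, dy=1)
        vals = extract_at(r, [(0.5, 0.5), (2.9, 2.9), (1.5, 0.1)])
        assert np.allclose(vals, 5.0)

    def test_manual_index_arithmetic(self, small_raster):
        # values are 0..15 row-major from the NW corner at (-10, 4)
        pts = [(-9.5, 3.5), (-8.5, 3.5), (-9.5, 2.5), (-6.5, 0.5)]
        vals = extract_at(small_raster, pts)
        assert list(vals) == [0.0, 1.0, 4.0, 15.0]

    def test_half_open_boundary_convention(self, small_raster):
        # point exactly on the x boundary between cols 0 and 1 belongs to col 1;
        # point on the y boundary between rows 0 and 1 belongs to row 1
        assert extract_at(small_raster, [(-9.0, 3.5)])[0] == 1.0
        assert extract_at(small_raster, [(-9.5, 3.0)])[0] == 4.0

    def test_outer_edges_belong_to_grid(self, small_raster):
        assert extract_at(small_raster, [(-10.0, 4.0)])[0] == 0.0  # NW corner
        assert extract_at(small_raster, [(-6.0, 0.0)])[0] == 15.0  # SE corner

    def test_out_of_extent_raises_naming_point(self, small_raster):
        with pytest.raises(ExtentError, match="-20"):
            extract_at(small_raster, [(-20.0, 3.5)])

    def test_nodata_yields_nan(self):
        vals = np.ones((2, 2))
        vals[0, 0] = np.nan
        r = Raster(vals, x_min=0, y_max=2, dx=1, dy=1)
        out = extract_at(r, [(0.5, 1.5)])
        assert np.isnan(out[0])


class TestAsciiGrid:
    def test_round_trip(self, tmp_path, small_raster):
        vals = small_raster.values.copy()
        vals[2, 1] = np.nan
        r = small_raster.copy_with(vals)
        path = tmp_path / "r.asc"
        write_ascii_grid(r, path)
        r2 = read_ascii_grid(path)
        assert r2.shape == r.shape
        assert r2.x_min == r.x_min and r2.y_max == r.y_max
        assert np.allclose(r2.values, r.values, equal_nan=True)


class TestEmpiricalVariogram:
    def test_two_points_hand_value(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0]])
        h, g, n = empirical_variogram(pts, np.array([0.0, 2.0]), n_bins=1, max_dist=200.0)
        assert g[0] == pytest.approx(2.0)  # 0.5 * (2)^2
        assert n[0] == 1

    def test_equal_values_zero_semivariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 5, size=(20, 2))
        h, g, n = empirical_variogram(pts, np.full(20, 3.3))
        assert np.allclose(g, 0.0)

    def test_collinear_points_match_pair_enumeration(self):
        # 4 equally spaced points on a meridian, values 0,1,0,1
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 2.0], [0.0, 3.0]])
        vals = np.array([0.0, 1.0, 0.0, 1.0])
        # brute-force oracle over all 6 pairs
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        d = np.array(
            [float(great_circle_km(pts[i, 0], pts[i, 1], pts[j, 0], pts[j, 1])) for i, j in pairs]
        )
        sq = np.array([0.5 * (vals[i] - vals[j]) ** 2 for i, j in pairs])
        max_dist = d.max() + 1.0
        edges = np.linspace(0.0, max_dist, 4)
        expected = []
        for b in range(3):
            m = (d > edges[b]) & (d <= edges[b + 1]) if b else (d <= edges[1])
            if m.sum():
                expected.append(sq[m].mean())
        h, g, n = empirical_variogram(pts, vals, n_bins=3, max_dist=max_dist)
        assert np.allclose(np.sort(g), np.sort(expected))
        assert n.sum() == 6

    def test_coincident_points_rejected(self):
        pts = np.zeros((3, 2))
        with pytest.raises(GeometryError):
            empirical_variogram(pts, np.array([1.0, 2.0, 3.0]))


class TestFitVariogram:
    def test_recovers_noiseless_exponential(self):
        truth = VariogramModel("exponential", nugget=0.0, partial_sill=1.0, range_km=50.0)
        h = np.linspace(5.0, 150.0, 12)
        emp = (h, truth(h), np.full(12, 30))
        fit = fit_variogram(emp, "exponential")
        assert fit.partial_sill == pytest.approx(1.0, rel=0.01)
        assert fit.range_km == pytest.approx(50.0, rel=0.01)
        assert fit.nugget == pytest.approx(0.0, abs=0.01)

    def test_flat_empirical_gives_pure_nugget(self):
        h = np.linspace(5.0, 150.0, 10)
        fit = fit_variogram((h, np.full(10, 2.5), np.full(10, 20)), "exponential")
        assert fit.nugget == pytest.approx(2.5, abs=0.05)
        assert fit.partial_sill == pytest.approx(0.0, abs=0.05)

    def test_scale_equivariance(self):
        truth = VariogramModel("spherical", nugget=0.2, partial_sill=1.0, range_km=80.0)
        h = np.linspace(5.0, 150.0, 12)
        g = truth(h)
        f1 = fit_variogram((h, g, np.full(12, 25)), "spherical")
        f2 = fit_variogram((h, 2.0 * g, np.full(12, 25)), "spherical")
        assert f2.nugget == pytest.approx(2.0 * f1.nugget, abs=1e-3)
        assert f2.partial_sill == pytest.approx(2.0 * f1.partial_sill, rel=1e-3)

    def test_semivariance_nondecreasing(self):
        for fam in ("exponential", "spherical", "gaussian"):
            m = VariogramModel(fam, nugget=0.1, partial_sill=1.0, range_km=60.0)
            h = np.linspace(0.1, 400.0, 200)
            g = m(h)
            assert np.all(np.diff(g) >= -1e-12)


def _target_grid():
    return Raster(np.zeros((3, 3)), x_min=0.0, y_max=3.0, dx=1.0, dy=1.0)


class TestKriging:
    def test_constant_field_reproduced(self):
        pts = np.array([[0.5, 0.5], [2.5, 2.5], [0.5, 2.5]])
        vg = VariogramModel("exponential", nugget=0.1, partial_sill=1.0, range_km=100.0)
        pred, var = krige_ordinary(pts, np.full(3, 7.0), vg, _target_grid())
        assert np.allclose(pred.values, 7.0, atol=1e-8)
        assert np.all(var.values >= -1e-12)

    def test_two_point_system_matches_hand_solve(self):
        """OK prediction equals the independently assembled 3x3 system solution."""
        pts = np.array([[0.5, 0.5], [2.5, 2.5]])
        vals = np.array([1.0, 3.0])
        vg = VariogramModel("exponential", nugget=0.05, partial_sill=1.0, range_km=150.0)
        grid = _target_grid()
        pred, var = krige_ordinary(pts, vals, vg, grid)

        # hand-assembled ordinary kriging system for the center cell (1.5, 1.5)
        def cov(p, q):
            h = float(great_circle_km(p[0], p[1], q[0], q[1]))
            total = vg.nugget + vg.partial_sill
            return total if h == 0 else total - float(vg(h))

        A = np.array(
            [
                [cov(pts[0], pts[0]), cov(pts[0], pts[1]), 1.0],
                [cov(pts[1], pts[0]), cov(pts[1], pts[1]), 1.0],
                [1.0, 1.0, 0.0],
            ]
        )
        target = (1.5, 1.5)
        b = np.array([cov(pts[0], target), cov(pts[1], target), 1.0])
        w = np.linalg.solve(A, b)
        assert w[0] + w[1] == pytest.approx(1.0, abs=1e-10)
        expected = w[0] * vals[0] + w[1] * vals[1]
        assert pred.values[1, 1] == pytest.approx(expected, abs=1e-8)
        expected_var = (vg.nugget + vg.partial_sill) - (w[0] * b[0] + w[1] * b[1]) - w[2]
        assert var.values[1, 1] == pytest.approx(expected_var, abs=1e-8)

    def test_zero_nugget_exact_interpolation(self):
        pts = np.array([[0.5, 2.5], [1.5, 1.5], [2.5, 0.5]])
        vals = np.array([1.0, 5.0, 2.0])
        vg = VariogramModel("exponential", nugget=0.0, partial_sill=2.0, range_km=120.0)
        pred, var = krige_ordinary(pts, vals, vg, _target_grid())
        assert pred.values[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert pred.values[1, 1] == pytest.approx(5.0, abs=1e-6)
        assert pred.values[2, 2] == pytest.approx(2.0, abs=1e-6)
        assert var.values[1, 1] == pytest.approx(0.0, abs=1e-6)

    def test_weights_sum_to_one_via_constant_shift(self):
        # shifting all values by c shifts every prediction by c iff weights sum to 1
        rng = np.random.default_rng(1)
        pts = rng.uniform(0.2, 2.8, size=(8, 2))
        vals = rng.normal(0.0, 1.0, 8)
        vg = VariogramModel("spherical", nugget=0.1, partial_sill=1.0, range_km=80.0)
        p1, _ = krige_ordinary(pts, vals, vg, _target_grid())
        p2, _ = krige_ordinary(pts, vals + 10.0, vg, _target_grid())
        assert np.allclose(p2.values - p1.values, 10.0, atol=1e-8)

    def test_duplicate_points_averaged(self):
        pts = np.array([[0.5, 0.5], [0.5, 0.5], [2.5, 2.5]])
        vals = np.array([1.0, 3.0, 5.0])
        vg = VariogramModel("exponential", nugget=0.0, partial_sill=1.0, range_km=100.0)
        pred, _ = krige_ordinary(pts, vals, vg, _target_grid())
        assert pred.values[2, 0] == pytest.approx(2.0, abs=1e-6)  # mean of 1 and 3

    def test_local_neighborhood_path(self):
        # more points than the neighbor cap exercises local kriging
        rng = np.random.default_rng(2)
        pts = rng.uniform(0.1, 2.9, size=(30, 2))
        vals = rng.normal(0.0, 1.0, 30)
        vg = VariogramModel("exponential", nugget=0.1, partial_sill=1.0, range_km=50.0)
        pred, var = krige_ordinary(pts, vals, vg, _target_grid(), max_neighbors=10)
        assert np.all(np.isfinite(pred.values))
        assert np.all(var.values >= -1e-12)


class TestTapwaterIsoscape:
    def _base(self, n=12):
        rows = np.linspace(-12.0, -4.0, n)
        return Raster(np.tile(rows[:, None], (1, n)), x_min=-110.0, y_max=45.0, dx=1.0, dy=1.0)

    def test_tap_equal_base_returns_base(self):
        base = self._base()
        rng = np.random.default_rng(3)
        pts = np.column_stack(
            [rng.uniform(-109.5, -98.5, 20), rng.uniform(33.5, 44.5, 20)]
        )
        tap = extract_at(base, pts)
        iso, unc = build_tapwater_isoscape(base, pts, tap)
        assert np.allclose(iso.values, base.values, atol=1e-8)

    def test_zero_base_additivity(self):
        base = self._base()
        zero = base.copy_with(np.zeros(base.shape))
        rng = np.random.default_rng(4)
        pts = np.column_stack(
            [rng.uniform(-109.5, -98.5, 15), rng.uniform(33.5, 44.5, 15)]
        )
        vals = rng.normal(0.0, 1.0, 15)
        vg = VariogramModel("exponential", nugget=0.0, partial_sill=1.0, range_km=200.0)
        iso, _ = build_tapwater_isoscape(zero, pts, vals, variogram=vg)
        direct, _ = krige_ordinary(pts, vals, vg, zero)
        assert np.allclose(iso.values, direct.values, atol=1e-10)

    def test_constant_shift_equivariance(self):
        base = self._base()
        rng = np.random.default_rng(5)
        pts = np.column_stack(
            [rng.uniform(-109.5, -98.5, 15), rng.uniform(33.5, 44.5, 15)]
        )
        vals = extract_at(base, pts) + rng.normal(0.0, 0.5, 15)
        vg = VariogramModel("exponential", nugget=0.05, partial_sill=0.5, range_km=300.0)
        iso1, _ = build_tapwater_isoscape(base, pts, vals, variogram=vg)
        shifted = base.copy_with(base.values + 4.0)
        iso2, _ = build_tapwater_isoscape(shifted, pts, vals + 4.0, variogram=vg)
        assert np.allclose(iso2.values, iso1.values + 4.0, atol=1e-8)

    def test_smooth_offset_recovery(self):
        """Base + known smooth offset sampled at ~50 sites is recovered well."""
        base = self._base(16)
        lon, lat = base.cell_centers()
        offset = 1.5 * np.cos(np.pi * (lon + 110.0) / 16.0) * np.cos(np.pi * (45.0 - lat) / 16.0)
        truth = base.values + offset
        rng = np.random.default_rng(6)
        idx = rng.choice(16 * 16, size=50, replace=False)
        rows, cols = np.unravel_index(idx, (16, 16))
        pts = np.array([base.cell_center(r, c) for r, c in zip(rows, cols)])
        tap = truth[rows, cols]
        iso, _ = build_tapwater_isoscape(base, pts, tap)
        mae = float(np.mean(np.abs(iso.values - truth)))
        assert mae < 0.15  # noiseless kriging of a smooth field

    def test_too_few_stations_refused(self):
        base = self._base()
        with pytest.raises(GeometryError, match="3"):
            build_tapwater_isoscape(base, np.array([[-105.0, 40.0]]), np.array([1.0]))
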