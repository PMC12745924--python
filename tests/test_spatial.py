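import numpy as np
import pandas as pd
import pytest

from skinkipm.cjs import CJSModel, CJSModelSpec
from skinkipm.gompertz import GompertzFit
from skinkipm.growth import GrowthFit
from skinkipm import ipm as ipm_mod
from skinkipm.spatial import (
    LambdaField,
    RasterStack,
    crop_with_buffer,
    mcp,
    period_aggregate,
    project_lambda,
    read_geotiff,
    vif_screen,
    write_geotiff,
)
from skinkipm.synthetic import simulate_climate_rasters


def _cjs_stub(beta_tmax=-0.5):
    m = CJSModel(CJSModelSpec(("tmax",), ()))
    m.cov_means_ = {"tmax": 28.0, "precip": 100.0, "mean_svl": 55.0}
    m.cov_sds_ = {"tmax": 2.0, "precip": 80.0, "mean_svl": 3.0}
    m.beta_phi_ = np.array([2.5, beta_tmax])
    m.beta_p_ = np.array([0.0])
    return m


GROWTH = GrowthFit(linf=79.0, k=0.094, sigma=0.4, birth_svl=35.0)
GOMP = GompertzFit(-3.5, 0.02)


class TestMCP:
    def test_triangle_is_its_own_hull(self):
        poly = mcp([(0, 0), (1, 0), (0, 1)])
        assert poly.area == pytest.approx(0.5)
        assert len(poly.exterior.coords) == 4  # closed ring

    def test_interior_points_do_not_add_vertices(self):
        poly = mcp([(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)])
        assert poly.area == pytest.approx(1.0)  # shoelace on the unit square
        assert len(poly.exterior.coords) - 1 == 4
        assert poly.exterior.is_ccw

    def test_hull_contains_every_input_point(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(40, 2))
        poly = mcp(pts)
        from shapely.geometry import Point

        assert all(poly.distance(Point(*p)) < 1e-12 for p in pts)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            mcp([(0, 0), (1, 1), (2, 2)])

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            mcp([(0, 0), (1, 1)])


class TestGeoTIFF:
    def test_round_trip_preserves_values_and_georeference(self, tmp_path):
        tmax, _, _ = simulate_climate_rasters(5, 4, 24, gradient=0.2, seed=3)
        stack = RasterStack(data=tmax, transform=(-60.0, 0.25, -10.0, -0.25))
        path = tmp_path / "tmax.tif"
        write_geotiff(path, stack)
        back = read_geotiff(path)
        np.testing.assert_array_equal(back.data, tmax.astype(np.float32))
        assert back.transform == stack.transform


class TestCrop:
    def _stack(self):
        data = np.arange(2 * 10 * 12, dtype=float).reshape(2, 10, 12)
        return RasterStack(data=data, transform=(-60.0, 1.0, -5.0, -1.0))

    def test_zero_buffer_crops_to_hull_bbox(self):
        stack = self._stack()
        poly = mcp([(-57.5, -8.5), (-52.5, -8.5), (-55.0, -11.5)])
        out = crop_with_buffer(stack, poly, buffer=0.0)
        assert out.data.shape == (2, 4, 6)
        assert out.transform == (-58.0, 1.0, -8.0, -1.0)

    def test_covering_polygon_keeps_full_extent(self):
        stack = self._stack()
        poly = mcp([(-70, 5), (-40, 5), (-55, -25)])
        out = crop_with_buffer(stack, poly, buffer=2.0)
        assert out.data.shape == stack.data.shape
        np.testing.assert_array_equal(out.data, stack.data)

    def test_pixel_values_bit_exact_in_overlap(self):
        stack = self._stack()
        poly = mcp([(-56.2, -7.2), (-53.8, -7.2), (-55.0, -9.8)])
        out = crop_with_buffer(stack, poly, buffer=0.0)
        x0, dx, y0, dy = out.transform
        c0 = int(round((x0 - stack.transform[0]) / dx))
        r0 = int(round((y0 - stack.transform[2]) / dy))
        np.testing.assert_array_equal(
            out.data,
            stack.data[:, r0 : r0 + out.data.shape[1], c0 : c0 + out.data.shape[2]],
        )

    def test_disjoint_polygon_rejected(self):
        stack = self._stack()
        poly = mcp([(100, 50), (101, 50), (100, 51)])
        with pytest.raises(ValueError, match="intersect"):
            crop_with_buffer(stack, poly, buffer=0.5)


class TestVIF:
    def test_orthogonal_columns_all_retained_with_unit_vif(self):
        rng = np.random.default_rng(0)
        raw = np.column_stack([np.ones(500), rng.normal(size=(500, 3))])
        Q = np.linalg.qr(raw, mode="reduced")[0]
        X = Q[:, 1:]  # centred and exactly mutually orthogonal
        cols, vifs = vif_screen(pd.DataFrame(X, columns=["a", "b", "c"]))
        assert cols == ["a", "b", "c"]
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in vifs.values())

    def test_duplicated_column_removed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=300)
        X = pd.DataFrame({"a": a, "b": rng.normal(size=300), "a_copy": a})
        cols, _ = vif_screen(X)
        assert cols == ["a", "b"]  # the larger-index duplicate is dropped

    def test_vif_matches_closed_form_on_known_covariance(self):
        rng = np.random.default_rng(2)
        n = 200_000
        z = rng.normal(size=(n, 3))
        rho = 0.8
        x1 = z[:, 0]
        x2 = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        x3 = z[:, 2]
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        _, vifs = vif_screen(X, threshold=np.inf)
        # regressing x1 on (x2, x3): R^2 = rho^2 -> VIF = 1 / (1 - rho^2)
        assert vifs["x1"] == pytest.approx(1 / (1 - rho**2), rel=0.02)

    def test_vif_agrees_with_statsmodels(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 3))
        X[:, 2] = 0.6 * X[:, 0] + 0.8 * X[:, 1] + 0.3 * rng.normal(size=400)
        _, vifs = vif_screen(pd.DataFrame(X, columns=["a", "b", "c"]), threshold=np.inf)
        Xc = sm.add_constant(X - X.mean(axis=0))
        for j, name in enumerate(["a", "b", "c"]):
            ref = variance_inflation_factor(Xc, j + 1)
            assert vifs[name] == pytest.approx(ref, rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            vif_screen(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError):
            vif_screen(pd.DataFrame(np.ones((2, 3))))


class TestProjection:
    def test_uniform_environment_reproduces_single_site_lambda(self):
        tmax, precip, env = simulate_climate_rasters(3, 3, 24, gradient=0.0, seed=6)
        cjs = _cjs_stub()
        field = project_lambda(
            tmax, precip, GROWTH, GOMP, cjs, 3.3, years=[0, 1],
            periods={"all": (0, 1)},
        )
        # every pixel identical
        for iy in range(2):
            assert np.ptp(field.yearly[iy]) == pytest.approx(0.0, abs=1e-12)
        # and equal (to eigensolver tolerance) to the single-site lambda
        from skinkipm.growth import growth_transition
        from skinkipm.gompertz import survival_by_size
        from scipy.special import expit, logit

        mesh, h = ipm_mod.make_mesh()
        G = growth_transition(mesh, GROWTH)
        s_size = survival_by_size(mesh, GOMP, GROWTH, clamp_warn=False)
        mats = []
        for m in range(12):
            dev = (
                cjs.beta_phi_[1]
                * (env["tmax"].iloc[m] - cjs.cov_means_["tmax"])
                / cjs.cov_sds_["tmax"]
            )
            S = expit(logit(np.clip(s_size, 1e-12, 1 - 1e-12)) + dev)
            F = ipm_mod.build_F(mesh, int(env["calendar_month"].iloc[m]), 3.3)
            mats.append(G * S[None, :] + F)
        lam = ipm_mod.lambda_eigen(ipm_mod.yearly_matrix(mats)).lam
        assert field.yearly[0, 0, 0] == pytest.approx(lam, abs=1e-9)

    def test_lambda_antitone_along_tmax_gradient(self):
        tmax, precip, _ = simulate_climate_rasters(6, 2, 24, gradient=0.4, seed=7)
        field = project_lambda(
            tmax, precip, GROWTH, GOMP, _cjs_stub(-0.5), 3.3, years=[0, 1],
            periods={"all": (0, 1)},
        )
        mean_map = field.period_mean["all"]
        assert np.all(np.diff(mean_map, axis=1) < 0)

    def test_time_constant_environment_has_zero_period_sd(self):
        nx, ny = 3, 2
        tmax = np.full((24, ny, nx), 28.0)
        precip = np.full((24, ny, nx), 100.0)
        field = project_lambda(
            tmax, precip, GROWTH, GOMP, _cjs_stub(), 3.3, years=[0, 1],
            periods={"all": (0, 1)},
        )
        np.testing.assert_allclose(field.period_sd["all"], 0.0, atol=1e-12)

    def test_missing_months_rejected(self):
        tmax = np.zeros((20, 2, 2))
        with pytest.raises(ValueError, match="monthly layers"):
            project_lambda(
                tmax, tmax, GROWTH, GOMP, _cjs_stub(), 3.3, years=[0, 1]
            )

    def test_mask_marks_pixels_inside_region(self):
        tmax, precip, _ = simulate_climate_rasters(4, 4, 24, gradient=0.0, seed=8)
        ts = RasterStack(data=tmax, transform=(0.0, 1.0, 4.0, -1.0))
        ps = RasterStack(data=precip, transform=(0.0, 1.0, 4.0, -1.0))
        region = mcp([(0.2, 0.2), (1.8, 0.2), (1.0, 3.8)])
        field = project_lambda(
            ts, ps, GROWTH, GOMP, _cjs_stub(), 3.3, years=[0, 1],
            region=region, periods={"all": (0, 1)},
        )
        assert field.mask is not None
        assert field.mask.any() and not field.mask.all()


class TestPeriodAggregate:
    def test_single_year_period_has_zero_sd(self):
        cube = np.random.default_rng(0).uniform(0.8, 1.2, (1, 3, 3))
        means, sds = period_aggregate(cube, [2005], {"p": (2005, 2005)})
        np.testing.assert_allclose(sds["p"], 0.0)

    def test_constant_cube_mean_is_the_constant(self):
        cube = np.full((5, 2, 2), 1.03)
        means, _ = period_aggregate(cube, range(2005, 2010), {"p": (2005, 2009)})
        np.testing.assert_allclose(means["p"], 1.03)

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(1)
        cube = rng.uniform(0.5, 1.5, (10, 4, 4))
        years = list(range(2005, 2015))
        periods = {"a": (2005, 2008), "b": (2009, 2014)}
        means, sds = period_aggregate(cube, years, periods)
        for label, (y0, y1) in periods.items():
            sel = [i for i, y in enumerate(years) if y0 <= y <= y1]
            for r in range(4):
                for c in range(4):
                    vals = cube[sel, r, c]
                    assert means[label][r, c] == pytest.approx(vals.mean())
                    assert sds[label][r, c] == pytest.approx(vals.std())

    def test_empty_period_set_rejected(self):
        with pytest.raises(ValueError):
            period_aggregate(np.ones((2, 2, 2)), [2005, 2006], {"p": (1990, 1999)})
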