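"""Spatially explicit demographic projection over climate raster grids.

Pixels are independent demographic units: each grid cell gets its own monthly
IPM kernel from its climate series, and the yearly population growth rate
lambda (dominant eigenvalue of the 12-month kernel product) is computed per
pixel and per year, then aggregated to period means and standard deviations
(present 2005-2020 and four future 20-year windows).  The analysis region is
the minimum convex polygon (MCP) of occurrence records; climate stacks are
cropped to the MCP bounding box plus a 2-degree buffer, and covariates are
screened for collinearity with the variance inflation factor (drop VIF > 5).

Rasters are single-band-per-month GeoTIFF stacks (row 0 = north, WGS84,
pixel-centre registration); I/O is built on tifffile with the minimal
GeoTIFF tag set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.special import expit, logit
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.geometry.polygon import orient

from . import ipm as ipm_mod
from .gompertz import survival_by_size
from .growth import growth_transition

__all__ = [
    "RasterStack",
    "LambdaField",
    "write_geotiff",
    "read_geotiff",
    "mcp",
    "crop_with_buffer",
    "vif_screen",
    "project_lambda",
    "period_aggregate",
]

DEFAULT_PERIODS = {
    "2005-2020": (2005, 2020),
    "2021-2040": (2021, 2040),
    "2041-2060": (2041, 2060),
    "2061-2080": (2061, 2080),
    "2081-2100": (2081, 2100),
}


@dataclass
class RasterStack:
    """Monthly raster layers on one grid.

    ``data`` has shape (n_layers, ny, nx); ``transform`` is
    (x0, dx, y0, dy) with dy < 0 (row 0 is the northernmost row); pixel
    centres sit at ``x0 + (col + 0.5) dx`` / ``y0 + (row + 0.5) dy``.
    """

    data: np.ndarray
    transform: tuple
    crs: str = "EPSG:4326"
    labels: list = field(default_factory=list)

    @property
    def shape(self):
        return self.data.shape

    def pixel_centers(self):
        x0, dx, y0, dy = self.transform
        ny, nx = self.data.shape[1:]
        lon = x0 + (np.arange(nx) + 0.5) * dx
        lat = y0 + (np.arange(ny) + 0.5) * dy
        return lon, lat


# -- GeoTIFF I/O -------------------------------------------------------------

_GEOKEYS = (
    1, 1, 0, 3,       # version, revision, minor, key count
    1024, 0, 1, 2,    # GTModelType = geographic
    1025, 0, 1, 1,    # GTRasterType = PixelIsArea
    2048, 0, 1, 4326, # GeographicType = WGS84
)


def write_geotiff(path, stack: RasterStack):
    """Write a stack as a multi-page float32 GeoTIFF (WGS84, north-up)."""
    x0, dx, y0, dy = stack.transform
    extratags = [
        (33550, "d", 3, (float(dx), float(abs(dy)), 0.0)),           # pixel scale
        (33922, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)), # tie point
        (34735, "H", len(_GEOKEYS), _GEOKEYS),                       # geo keys
    ]
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        extratags=extratags,
        metadata=None,
    )


def read_geotiff(path):
    """Read a (Geo)TIFF written by :func:`write_geotiff` back into a stack."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        scale = page.tags[33550].value
        tie = page.tags[33922].value
    if data.ndim == 2:
        data = data[None]
    transform = (float(tie[3]), float(scale[0]), float(tie[4]), -float(scale[1]))
    return RasterStack(data=np.asarray(data), transform=transform)


# -- geometry ----------------------------------------------------------------

def mcp(points):
    """Minimum convex polygon of occurrence points (counter-clockwise hull)."""
    pts = [tuple(map(float, p)) for p in points]
    if len(pts) < 3:
        raise ValueError("MCP needs at least 3 points")
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("occurrence points are collinear; hull is degenerate")
    return orient(hull, sign=1.0)


def crop_with_buffer(stack: RasterStack, polygon: Polygon, buffer=2.0):
    """Crop a stack to the polygon's bounding box expanded by ``buffer`` degrees."""
    minx, miny, maxx, maxy = polygon.bounds
    minx -= buffer
    miny -= buffer
    maxx += buffer
    maxy += buffer
    x0, dx, y0, dy = stack.transform
    ny, nx = stack.data.shape[1:]
    c0 = max(int(np.floor((minx - x0) / dx)), 0)
    c1 = min(int(np.ceil((maxx - x0) / dx)), nx)
    # dy < 0: larger y -> smaller row index
    r0 = max(int(np.floor((maxy - y0) / dy)), 0)
    r1 = min(int(np.ceil((miny - y0) / dy)), ny)
    if c0 >= c1 or r0 >= r1:
        raise ValueError("polygon (plus buffer) does not intersect the raster")
    sub = stack.data[:, r0:r1, c0:c1]
    new_transform = (x0 + c0 * dx, dx, y0 + r0 * dy, dy)
    return RasterStack(data=sub, transform=new_transform, crs=stack.crs,
                       labels=list(stack.labels))


# -- covariate screening -----------------------------------------------------

def vif_screen(covariates, threshold=5.0):
    """Iteratively drop the highest-VIF variable until all VIF <= threshold.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing column j on the others
    (with intercept).  Perfectly collinear pairs yield infinite VIF; the
    member with the largest column index is dropped first.  Returns
    ``(retained_names, final_vifs)``.
    """
    X = pd.DataFrame(covariates)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate variables")
    if len(X) <= X.shape[1]:
        raise ValueError("need more observations than variables")
    cols = list(X.columns)

    def vif_of(cols_):
        M = X[cols_].to_numpy(dtype=float)
        M = M - M.mean(axis=0)
        vifs = []
        for j in range(M.shape[1]):
            yj = M[:, j]
            Z = np.delete(M, j, axis=1)
            coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
            ss_res = float(np.sum((yj - Z @ coef) ** 2))
            ss_tot = float(np.sum(yj**2))
            r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
            vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
        return np.asarray(vifs)

    while len(cols) >= 2:
        vifs = vif_of(cols)
        worst = float(np.max(vifs))
        if worst <= threshold:
            break
        # drop the largest-index column among the (tied) worst
        drop = max(int(i) for i in np.nonzero(vifs == worst)[0])
        cols.pop(drop)
    final = vif_of(cols) if len(cols) >= 2 else np.array([1.0])
    return cols, dict(zip(cols, (float(v) for v in final)))


# -- lambda projection -------------------------------------------------------

@dataclass
class LambdaField:
    """Per-pixel yearly lambda and its period aggregates."""

    yearly: np.ndarray          # (n_years, ny, nx)
    years: list
    transform: tuple
    scenario: str = ""
    mask: np.ndarray | None = None  # True = inside region
    period_mean: dict = field(default_factory=dict)
    period_sd: dict = field(default_factory=dict)


def _phi_logit_deviation(cjs_fit, tmax, precip):
    """logit phi(env) - logit phi(mean env) per layer/pixel, vectorised."""
    terms = cjs_fit.spec.phi_terms
    beta = np.asarray(cjs_fit.beta_phi_, dtype=float)
    dev = np.zeros_like(tmax, dtype=float)
    cube = {"tmax": tmax, "precip": precip}
    for name, b in zip(terms, beta[1:]):
        if name == "mean_svl":
            continue  # size structure held at its study mean when projecting
        z = (cube[name] - cjs_fit.cov_means_[name]) / cjs_fit.cov_sds_[name]
        dev = dev + b * z
    return dev


def project_lambda(
    tmax_stack,
    precip_stack,
    growth_fit,
    gompertz_fit,
    cjs_fit,
    litter_mean,
    years,
    scenario="",
    start_calendar_month=1,
    maturity_svl=54.0,
    breeding_months=ipm_mod.DEFAULT_BREEDING,
    neonate_mu=35.0,
    neonate_sd=1.5,
    sex_ratio=0.5,
    mesh_points=ipm_mod.MESH_POINTS,
    region=None,
    periods=DEFAULT_PERIODS,
):
    """Per-pixel yearly lambda from monthly climate stacks.

    ``tmax_stack``/``precip_stack`` carry ``12 * len(years)`` monthly layers
    on a common grid.  For each pixel and year, twelve monthly kernels are
    assembled (survival combines the size-dependent Gompertz baseline with
    the pixel's CJS environmental deviation on the logit scale) and
    multiplied chronologically; lambda is the product's dominant eigenvalue.
    Results are aggregated into period mean/SD maps and masked to the
    occurrence MCP when ``region`` is given.
    """
    tmax = tmax_stack.data if isinstance(tmax_stack, RasterStack) else np.asarray(tmax_stack)
    precip = precip_stack.data if isinstance(precip_stack, RasterStack) else np.asarray(precip_stack)
    if tmax.shape != precip.shape:
        raise ValueError("tmax and precip stacks must share grid and layer count")
    n_layers, ny, nx = tmax.shape
    if n_layers != 12 * len(years):
        missing = 12 * len(years) - n_layers
        raise ValueError(
            f"expected {12 * len(years)} monthly layers for years {years[0]}..{years[-1]}, "
            f"got {n_layers} ({missing:+d})"
        )

    mesh, h = ipm_mod.make_mesh(mesh_points)
    G = growth_transition(mesh, growth_fit)
    s_size = np.clip(
        survival_by_size(mesh, gompertz_fit, growth_fit, clamp_warn=False),
        1e-12,
        1 - 1e-12,
    )
    logit_s_size = logit(s_size)
    dev = _phi_logit_deviation(cjs_fit, tmax, precip)  # (n_layers, ny, nx)

    cal = (start_calendar_month - 1 + np.arange(12)) % 12 + 1
    F_by_month = [
        ipm_mod.build_F(
            mesh,
            int(m),
            litter_mean,
            maturity_svl=maturity_svl,
            breeding_months=breeding_months,
            neonate_mu=neonate_mu,
            neonate_sd=neonate_sd,
            sex_ratio=sex_ratio,
        )
        for m in cal
    ]

    yearly = np.empty((len(years), ny, nx))
    for iy in range(len(years)):
        for r in range(ny):
            for c in range(nx):
                A = np.eye(mesh.size)
                for im in range(12):
                    d = dev[iy * 12 + im, r, c]
                    S = expit(logit_s_size + d)
                    K = G * S[None, :] + F_by_month[im]
                    A = K @ A
                lam, _ = ipm_mod._power_iteration(A, tol=1e-12)
                yearly[iy, r, c] = lam

    transform = (
        tmax_stack.transform if isinstance(tmax_stack, RasterStack) else (0.0, 1.0, 0.0, -1.0)
    )
    mask = None
    if region is not None:
        lon, lat = RasterStack(data=tmax, transform=transform).pixel_centers()
        mask = np.array(
            [[region.contains(Point(x, y)) for x in lon] for y in lat], dtype=bool
        )
    field_ = LambdaField(
        yearly=yearly, years=list(years), transform=transform, scenario=scenario, mask=mask
    )
    pm, ps = period_aggregate(yearly, years, periods)
    field_.period_mean, field_.period_sd = pm, ps
    return field_


def period_aggregate(yearly, years, periods=DEFAULT_PERIODS):
    """Arithmetic mean and SD maps of yearly lambda within each period window.

    Periods with no covered years are skipped; requesting only such periods
    is an error.
    """
    yearly = np.asarray(yearly)
    years = np.asarray(list(years))
    means, sds = {}, {}
    for label, (y0, y1) in periods.items():
        sel = (years >= y0) & (years <= y1)
        if not sel.any():
            continue
        means[label] = yearly[sel].mean(axis=0)
        sds[label] = yearly[sel].std(axis=0)
    if not means:
        raise ValueError("no requested period overlaps the projected years")
    return means, sds
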