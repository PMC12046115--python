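"""Rasters and tap-water isoscape construction by difference kriging.

An isoscape is a gridded predictive model of isotope variation in space.
The tap-water d18O isoscape is built from a base precipitation surface by
(1) differencing point tap-water observations against the base raster at
their cells, (2) interpolating the difference field with ordinary kriging
under a fitted semivariogram, and (3) adding the kriged differences back
onto the base surface. Kriging the *difference* rather than the raw values
preserves the fine structure of the base isoscape between stations.

Rasters are plain lon/lat grids with an affine transform; they are read
and written as single-band ESRI ASCII grids (a text format; the nodata
tag is respected). Cells are half-open: a point on a shared boundary
belongs to the cell whose [x, x+dx) x (y-dy, y] interval contains it.

Distances are great-circle km; the kriging system treats them as planar,
an accepted approximation at continental scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .data_model import great_circle_km

logger = logging.getLogger("isogeoloc")

__all__ = [
    "Raster",
    "VariogramModel",
    "read_ascii_grid",
    "write_ascii_grid",
    "extract_at",
    "empirical_variogram",
    "fit_variogram",
    "krige_ordinary",
    "build_tapwater_isoscape",
]

#: cap on the local kriging neighborhood (full solve when n <= cap)
MAX_KRIGING_NEIGHBORS = 64

DEFAULT_NODATA = -9999.0


class ExtentError(ValueError):
    """A query point falls outside the raster extent."""


class GeometryError(ValueError):
    """Degenerate spatial configuration (coincident points etc.)."""


@dataclass
class Raster:
    """Georeferenced grid of isotope values on a regular lon/lat mesh.

    ``values[0, 0]`` is the north-west cell. ``x_min``/``y_max`` are the
    outer edges of that corner cell; ``dx``/``dy`` are positive cell sizes
    in degrees. Nodata cells are NaN in memory and excluded from every
    statistic.
    """

    values: np.ndarray  # 2-D float array, NaN = nodata
    x_min: float
    y_max: float
    dx: float
    dy: float
    crs_note: str = "WGS84 lon/lat"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("raster grid must be 2-D with dimensions >= 1x1")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_max(self) -> float:
        return self.x_min + self.shape[1] * self.dx

    @property
    def y_min(self) -> float:
        return self.y_max - self.shape[0] * self.dy

    def copy_with(self, values: np.ndarray) -> "Raster":
        if values.shape != self.shape:
            raise ValueError("replacement grid has wrong shape")
        return Raster(np.asarray(values, dtype=float), self.x_min, self.y_max,
                      self.dx, self.dy, self.crs_note)

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the half-open cell containing a point."""
        col = math.floor((lon - self.x_min) / self.dx)
        row = math.floor((self.y_max - lat) / self.dy)
        nrow, ncol = self.shape
        # points exactly on the east/south outer edge belong to the last cell
        if col == ncol and math.isclose(lon, self.x_max):
            col -= 1
        if row == nrow and math.isclose(lat, self.y_min):
            row -= 1
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ExtentError(f"point ({lon}, {lat}) outside raster extent")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_min + (col + 0.5) * self.dx,
            self.y_max - (row + 0.5) * self.dy,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of all cell centers, shaped like the grid."""
        nrow, ncol = self.shape
        lon = self.x_min + (np.arange(ncol) + 0.5) * self.dx
        lat = self.y_max - (np.arange(nrow) + 0.5) * self.dy
        return np.meshgrid(lon, lat)

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def area_weights(self) -> np.ndarray:
        """Normalized cell-area weights, cos(latitude) of the cell center.

        Lon/lat grids are not equal-area; cos(lat) is proportional to the
        true cell area on the sphere for a fixed dx, dy. Nodata cells get
        weight 0; valid weights sum to 1.
        """
        _, lat = self.cell_centers()
        w = np.cos(np.radians(lat))
        w = np.where(self.valid_mask(), w, 0.0)
        total = w.sum()
        if total <= 0:
            raise ValueError("raster has no valid cells")
        return w / total


def extract_at(raster: Raster, points: Sequence[tuple[float, float]]) -> np.ndarray:
    """Cell values of the raster at lon/lat points (no interpolation).

    Nodata cells yield NaN. A point outside the raster extent raises
    :class:`ExtentError` naming the offending point.
    """
    out = np.empty(len(points), dtype=float)
    for i, (lon, lat) in enumerate(points):
        row, col = raster.index_of(float(lon), float(lat))
        out[i] = raster.values[row, col]
    return out


# --- text raster I/O (ESRI ASCII grid) ---------------------------------------


def write_ascii_grid(raster: Raster, path, nodata: float = DEFAULT_NODATA) -> None:
    nrow, ncol = raster.shape
    vals = np.where(raster.valid_mask(), raster.values, nodata)
    if not math.isclose(raster.dx, raster.dy):
        raise ValueError("ASCII grid requires square cells (dx == dy)")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {float(raster.x_min):.17g}\n")
        fh.write(f"yllcorner {float(raster.y_min):.17g}\n")
        fh.write(f"cellsize {float(raster.dx):.17g}\n")
        fh.write(f"NODATA_value {float(nodata):.17g}\n")
        for r in range(nrow):
            fh.write(" ".join(f"{float(v):.17g}" for v in vals[r]) + "\n")


def read_ascii_grid(path) -> Raster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid missing header line {key!r}")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared dimensions")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.where(np.isclose(values, nodata), np.nan, values)
    cell = header["cellsize"]
    return Raster(
        values=values,
        x_min=header["xllcorner"],
        y_max=header["yllcorner"] + int(header["nrows"]) * cell,
        dx=cell,
        dy=cell,
    )


# --- variography --------------------------------------------------------------


@dataclass
class VariogramModel:
    """Isotropic semivariogram with nugget, partial sill and range (km)."""

    model_family: str  # exponential | spherical | gaussian
    nugget: float
    partial_sill: float
    range_km: float

    def __post_init__(self) -> None:
        if self.model_family not in ("exponential", "spherical", "gaussian"):
            raise ValueError(f"unknown variogram family {self.model_family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_km <= 0:
            raise ValueError("variogram requires nugget >= 0, sill >= 0, range > 0")

    def __call__(self, h) -> np.ndarray:
        """Semivariance gamma(h) for separation h in km."""
        h = np.asarray(h, dtype=float)
        a = self.range_km
        if self.model_family == "exponential":
            struct = 1.0 - np.exp(-h / a)
        elif self.model_family == "gaussian":
            struct = 1.0 - np.exp(-((h / a) ** 2))
        else:  # spherical
            hr = np.clip(h / a, 0.0, 1.0)
            struct = 1.5 * hr - 0.5 * hr**3
        gamma = self.nugget + self.partial_sill * struct
        return np.where(h == 0.0, 0.0, gamma)

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill_total - gamma(h), with C(0)=total."""
        h = np.asarray(h, dtype=float)
        total = self.nugget + self.partial_sill
        return np.where(h == 0.0, total, total - self(h))


def empirical_variogram(
    points: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    max_dist: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram of a point set.

    Returns (h, gamma_hat, n_pairs) for the non-empty bins, where
    gamma_hat(h) = 1/2 * mean over pairs in the bin of (dv)^2 and h is the
    mean pair distance of the bin (great-circle km). ``max_dist`` defaults
    to half the maximum pairwise distance, the usual variography cutoff.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(points)
    if n < 2:
        raise GeometryError("need at least 2 points for a variogram")
    iu, ju = np.triu_indices(n, k=1)
    d = great_circle_km(points[iu, 0], points[iu, 1], points[ju, 0], points[ju, 1])
    if np.max(d) == 0.0:
        raise GeometryError("all points coincident")
    sq = 0.5 * (values[iu] - values[ju]) ** 2
    if max_dist is None:
        max_dist = 0.5 * float(np.max(d))
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    keep = d <= max_dist
    d, sq = d[keep], sq[keep]
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    h_out, g_out, n_out = [], [], []
    for b in range(n_bins):
        m = which == b
        cnt = int(m.sum())
        if cnt == 0:
            continue
        h_out.append(float(d[m].mean()))
        g_out.append(float(sq[m].mean()))
        n_out.append(cnt)
    return np.array(h_out), np.array(g_out), np.array(n_out, dtype=int)


def fit_variogram(
    empirical: tuple[np.ndarray, np.ndarray, np.ndarray],
    model_family: str = "exponential",
) -> VariogramModel:
    """Weighted least-squares fit of a variogram family to binned data.

    Bins are weighted n_pairs / h^2 (close pairs matter most for kriging).
    If the optimizer fails, falls back to a pure-nugget model at the mean
    empirical semivariance with a logged warning.
    """
    h, gamma, n_pairs = (np.asarray(a, dtype=float) for a in empirical)
    if len(h) < 3:
        raise GeometryError("need >= 3 non-empty bins to fit a variogram")
    w = np.sqrt(n_pairs / np.maximum(h, 1e-9) ** 2)

    g_max = float(np.max(gamma))
    h_max = float(np.max(h))
    scale = g_max if g_max > 0 else 1.0

    def residual(theta):
        nug, psill, rng = theta
        model = VariogramModel(model_family, max(nug, 0.0), max(psill, 0.0), max(rng, 1e-6))
        return w * (model(h) - gamma) / scale

    x0 = np.array([0.1 * scale, 0.9 * scale, max(h_max / 3.0, 1e-3)])
    try:
        sol = least_squares(
            residual,
            x0,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 100.0 * max(h_max, 1.0)]),
        )
        if not sol.success or not np.all(np.isfinite(sol.x)):
            raise RuntimeError(sol.message)
        nug, psill, rng = sol.x
        return VariogramModel(model_family, float(nug), float(psill), float(max(rng, 1e-6)))
    except Exception as exc:  # noqa: BLE001 - fallback contract
        logger.warning("variogram fit failed (%s); falling back to pure nugget", exc)
        return VariogramModel(model_family, float(np.mean(gamma)), 0.0, max(h_max, 1.0))


# --- ordinary kriging ----------------------------------------------------------


def _average_duplicates(points: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at coincident coordinates; OK matrices need distinct points."""
    rounded = np.round(points, 9)
    uniq, inverse = np.unique(rounded, axis=0, return_inverse=True)
    if len(uniq) == len(points):
        return points, values
    logger.info("averaging %d duplicate point(s) before kriging", len(points) - len(uniq))
    out = np.zeros(len(uniq))
    counts = np.bincount(inverse, minlength=len(uniq))
    np.add.at(out, inverse, values)
    return uniq, out / counts


def krige_ordinary(
    points: np.ndarray,
    values: np.ndarray,
    variogram: VariogramModel,
    grid: Raster,
    max_neighbors: int = MAX_KRIGING_NEIGHBORS,
) -> tuple[Raster, Raster]:
    """Ordinary kriging of point data onto the grid of ``grid``.

    Solves, per target cell, the OK system with the unbiasedness constraint
    (weights sum to 1), using the covariance form C = sill - gamma. With
    more than ``max_neighbors`` observations, each cell uses its nearest
    ``max_neighbors`` points (local kriging); otherwise one global solve
    is factorized and reused. Returns (prediction, kriging variance)
    rasters on the same grid; nodata cells of ``grid`` stay nodata.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise GeometryError("ordinary kriging needs >= 2 distinct points")
    points, values = _average_duplicates(points, values)
    if len(points) < 2:
        raise GeometryError("fewer than 2 distinct points after duplicate averaging")

    lon_g, lat_g = grid.cell_centers()
    valid = grid.valid_mask()
    targets = np.column_stack([lon_g[valid], lat_g[valid]])

    pred = np.full(grid.shape, np.nan)
    kvar = np.full(grid.shape, np.nan)
    sill = variogram.nugget + variogram.partial_sill

    n = len(points)
    if n <= max_neighbors:
        # one global system: factorize once, solve all targets
        pi, pj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        dmat = great_circle_km(
            points[pi.ravel(), 0], points[pi.ravel(), 1],
            points[pj.ravel(), 0], points[pj.ravel(), 1],
        ).reshape(n, n)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = variogram.covariance(dmat)
        A[n, :n] = 1.0
        A[:n, n] = 1.0
        A[n, n] = 0.0
        d0 = great_circle_km(
            np.repeat(targets[:, 0], n), np.repeat(targets[:, 1], n),
            np.tile(points[:, 0], len(targets)), np.tile(points[:, 1], len(targets)),
        ).reshape(len(targets), n)
        B = np.empty((len(targets), n + 1))
        B[:, :n] = variogram.covariance(d0)
        B[:, n] = 1.0
        try:
            sol = np.linalg.solve(A, B.T).T  # rows: [weights..., lagrange]
        except np.linalg.LinAlgError:
            A += np.eye(n + 1) * 1e-10
            sol = np.linalg.solve(A, B.T).T
        weights = sol[:, :n]
        mu = sol[:, n]
        zhat = weights @ values
        variance = sill - np.einsum("ij,ij->i", weights, B[:, :n]) - mu
    else:
        tree = cKDTree(points)  # planar neighbor search is fine for ranking
        zhat = np.empty(len(targets))
        variance = np.empty(len(targets))
        for t, (lon, lat) in enumerate(targets):
            _, idx = tree.query([lon, lat], k=max_neighbors)
            sub = points[idx]
            vals = values[idx]
            m = len(sub)
            pi, pj = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
            dmat = great_circle_km(
                sub[pi.ravel(), 0], sub[pi.ravel(), 1],
                sub[pj.ravel(), 0], sub[pj.ravel(), 1],
            ).reshape(m, m)
            A = np.empty((m + 1, m + 1))
            A[:m, :m] = variogram.covariance(dmat)
            A[m, :m] = 1.0
            A[:m, m] = 1.0
            A[m, m] = 0.0
            b = np.empty(m + 1)
            b[:m] = variogram.covariance(
                great_circle_km(np.full(m, lon), np.full(m, lat), sub[:, 0], sub[:, 1])
            )
            b[m] = 1.0
            try:
                sol = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                sol = np.linalg.solve(A + np.eye(m + 1) * 1e-10, b)
            zhat[t] = sol[:m] @ vals
            variance[t] = sill - sol[:m] @ b[:m] - sol[m]

    pred[valid] = zhat
    kvar[valid] = np.maximum(variance, 0.0)
    return grid.copy_with(pred), grid.copy_with(kvar)


def build_tapwater_isoscape(
    base: Raster,
    tap_points: np.ndarray,
    tap_values: np.ndarray,
    variogram: VariogramModel | None = None,
    n_bins: int = 15,
) -> tuple[Raster, Raster]:
    """Tap-water isoscape = base + kriged(tap - base at the stations).

    Station values are differenced against the base raster at their cells,
    duplicate sites are pre-averaged, the difference field is interpolated
    by ordinary kriging (variogram fitted from the differences unless one
    is supplied), and the interpolated differences are added back to the
    base surface. Returns (isoscape, kriging-sd uncertainty) rasters.
    """
    tap_points = np.asarray(tap_points, dtype=float)
    tap_values = np.asarray(tap_values, dtype=float)
    base_at = extract_at(base, tap_points)
    usable = np.isfinite(base_at) & np.isfinite(tap_values)
    if usable.sum() < 3:
        raise GeometryError(
            f"need >= 3 usable tap stations inside the base extent, got {int(usable.sum())}"
        )
    pts, vals = _average_duplicates(tap_points[usable], tap_values[usable] - base_at[usable])

    if variogram is None:
        if np.allclose(vals, vals[0]):
            # constant difference field: kriging of a constant is exact
            variogram = VariogramModel("exponential", nugget=0.0, partial_sill=1.0, range_km=1.0)
        else:
            emp = empirical_variogram(pts, vals, n_bins=n_bins)
            variogram = fit_variogram(emp, "exponential")

    diff_surface, diff_var = krige_ordinary(pts, vals, variogram, base)
    iso = base.copy_with(base.values + diff_surface.values)
    unc = base.copy_with(np.sqrt(np.maximum(diff_var.values, 0.0)))
    return iso, unc
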