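"""Ordinary kriging of station HSI onto a regular grid, plus map classes.

Station-level habitat suitability is interpolated to cell centres of a
regular lat/lon grid (default 0.1°, finer than the 0.5° station spacing) by
ordinary kriging: an empirical semivariogram is estimated from binned
pairwise squared differences, a parametric model (spherical by default) is
fitted by weighted least squares, and the kriging system is solved for every
cell.  Coordinates are decimal degrees with no projection — downstream area
accounting is in cell counts, so geodesic correction is unnecessary.

Kriging predictions can undershoot zero even though suitability is
non-negative; negative values are retained and mapped to their own display
category.  Cells outside the convex hull of the stations are flagged and
excluded from all area accounting (extrapolation artifacts would distort
overlap statistics).

Display classification uses five categories: value <= 0 -> 0, then four
equal intervals over (0, 1] — (0, 0.25] -> 1 ... (0.75, inf) -> 4 (kriged
values above 1 fall in the top class).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial import Delaunay, distance_matrix

VARIOGRAM_MODELS = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class VariogramFit:
    model: str
    nugget: float
    psill: float  # partial sill; total sill = nugget + psill
    range_: float

    @property
    def sill(self) -> float:
        return self.nugget + self.psill


@dataclass(frozen=True)
class GridSpec:
    lat_range: tuple[float, float] = (27.0, 34.0)
    lon_range: tuple[float, float] = (122.0, 127.0)
    resolution: float = 0.1

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        lat_ax = np.arange(
            self.lat_range[0], self.lat_range[1] + self.resolution / 2, self.resolution
        )
        lon_ax = np.arange(
            self.lon_range[0], self.lon_range[1] + self.resolution / 2, self.resolution
        )
        lats = np.repeat(lat_ax, len(lon_ax))
        lons = np.tile(lon_ax, len(lat_ax))
        return lats, lons


@dataclass(frozen=True)
class HsiSurface:
    """Interpolated suitability on a regular grid (long format)."""

    species: str
    season: str
    grid_spec: GridSpec
    cells: pd.DataFrame  # cell_id, lat, lon, value, in_hull[, category]
    variogram: VariogramFit | None = None

    @property
    def grid_id(self) -> tuple:
        return (self.grid_spec.lat_range, self.grid_spec.lon_range, self.grid_spec.resolution)


def _gamma(model: str, h: np.ndarray, nugget: float, psill: float, rng: float) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if model == "spherical":
        hr = np.minimum(h / rng, 1.0)
        structure = 1.5 * hr - 0.5 * hr**3
    elif model == "exponential":
        structure = 1.0 - np.exp(-3.0 * h / rng)
    elif model == "gaussian":
        structure = 1.0 - np.exp(-3.0 * (h / rng) ** 2)
    else:
        raise ValueError(f"unknown variogram model {model!r}")
    return np.where(h > 0, nugget + psill * structure, 0.0)


def empirical_variogram(
    points: np.ndarray, values: np.ndarray, n_lags: int = 15, maxlag: float | None = None
) -> pd.DataFrame:
    """Binned empirical semivariogram: columns lag, gamma, count."""
    d = distance_matrix(points, points)
    iu = np.triu_indices(len(points), k=1)
    h = d[iu]
    sq = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    maxlag = maxlag if maxlag is not None else 0.5 * h.max()
    edges = np.linspace(0.0, maxlag, n_lags + 1)
    which = np.digitize(h, edges) - 1
    rows = []
    for b in range(n_lags):
        m = which == b
        if m.sum() == 0:
            continue
        rows.append({"lag": h[m].mean(), "gamma": sq[m].mean(), "count": int(m.sum())})
    return pd.DataFrame(rows)


def fit_variogram(
    points: np.ndarray,
    values: np.ndarray,
    model: str = "spherical",
    n_lags: int = 15,
) -> VariogramFit:
    """Fit variogram parameters to the empirical semivariogram by weighted
    least squares (weights proportional to sqrt of the pair count per lag)."""
    if model not in VARIOGRAM_MODELS:
        raise ValueError(f"unknown variogram model {model!r}")
    emp = empirical_variogram(points, values, n_lags=n_lags)
    if len(emp) < 3:
        raise ValueError("too few variogram lags to fit a model")
    lag = emp["lag"].to_numpy()
    gam = emp["gamma"].to_numpy()
    wts = np.sqrt(emp["count"].to_numpy(dtype=float))
    var = max(values.var(), 1e-12)

    def resid(theta):
        nugget, psill, rng = theta
        return wts * (_gamma(model, lag, nugget, psill, rng) - gam)

    x0 = np.array([1e-6, var, lag.max() / 2])
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 1e-12, 1e-6], [np.inf, np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
    )
    nugget, psill, rng = sol.x
    return VariogramFit(model=model, nugget=float(nugget), psill=float(psill), range_=float(rng))


def krige(
    lats: np.ndarray,
    lons: np.ndarray,
    values: np.ndarray,
    pred_lats: np.ndarray,
    pred_lons: np.ndarray,
    variogram_model: str = "spherical",
    variogram: VariogramFit | None = None,
    n_lags: int = 15,
) -> tuple[np.ndarray, VariogramFit]:
    """Ordinary-kriging prediction at arbitrary points.

    Pass ``variogram`` to use fixed parameters (e.g. zero nugget for exact
    interpolation tests); otherwise the variogram is fitted to the data.
    Duplicate station coordinates make the kriging system singular and are
    rejected by name.
    """
    pts = np.column_stack([np.asarray(lats, float), np.asarray(lons, float)])
    z = np.asarray(values, dtype=float)
    if len(pts) < 10:
        raise ValueError(f"need >= 10 stations to krige, got {len(pts)}")
    _, inv, counts = np.unique(
        pts.round(12), axis=0, return_inverse=True, return_counts=True
    )
    if (counts > 1).any():
        dup = np.flatnonzero(counts[inv] > 1)
        coords = ", ".join(f"({pts[i, 0]:g}, {pts[i, 1]:g})" for i in dup[:6])
        raise ValueError(f"duplicate station coordinates: {coords}")

    vgm = variogram or fit_variogram(pts, z, model=variogram_model, n_lags=n_lags)

    n = len(pts)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = _gamma(vgm.model, distance_matrix(pts, pts), vgm.nugget, vgm.psill, vgm.range_)
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    try:
        lu = lu_factor(a)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ValueError(f"singular kriging system: {exc}") from exc

    pred_pts = np.column_stack([np.asarray(pred_lats, float), np.asarray(pred_lons, float)])
    b = np.empty((n + 1, len(pred_pts)))
    b[:n] = _gamma(
        vgm.model, distance_matrix(pts, pred_pts), vgm.nugget, vgm.psill, vgm.range_
    )
    b[n] = 1.0
    lam = lu_solve(lu, b)
    return lam[:n].T @ z, vgm


def krige_hsi(
    stations: pd.DataFrame,
    grid_spec: GridSpec | None = None,
    variogram_model: str = "spherical",
    variogram: VariogramFit | None = None,
    species: str = "",
    season: str = "",
    value_col: str = "hsi",
) -> HsiSurface:
    """Krige station HSI onto the grid and flag cells outside the station hull.

    ``stations`` needs lat, lon and ``value_col`` columns.  Negative kriged
    values are retained (see module docstring).
    """
    grid_spec = grid_spec or GridSpec()
    lats = stations["lat"].to_numpy(dtype=float)
    lons = stations["lon"].to_numpy(dtype=float)
    vals = stations[value_col].to_numpy(dtype=float)
    glats, glons = grid_spec.cell_centers()
    pred, vgm = krige(lats, lons, vals, glats, glons, variogram_model, variogram)
    hull = Delaunay(np.column_stack([lats, lons]))
    in_hull = hull.find_simplex(np.column_stack([glats, glons])) >= 0
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(glats)),
            "lat": glats,
            "lon": glons,
            "value": pred,
            "in_hull": in_hull,
        }
    )
    return HsiSurface(
        species=species, season=season, grid_spec=grid_spec, cells=cells, variogram=vgm
    )


def classify_values(values: np.ndarray) -> np.ndarray:
    """Five display categories: <= 0 -> 0; (0, 0.25] -> 1; (0.25, 0.5] -> 2;
    (0.5, 0.75] -> 3; (0.75, inf) -> 4."""
    v = np.asarray(values, dtype=float)
    cat = np.ceil(v / 0.25).astype(int)
    cat = np.clip(cat, None, 4)
    cat[v <= 0] = 0
    return cat


def classify_hsi(surface: HsiSurface) -> HsiSurface:
    """Return the surface with a per-cell ``category`` column added."""
    cells = surface.cells.copy()
    cells["category"] = classify_values(cells["value"].to_numpy())
    return replace(surface, cells=cells)


def loo_error(
    lats: np.ndarray,
    lons: np.ndarray,
    values: np.ndarray,
    variogram: VariogramFit,
) -> float:
    """Leave-one-out RMSE of ordinary kriging under fixed variogram parameters."""
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    values = np.asarray(values, float)
    n = len(values)
    errs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        pred, _ = krige(
            lats[keep], lons[keep], values[keep], lats[[i]], lons[[i]], variogram=variogram
        )
        errs[i] = pred[0] - values[i]
    return float(np.sqrt(np.mean(errs**2)))
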