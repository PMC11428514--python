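"""Per-factor suitability curves: LOESS-smoothed yield, min-max normalised.

The suitability index (SI) for one environmental factor is the smoothed
yield response rescaled to [0, 1]:

    SI(x) = (Yhat(x) - Yhat_min) / (Yhat_max - Yhat_min)

where Yhat is a LOESS (locally weighted polynomial) fit of station yield
(g/h) against the factor, evaluated on an equispaced grid over the observed
factor range, and Yhat_max / Yhat_min are the extremes of those fitted
values.  Min-max normalisation makes SI invariant to positive affine
transformations of yield, so units and effort scaling drop out.

The LOESS here is the classic tricube-weighted local polynomial (default
degree 2, span 0.75), fitted independently per (species, season, factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class FlatResponseError(ValueError):
    """Smoothed yield is constant, so SI is undefined (Yhat_max == Yhat_min)."""


@dataclass(frozen=True)
class SuitabilityCurve:
    species: str
    season: str
    factor: str
    eval_grid: np.ndarray  # strictly increasing factor values
    y_hat: np.ndarray  # fitted yield on the grid, g/h (clipped at 0)
    si: np.ndarray  # suitability in [0, 1]
    y_hat_max: float
    y_hat_min: float
    loess_span: float
    loess_degree: int

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.eval_grid) > 0):
            raise ValueError("eval_grid must be strictly increasing")


def loess(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Tricube-weighted local polynomial regression.

    For each evaluation point the nearest ``ceil(span * n)`` observations are
    weighted by the tricube kernel of their scaled distance and a degree-
    ``degree`` polynomial is fitted by weighted least squares; the fitted
    value at the evaluation point is returned.  Fully vectorised over the
    evaluation grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = min(n, max(degree + 2, int(np.ceil(span * n))))

    d = np.abs(x_eval[:, None] - x[None, :])  # (m, n)
    d_k = np.partition(d, k - 1, axis=1)[:, k - 1]  # k-th nearest distance
    d_k = np.maximum(d_k, 1e-300)
    w = np.clip(1.0 - (d / d_k[:, None]) ** 3, 0.0, None) ** 3
    # the k-th point itself gets zero tricube weight; guard against rows where
    # fewer than degree+1 points carry weight (duplicated x values)
    deficient = (w > 0).sum(axis=1) < degree + 1
    if deficient.any():
        w[deficient] = np.clip(1.0 - (d[deficient] / (2 * d_k[deficient, None])) ** 3, 0.0, None) ** 3

    t = x[None, :] - x_eval[:, None]  # centred predictor, (m, n)
    powers = np.arange(degree + 1)
    basis = t[:, :, None] ** powers[None, None, :]  # (m, n, p)
    a = np.einsum("mip,miq,mi->mpq", basis, basis, w)
    b = np.einsum("mip,mi,i->mp", basis, w, y)
    a += 1e-10 * np.eye(degree + 1)[None, :, :] * np.maximum(np.trace(a, axis1=1, axis2=2), 1.0)[:, None, None]
    coef = np.linalg.solve(a, b[:, :, None])[:, :, 0]
    return coef[:, 0]  # value of the centred polynomial at t = 0


def fit_si_curve(
    yields: np.ndarray,
    factor_values: np.ndarray,
    species: str = "",
    season: str = "",
    factor: str = "",
    span: float = 0.75,
    degree: int = 2,
    n_grid: int = 100,
) -> SuitabilityCurve:
    """Fit a suitability curve for one (species, season, factor).

    Requires at least 10 stations with finite yield and factor value.  Fitted
    yields are clipped at zero before normalisation (a negative smoothed
    yield is physically meaningless; clipping cannot move the argmax).
    """
    yields = np.asarray(yields, dtype=float)
    factor_values = np.asarray(factor_values, dtype=float)
    ok = np.isfinite(yields) & np.isfinite(factor_values)
    yields, factor_values = yields[ok], factor_values[ok]
    if len(yields) < 10:
        raise ValueError(f"need >= 10 finite stations, got {len(yields)}")
    lo, hi = factor_values.min(), factor_values.max()
    if hi - lo <= 0:
        raise ValueError("all factor values identical; no gradient to fit")
    grid = np.linspace(lo, hi, n_grid)
    y_hat = np.clip(loess(factor_values, yields, grid, span=span, degree=degree), 0.0, None)
    y_max, y_min = float(y_hat.max()), float(y_hat.min())
    # numeric jitter of the regularised solver on a truly constant response
    # is ~1e-7 relative; anything below 1e-6 relative variation is flat
    if y_max - y_min <= 1e-6 * max(1.0, abs(y_max)):
        raise FlatResponseError(
            f"flat response for {species or '?'}/{season or '?'}/{factor or '?'}: "
            "smoothed yield is constant"
        )
    si = (y_hat - y_min) / (y_max - y_min)
    return SuitabilityCurve(
        species=species,
        season=season,
        factor=factor,
        eval_grid=grid,
        y_hat=y_hat,
        si=si,
        y_hat_max=y_max,
        y_hat_min=y_min,
        loess_span=span,
        loess_degree=degree,
    )


def si_at(curve: SuitabilityCurve, x) -> np.ndarray | float:
    """SI at arbitrary factor values: linear interpolation on the curve grid,
    clamped to the endpoint SI outside the observed range."""
    return np.interp(x, curve.eval_grid, curve.si)


def optimal_range(curve: SuitabilityCurve, level: float = 0.7) -> list[tuple[float, float]]:
    """Maximal grid intervals where SI >= level (possibly several: a species
    may show a secondary suitable range).  Empty if SI never reaches level."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    above = curve.si >= level
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)
    return [
        (float(curve.eval_grid[s]), float(curve.eval_grid[e]))
        for s, e in zip(starts, ends)
    ]
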