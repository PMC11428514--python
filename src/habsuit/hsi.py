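"""Composite habitat suitability: weighted AMM/GMM, CV + AIC model choice.

Per-factor suitability indices SI_i are combined into one habitat
suitability index per station using BRT weights w_i, by either

    AMM:  HSI = sum_i w_i SI_i / sum_i w_i          (weighted arithmetic mean)
    GMM:  HSI = (prod_i SI_i^w_i)^(1 / sum_i w_i)   (weighted geometric mean)

The GMM is the stricter composite — a single totally unsuitable factor
(SI = 0 with positive weight) vetoes the habitat — and by the weighted
AM-GM inequality never exceeds the AMM.  The better composite is chosen by
repeated random-split cross-validation: suitability curves are refit on 80 %
of stations, HSI is predicted on the held-out 20 %, observed suitability
(min-max-normalised raw yield) is regressed on predicted HSI by OLS, and the
model with the lower mean Gaussian AIC over the repetitions wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from habsuit.core import FACTORS, FACTOR_COLUMNS
from habsuit.importance import ImportanceWeights
from habsuit.suitability import FlatResponseError, fit_si_curve, si_at

MODELS = ("AMM", "GMM")


def _check_si_w(si: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    si = np.asarray(si, dtype=float)
    w = np.asarray(w, dtype=float)
    if si.shape[-1] != w.shape[0]:
        raise ValueError("si and w length mismatch")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    if (si < -1e-9).any() or (si > 1 + 1e-9).any():
        raise ValueError("SI values must lie in [0, 1]")
    return np.clip(si, 0.0, 1.0), w


def hsi_amm(si, w) -> float:
    """Weighted arithmetic-mean composite of per-factor SI values."""
    si, w = _check_si_w(si, w)
    return float(si @ w / w.sum())


def hsi_gmm(si, w) -> float:
    """Weighted geometric-mean composite; a zero SI with positive weight
    yields zero (one unsuitable factor vetoes the habitat)."""
    si, w = _check_si_w(si, w)
    if ((si == 0) & (w > 0)).any():
        return 0.0
    active = w > 0
    return float(np.exp((w[active] * np.log(si[active])).sum() / w.sum()))


def composite_hsi(si_matrix: np.ndarray, w, model: str) -> np.ndarray:
    """Vectorised composite over stations: ``si_matrix`` is (n_stations, n_factors)."""
    si, w = _check_si_w(np.atleast_2d(si_matrix), np.asarray(w, dtype=float))
    if model == "AMM":
        return si @ w / w.sum()
    if model == "GMM":
        active = w > 0
        veto = (si[:, active] == 0).any(axis=1)
        safe = np.maximum(si[:, active], 1e-300)
        out = np.exp((np.log(safe) * w[active]).sum(axis=1) / w.sum())
        out[veto] = 0.0
        return out
    raise ValueError(f"unknown model {model!r}")


def observed_si(yields) -> np.ndarray:
    """Observed suitability per station: min-max-normalised raw yield (the
    suitability formula applied directly to catch per unit time, unsmoothed)."""
    y = np.asarray(yields, dtype=float)
    lo, hi = y.min(), y.max()
    if hi - lo <= 0:
        raise ValueError("constant yields: observed SI undefined")
    return (y - lo) / (hi - lo)


@dataclass(frozen=True)
class CvResult:
    model: str
    n_rep: int
    train_frac: float
    seed: int
    reps: pd.DataFrame  # columns: rep, aic, slope, intercept, r2
    mean_aic: float
    n_skipped: int

    def __post_init__(self) -> None:
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")


def cross_validate(
    stations: pd.DataFrame,
    weights: ImportanceWeights,
    model: str,
    n_rep: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    refit_curves: bool = True,
    span: float = 0.75,
    degree: int = 2,
    n_grid: int = 100,
) -> CvResult:
    """Repeated random-split validation of one composite model.

    ``stations`` needs columns yield_gph, temp_c, sal_psu, depth_m.  Each
    repetition draws a seeded train/test split; suitability curves are refit
    on the training stations (set ``refit_curves=False`` to fit once on all
    data), HSI is predicted at the test stations, and observed suitability is
    regressed on predicted HSI.  The Gaussian AIC of that regression (three
    parameters: slope, intercept, error variance) is recorded per repetition;
    ``mean_aic`` is the average over non-skipped repetitions.

    Splits depend only on (seed, n_rep, train_frac), never on the model, so
    AMM and GMM results with the same seed are paired.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    n = len(stations)
    if n < 10:
        raise ValueError(f"need >= 10 stations for cross-validation, got {n}")
    yields = stations["yield_gph"].to_numpy(dtype=float)
    obs = observed_si(yields)
    x_env = {f: stations[FACTOR_COLUMNS[f]].to_numpy(dtype=float) for f in FACTORS}
    w_arr = weights.as_array()

    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 173]))

    full_curves = None
    if not refit_curves:
        full_curves = {
            f: fit_si_curve(yields, x_env[f], factor=f, span=span, degree=degree, n_grid=n_grid)
            for f in FACTORS
        }

    rows, skipped = [], 0
    for rep in range(n_rep):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if len(test) < 3:
            warnings.warn(f"rep {rep}: test subset < 3 stations, skipped", stacklevel=2)
            skipped += 1
            continue
        try:
            if refit_curves:
                curves = {
                    f: fit_si_curve(
                        yields[train], x_env[f][train], factor=f,
                        span=span, degree=degree, n_grid=n_grid,
                    )
                    for f in FACTORS
                }
            else:
                curves = full_curves
        except (FlatResponseError, ValueError) as exc:
            warnings.warn(f"rep {rep}: curve fit failed ({exc}), skipped", stacklevel=2)
            skipped += 1
            continue
        si_test = np.column_stack([si_at(curves[f], x_env[f][test]) for f in FACTORS])
        pred = composite_hsi(si_test, w_arr, model)
        if np.ptp(pred) <= 0:
            warnings.warn(f"rep {rep}: constant prediction, skipped", stacklevel=2)
            skipped += 1
            continue
        res = sm.OLS(obs[test], sm.add_constant(pred)).fit()
        aic = -2.0 * res.llf + 2.0 * 3  # slope, intercept, error variance
        rows.append(
            {
                "rep": rep,
                "aic": aic,
                "slope": float(res.params[1]),
                "intercept": float(res.params[0]),
                "r2": float(res.rsquared),
            }
        )
    if not rows:
        raise RuntimeError("every cross-validation repetition was skipped")
    reps = pd.DataFrame(rows)
    return CvResult(
        model=model,
        n_rep=n_rep,
        train_frac=train_frac,
        seed=seed,
        reps=reps,
        mean_aic=float(reps["aic"].mean()),
        n_skipped=skipped,
    )


def select_model(cv_amm: CvResult, cv_gmm: CvResult) -> str:
    """Composite with the lower mean AIC; an exact tie goes to AMM."""
    if cv_amm.model != "AMM" or cv_gmm.model != "GMM":
        raise ValueError("pass (AMM result, GMM result) in that order")
    if cv_amm.seed != cv_gmm.seed:
        raise ValueError("CV results were produced with different seeds (unpaired splits)")
    return "GMM" if cv_gmm.mean_aic < cv_amm.mean_aic else "AMM"
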