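"""Relative importance of environmental factors via boosted regression trees.

A gradient-boosted regression-tree ensemble is fitted to station yield
(log1p-transformed to tame the heavy right tail of catch data) on bottom
temperature, salinity and depth.  Each factor's relative influence is its
share of the total squared-error reduction attributable to splits on that
factor across all trees (Friedman's split-gain measure), normalised to sum
to 1.  These weights feed the composite habitat-suitability models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from habsuit.core import FACTORS, FACTOR_COLUMNS


@dataclass(frozen=True)
class BrtParams:
    """Boosting hyperparameters (gbm/dismo-style defaults)."""

    n_trees: int = 1000
    learning_rate: float = 0.01
    tree_depth: int = 3
    bag_fraction: float = 0.75


@dataclass(frozen=True)
class ImportanceWeights:
    species: str
    season: str
    w: dict[str, float]  # factor -> weight, nonnegative, sums to 1
    brt_params: BrtParams = field(default_factory=BrtParams)
    seed: int = 0

    def __post_init__(self) -> None:
        vals = np.array([self.w[f] for f in FACTORS])
        if (vals < -1e-12).any():
            raise ValueError("weights must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {vals.sum()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w[f] for f in FACTORS], dtype=float)


def fit_brt_importance(
    yields: np.ndarray,
    env: pd.DataFrame,
    params: BrtParams | None = None,
    seed: int = 0,
    species: str = "",
    season: str = "",
) -> ImportanceWeights:
    """Fit the BRT and return normalised per-factor relative influence.

    ``env`` must hold complete temp_c / sal_psu / depth_m columns (impute
    first).  A constant response carries no split information: uniform
    weights are returned with a warning.
    """
    params = params or BrtParams()
    yields = np.asarray(yields, dtype=float)
    if len(yields) < 20:
        raise ValueError(f"need >= 20 stations for BRT importance, got {len(yields)}")
    cols = [FACTOR_COLUMNS[f] for f in FACTORS]
    x = env[cols].to_numpy(dtype=float)
    if len(x) != len(yields):
        raise ValueError("env and yields length mismatch")
    if np.isnan(x).any():
        raise ValueError("env has missing values; impute before fitting")

    y = np.log1p(yields)
    if np.ptp(y) <= 0:
        warnings.warn(
            f"constant response for {species or '?'}/{season or '?'}; "
            "returning uniform weights",
            stacklevel=2,
        )
        w = {f: 1.0 / len(FACTORS) for f in FACTORS}
        return ImportanceWeights(species, season, w, params, seed)

    model = GradientBoostingRegressor(
        n_estimators=params.n_trees,
        learning_rate=params.learning_rate,
        max_depth=params.tree_depth,
        subsample=params.bag_fraction,
        random_state=seed,
    )
    model.fit(x, y)
    imp = model.feature_importances_
    total = imp.sum()
    if total <= 0:  # no informative split found
        warnings.warn("no informative splits; returning uniform weights", stacklevel=2)
        imp = np.ones(len(FACTORS))
        total = imp.sum()
    w = {f: float(v / total) for f, v in zip(FACTORS, imp)}
    return ImportanceWeights(species, season, w, params, seed)


def dominant_factor(weights: ImportanceWeights, margin: float = 0.1) -> str | None:
    """The top factor if it beats the runner-up by at least ``margin``.

    Returns None when no factor stands out — the community-analysis notion
    of "no predominant influencing factor" made operational.
    """
    order = sorted(FACTORS, key=lambda f: weights.w[f], reverse=True)
    if weights.w[order[0]] - weights.w[order[1]] >= margin:
        return order[0]
    return None
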