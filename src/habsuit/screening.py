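"""Survey-table I/O, yield computation and seasonal dominance screening.

The analysed species set per season is defined by biomass dominance: a
species is retained when its share of the season's total catch weight
strictly exceeds a threshold (default 5 %).  Proportions are always taken
over the all-species season total, so the retained species' cumulative
proportion is generally below 1 — it measures how much of the community the
dominant set represents.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from habsuit.core import CATCH_COLUMNS, ENV_COLUMNS, SEASONS

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Input table failed validation; ``errors`` lists offending lines."""

    def __init__(self, message: str, errors: list[str]):
        super().__init__(message + "\n" + "\n".join(errors))
        self.errors = errors


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns", [", ".join(missing)])


def read_catch(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-station catch table.

    Required columns: station_id, lat, lon, season, species, weight_g, tow_h.
    Rows with negative weight, non-positive tow duration or an unknown season
    are reported with their file line numbers (header = line 1).
    """
    df = pd.read_csv(path)
    _check_columns(df, CATCH_COLUMNS, path)
    if df.empty:
        warnings.warn(f"{path}: catch table is empty", stacklevel=2)
        return df
    errors = []
    lines = df.index + 2  # header occupies line 1
    for idx, line in zip(df.index, lines):
        row = df.loc[idx]
        if not np.isfinite(row["weight_g"]) or row["weight_g"] < 0:
            errors.append(f"line {line}: weight_g must be >= 0, got {row['weight_g']}")
        if not np.isfinite(row["tow_h"]) or row["tow_h"] <= 0:
            errors.append(f"line {line}: tow_h must be > 0, got {row['tow_h']}")
        if row["season"] not in SEASONS:
            errors.append(f"line {line}: unknown season {row['season']!r}")
    if errors:
        raise ValidationError(f"{path}: invalid catch records", errors)
    return df


def read_env(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-station environment table.

    Required columns: station_id, lat, lon, season, temp_c, sal_psu, depth_m,
    source.  Missing values are allowed (source ``"missing"``) and handled by
    imputation downstream; present values must satisfy depth > 0 and
    salinity within [0, 45].
    """
    df = pd.read_csv(path)
    _check_columns(df, ENV_COLUMNS, path)
    if df.empty:
        warnings.warn(f"{path}: env table is empty", stacklevel=2)
        return df
    errors = []
    for idx, line in zip(df.index, df.index + 2):
        row = df.loc[idx]
        if row["season"] not in SEASONS:
            errors.append(f"line {line}: unknown season {row['season']!r}")
        if np.isfinite(row["depth_m"]) and row["depth_m"] <= 0:
            errors.append(f"line {line}: depth_m must be > 0, got {row['depth_m']}")
        if np.isfinite(row["sal_psu"]) and not 0 <= row["sal_psu"] <= 45:
            errors.append(f"line {line}: sal_psu out of [0, 45], got {row['sal_psu']}")
        if row["source"] not in ("measured", "modelled", "missing"):
            errors.append(f"line {line}: unknown source {row['source']!r}")
    if errors:
        raise ValidationError(f"{path}: invalid env records", errors)
    return df


def compute_yield(weight_g: float, tow_h: float) -> float:
    """Fishing yield in g/h: catch weight divided by tow duration."""
    if tow_h <= 0:
        raise ValueError("tow_h must be positive")
    return weight_g / tow_h


def add_yield(catch: pd.DataFrame) -> pd.DataFrame:
    """Append a ``yield_gph`` column (g/h) to a catch table."""
    out = catch.copy()
    out["yield_gph"] = out["weight_g"] / out["tow_h"]
    return out


def screen_species(catch: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Seasonal dominance screening.

    Per season: sum each species' catch weight across stations, take its
    proportion of the all-species season total, and retain species whose
    proportion strictly exceeds ``threshold``.  Retained species are ordered
    by descending biomass and the cumulative proportion is computed down that
    list.  Columns: season, species, biomass_g, proportion, cumulative.
    """
    if catch.empty:
        raise ValueError("catch table is empty")
    frames = []
    for season, grp in catch.groupby("season", sort=False):
        totals = grp.groupby("species", sort=False)["weight_g"].sum()
        season_total = totals.sum()
        if season_total <= 0:
            raise ValueError(f"season {season!r} has zero total biomass")
        prop = totals / season_total
        kept = prop[prop > threshold]
        # descending biomass; species name breaks exact ties deterministically
        kept = kept.sort_index(kind="stable").sort_values(
            ascending=False, kind="stable"
        )
        frames.append(
            pd.DataFrame(
                {
                    "season": season,
                    "species": kept.index,
                    "biomass_g": totals[kept.index].to_numpy(),
                    "proportion": kept.to_numpy(),
                    "cumulative": kept.cumsum().to_numpy(),
                }
            )
        )
        if kept.empty:
            log.info("season %s: no species exceeds threshold %.3f", season, threshold)
    order = [s for s in SEASONS if s in set(catch["season"])]
    out = pd.concat(frames, ignore_index=True)
    out["season"] = pd.Categorical(out["season"], categories=order, ordered=True)
    return out.sort_values(["season", "proportion"], ascending=[True, False], kind="stable").reset_index(
        drop=True
    )
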