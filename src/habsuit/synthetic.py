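"""Synthetic trawl-survey generator with known ground-truth species responses.

Emulates a fixed-station bottom-trawl survey on a regular graticule
(default: 30-arcminute spacing over 27–34° N, 122–127° E, the East China
Sea shelf): smooth seasonal bottom-temperature / salinity / depth fields,
species with unimodal (Gaussian) preference responses to each factor,
heavy-tailed multiplicative catch noise with zero inflation, and partial
environmental missingness with an imputation step standing in for the
external-model gap-fill used on real surveys.

Because every species' preference optimum, width and peak yield are known,
downstream stages (suitability curves, factor importance, composite model
selection, overlap trends) are testable by parameter recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from habsuit.core import FACTORS, FACTOR_COLUMNS, SEASONS

Field2D = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class SurveyGrid:
    """Rectangular lattice of survey stations (cell centres, decimal degrees)."""

    station_ids: tuple[str, ...]
    lats: np.ndarray
    lons: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if len(set(self.station_ids)) != len(self.station_ids):
            raise ValueError("station ids must be unique")

    def __len__(self) -> int:
        return len(self.station_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"station_id": self.station_ids, "lat": self.lats, "lon": self.lons}
        )


@dataclass(frozen=True)
class SpeciesResponseSpec:
    """Ground-truth species-environment response.

    Expected yield at a station is ``q_max * prod_f exp(-((x_f - mu_f)/sigma_f)^2)``
    over the three factors; realised yield multiplies a lognormal(0, noise_sigma)
    factor and is zeroed with probability ``zero_inflation``.  ``weight_share``
    records the intended relative influence of each factor (sums to 1); in the
    generator a factor's actual influence is governed by how narrow ``sigma`` is
    relative to the field's range — ``weight_shares_from_sigmas`` derives
    consistent shares.  ``sigma = inf`` makes a factor uninformative.
    """

    species: str
    q_max: float  # peak expected yield, g/h
    mu: dict[str, float]  # factor -> preference optimum
    sigma: dict[str, float]  # factor -> preference width (may be inf)
    weight_share: dict[str, float]
    noise_sigma: float = 0.0  # log-scale multiplicative noise
    zero_inflation: float = 0.0

    def __post_init__(self) -> None:
        if self.q_max <= 0:
            raise ValueError(f"{self.species}: q_max must be positive")
        for f in FACTORS:
            if self.sigma[f] <= 0:
                raise ValueError(f"{self.species}: sigma[{f}] must be positive")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError(f"{self.species}: zero_inflation must be in [0, 1]")
        total = sum(self.weight_share.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"{self.species}: weight_share must sum to 1, got {total}")

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "q_max": self.q_max,
            "mu": dict(self.mu),
            "sigma": {k: (None if math.isinf(v) else v) for k, v in self.sigma.items()},
            "weight_share": dict(self.weight_share),
            "noise_sigma": self.noise_sigma,
            "zero_inflation": self.zero_inflation,
        }


@dataclass
class SeasonScenario:
    """One season's environmental fields, species set and missingness regime."""

    season: str
    temp_field: Field2D
    sal_field: Field2D
    depth_field: Field2D
    species_specs: list[SpeciesResponseSpec]
    env_missing_fraction: float = 0.0
    missing_block_south_of: float | None = None  # flag all stations south of this lat
    seed: int = 0

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if not 0.0 <= self.env_missing_fraction <= 0.5:
            raise ValueError("env_missing_fraction must be in [0, 0.5]")

    def field_for(self, factor: str) -> Field2D:
        return {"temp": self.temp_field, "sal": self.sal_field, "depth": self.depth_field}[factor]


def make_grid(
    lat_range: tuple[float, float],
    lon_range: tuple[float, float],
    spacing: float,
) -> SurveyGrid:
    """Build the full rectangular station lattice, endpoints included.

    Stations are row-major (latitude outer, longitude inner), lowest
    latitude first, with deterministic ids ``S001, S002, ...``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    axes = []
    for name, (lo, hi) in (("latitude", lat_range), ("longitude", lon_range)):
        if hi < lo:
            raise ValueError(f"{name} range must be ordered (lo <= hi)")
        n_steps = (hi - lo) / spacing
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                f"spacing {spacing} does not divide the {name} range [{lo}, {hi}]"
            )
        axes.append(lo + spacing * np.arange(round(n_steps) + 1))
    lat_ax, lon_ax = axes
    lats = np.repeat(lat_ax, len(lon_ax))
    lons = np.tile(lon_ax, len(lat_ax))
    ids = tuple(f"S{i + 1:03d}" for i in range(len(lats)))
    return SurveyGrid(station_ids=ids, lats=lats, lons=lons, spacing=spacing)


def make_env_fields(
    grid: SurveyGrid,
    scenario: SeasonScenario,
    with_missing: bool = True,
) -> pd.DataFrame:
    """Evaluate the scenario's parametric surfaces at station centres.

    Returns one env record per station.  When ``with_missing`` is true, a
    seeded subset of stations (``round(env_missing_fraction * n)`` of them,
    plus any station south of ``missing_block_south_of``) has its three
    environmental values blanked and its source set to ``"missing"``.
    """
    env = grid.to_frame()
    env["season"] = scenario.season
    for factor in FACTORS:
        vals = np.asarray(scenario.field_for(factor)(grid.lats, grid.lons), dtype=float)
        if factor == "depth" and np.any(vals <= 0):
            raise ValueError("depth_field must be strictly positive over the grid")
        env[FACTOR_COLUMNS[factor]] = vals
    env["source"] = "measured"

    if with_missing:
        n = len(env)
        missing = np.zeros(n, dtype=bool)
        if scenario.missing_block_south_of is not None:
            missing |= env["lat"].to_numpy() < scenario.missing_block_south_of
        n_random = round(scenario.env_missing_fraction * n)
        if n_random:
            rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 11]))
            candidates = np.flatnonzero(~missing)
            take = rng.choice(candidates, size=min(n_random, len(candidates)), replace=False)
            missing[take] = True
        cols = [FACTOR_COLUMNS[f] for f in FACTORS]
        env.loc[missing, cols] = np.nan
        env.loc[missing, "source"] = "missing"
    return env[["station_id", "lat", "lon", "season", "temp_c", "sal_psu", "depth_m", "source"]]


def expected_yield(spec: SpeciesResponseSpec, env: pd.DataFrame) -> np.ndarray:
    """Noiseless expected yield (g/h) at each env row under a response spec."""
    log_resp = np.zeros(len(env))
    for factor in FACTORS:
        sigma = spec.sigma[factor]
        if math.isinf(sigma):
            continue
        x = env[FACTOR_COLUMNS[factor]].to_numpy(dtype=float)
        log_resp -= ((x - spec.mu[factor]) / sigma) ** 2
    return spec.q_max * np.exp(log_resp)


def sample_catch(
    grid: SurveyGrid,
    env: pd.DataFrame,
    specs: Sequence[SpeciesResponseSpec],
    seed: int,
) -> pd.DataFrame:
    """Draw one tow per station and species from the ground-truth responses.

    ``env`` must hold the true (complete) fields: sampling never uses
    gap-filled values.  Tow duration is fixed at 1 h so catch weight and
    yield coincide numerically.  Zero-yield rows are kept — absence carries
    information downstream.
    """
    missing_ids = set(grid.station_ids) - set(env["station_id"])
    if missing_ids:
        raise ValueError(f"stations absent from env table: {sorted(missing_ids)[:5]}")
    cols = [FACTOR_COLUMNS[f] for f in FACTORS]
    sub = env[env["station_id"].isin(grid.station_ids)]
    if sub[cols].isna().any().any():
        raise ValueError("env table has missing values; sample from the true fields")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    frames = []
    for spec in specs:
        mu_y = expected_yield(spec, sub)
        y = mu_y.copy()
        if spec.noise_sigma > 0:
            y = y * np.exp(rng.normal(0.0, spec.noise_sigma, size=len(sub)))
        if spec.zero_inflation > 0:
            y[rng.random(len(sub)) < spec.zero_inflation] = 0.0
        frames.append(
            pd.DataFrame(
                {
                    "station_id": sub["station_id"].to_numpy(),
                    "lat": sub["lat"].to_numpy(),
                    "lon": sub["lon"].to_numpy(),
                    "season": sub["season"].to_numpy(),
                    "species": spec.species,
                    "weight_g": y,
                    "tow_h": 1.0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def impute_env(env: pd.DataFrame, method: str = "idw") -> pd.DataFrame:
    """Fill missing environmental values from measured stations.

    ``idw`` — inverse-squared-distance weighting over all measured stations;
    ``nearest`` — value of the geographically closest measured station.
    Measured rows are never altered; imputed rows get source ``"modelled"``.
    """
    if method not in ("idw", "nearest"):
        raise ValueError(f"unknown imputation method {method!r}")
    out = env.copy()
    imputed_any = np.zeros(len(out), dtype=bool)
    for factor in FACTORS:
        col = FACTOR_COLUMNS[factor]
        vals = out[col].to_numpy(dtype=float)
        miss = np.isnan(vals)
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(f"all values missing for factor {factor!r}; cannot impute")
        pts = out[["lat", "lon"]].to_numpy(dtype=float)
        known_pts, known_vals = pts[~miss], vals[~miss]
        if method == "nearest":
            _, idx = cKDTree(known_pts).query(pts[miss])
            vals[miss] = known_vals[idx]
        else:
            d = np.sqrt(((pts[miss, None, :] - known_pts[None, :, :]) ** 2).sum(axis=2))
            exact = d < 1e-12
            # a coincident measured station wins outright; otherwise 1/d^2 weights
            w = np.where(
                exact.any(axis=1, keepdims=True),
                exact.astype(float),
                1.0 / np.maximum(d, 1e-12) ** 2,
            )
            vals[miss] = (w * known_vals).sum(axis=1) / w.sum(axis=1)
        out[col] = vals
        imputed_any |= miss
    out.loc[imputed_any, "source"] = "modelled"
    return out


def weight_shares_from_sigmas(
    sigma: dict[str, float], spans: dict[str, float]
) -> dict[str, float]:
    """Relative factor influence implied by preference widths.

    A factor matters in proportion to how much the response can vary over the
    field's span: share_f ∝ (span_f / sigma_f)^2, normalised to sum to 1.
    """
    raw = {
        f: 0.0 if math.isinf(sigma[f]) else (spans[f] / sigma[f]) ** 2 for f in FACTORS
    }
    total = sum(raw.values())
    if total == 0:
        return {f: 1.0 / len(FACTORS) for f in FACTORS}
    return {f: v / total for f, v in raw.items()}


# ---------------------------------------------------------------------------
# Default four-season study conditions
# ---------------------------------------------------------------------------

_SEASON_TEMP_BASE = {"spring": 16.0, "summer": 26.0, "autumn": 20.0, "winter": 11.0}
_SEASON_SAL_OFFSET = {"spring": 0.0, "summer": -0.6, "autumn": 0.2, "winter": 0.5}

#: species preference optima are placed at centre + spread * offset; the
#: spread shrinks from spring to winter (habitat preferences converge as the
#: community shifts from dispersed breeding to shared overwintering grounds)
_SEASON_SPREAD = {"spring": 2.0, "summer": 1.2, "autumn": 0.7, "winter": 0.1}

_DOMINANT = [
    ("hairtail", 30000.0, 1.0),
    ("small_yellow_croaker", 20000.0, 0.5),
    ("pacific_squid", 15000.0, 0.0),
    ("half_fin_anchovy", 9000.0, -0.5),
    ("bombay_duck", 7000.0, -1.0),
]


def _season_fields(season: str) -> tuple[Field2D, Field2D, Field2D]:
    t0 = _SEASON_TEMP_BASE[season]
    s0 = _SEASON_SAL_OFFSET[season]

    def temp(lat, lon):
        return t0 - 0.9 * (np.asarray(lat) - 30.5) + 0.35 * (np.asarray(lon) - 124.5)

    def sal(lat, lon):
        return (
            32.0
            + s0
            + 0.55 * (np.asarray(lon) - 124.5)
            - 0.12 * (np.asarray(lat) - 30.5)
        )

    def depth(lat, lon):
        # shelf deepening offshore (east) and slightly northward; 20-161 m
        return 20.0 + 24.0 * (np.asarray(lon) - 122.0) + 3.0 * (np.asarray(lat) - 27.0)

    return temp, sal, depth


def default_scenarios(
    seed: int = 42,
    noise_sigma: float = 0.3,
    zero_inflation: float = 0.2,
    env_missing_fraction: float = 0.1,
) -> list[SeasonScenario]:
    """The default four-season study conditions.

    A 30-arcminute station lattice's worth of smooth fields, five dominant
    species whose preference optima converge progressively from spring to
    winter, and a handful of low-biomass background species.  Lognormal
    catch noise (sigma 0.3) and 20 % zero inflation mimic heavy-tailed,
    zero-rich trawl catches; 10 % of stations lose their CTD cast.
    """
    scenarios = []
    spans = {"temp": 8.0, "sal": 4.0, "depth": 140.0}
    scales = {"temp": 2.0, "sal": 0.9, "depth": 35.0}  # offset -> factor units
    sigmas = {"temp": 2.5, "sal": 1.2, "depth": 45.0}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    for si, season in enumerate(SEASONS):
        temp_f, sal_f, depth_f = _season_fields(season)
        centre = {
            "temp": float(temp_f(np.array(30.5), np.array(124.5))),
            "sal": float(sal_f(np.array(30.5), np.array(124.5))),
            "depth": float(depth_f(np.array(30.5), np.array(124.5))),
        }
        spread = _SEASON_SPREAD[season]
        specs = []
        for name, q_max, offset in _DOMINANT:
            mu = {f: centre[f] + spread * scales[f] * offset for f in FACTORS}
            sigma = dict(sigmas)
            specs.append(
                SpeciesResponseSpec(
                    species=name,
                    q_max=q_max,
                    mu=mu,
                    sigma=sigma,
                    weight_share=weight_shares_from_sigmas(sigma, spans),
                    noise_sigma=noise_sigma,
                    zero_inflation=zero_inflation,
                )
            )
        for b in range(6):  # low-biomass background species, each well below 5 %
            mu = {
                f: centre[f] + float(rng.uniform(-1.5, 1.5)) * scales[f] for f in FACTORS
            }
            sigma = {f: sigmas[f] * float(rng.uniform(1.0, 2.0)) for f in FACTORS}
            specs.append(
                SpeciesResponseSpec(
                    species=f"background_{b + 1:02d}",
                    q_max=float(rng.uniform(200.0, 600.0)),
                    mu=mu,
                    sigma=sigma,
                    weight_share=weight_shares_from_sigmas(sigma, spans),
                    noise_sigma=noise_sigma,
                    zero_inflation=zero_inflation,
                )
            )
        scenarios.append(
            SeasonScenario(
                season=season,
                temp_field=temp_f,
                sal_field=sal_f,
                depth_field=depth_f,
                species_specs=specs,
                env_missing_fraction=env_missing_fraction,
                seed=seed * 1000 + si,
            )
        )
    return scenarios


def generate_survey(
    scenarios: Sequence[SeasonScenario],
    grid: SurveyGrid | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the generator for each season.

    Returns (catch table, observed env table with missingness, ground-truth
    sidecar dict keyed by season).  Catch is always sampled from the true
    fields; the observed env table is what an analyst would see.
    """
    if grid is None:
        grid = make_grid((27.0, 34.0), (122.0, 127.0), 0.5)
    catch_frames, env_frames, truth = [], [], {}
    for sc in scenarios:
        true_env = make_env_fields(grid, sc, with_missing=False)
        obs_env = make_env_fields(grid, sc, with_missing=True)
        catch_frames.append(sample_catch(grid, true_env, sc.species_specs, seed=sc.seed))
        env_frames.append(obs_env)
        truth[sc.season] = {
            "seed": sc.seed,
            "env_missing_fraction": sc.env_missing_fraction,
            "species": [spec.to_dict() for spec in sc.species_specs],
        }
    return (
        pd.concat(catch_frames, ignore_index=True),
        pd.concat(env_frames, ignore_index=True),
        truth,
    )


def write_survey(
    catch: pd.DataFrame, env: pd.DataFrame, truth: dict, outdir: str | Path
) -> dict[str, Path]:
    """Write catch/env CSVs and the ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "catch": outdir / "catch.csv",
        "env": outdir / "env.csv",
        "truth": outdir / "truth.json",
    }
    catch.to_csv(paths["catch"], index=False)
    env.to_csv(paths["env"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
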