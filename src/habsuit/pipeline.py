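"""End-to-end orchestration: screen -> SI -> importance -> HSI -> krige -> overlap.

Each stage is a plain function over DataFrames so the command-line interface
can run stages independently from CSVs; ``run_pipeline`` chains them, writes
every stage's output under the configured outdir, and records a manifest
(config, derived seeds, output checksums).  A single top-level seed
deterministically derives every stage seed, so a full run is bit-exact
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from habsuit.config import PipelineConfig
from habsuit.core import FACTORS, FACTOR_COLUMNS, SEASONS
from habsuit.hsi import composite_hsi, cross_validate, observed_si, select_model
from habsuit.importance import ImportanceWeights, fit_brt_importance
from habsuit.overlap import (
    OptimalMask,
    extract_optimal,
    overlap_levels,
    seasonal_report,
    summarize_overlap,
)
from habsuit.screening import add_yield, read_catch, read_env, screen_species
from habsuit.spatial import GridSpec, HsiSurface, classify_hsi, krige_hsi
from habsuit.suitability import fit_si_curve, si_at
from habsuit.synthetic import impute_env

log = logging.getLogger(__name__)

_STAGE_CODES = {"brt": 1, "cv": 2}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def derive_seed(root_seed: int, stage: str, season: str, species: str) -> int:
    """Deterministic per-(stage, season, species) integer seed below 2^31."""
    key = [
        root_seed,
        _STAGE_CODES[stage],
        SEASONS.index(season),
        int(hashlib.sha256(species.encode()).hexdigest()[:8], 16),
    ]
    return int(np.random.default_rng(np.random.SeedSequence(key)).integers(2**31))


def station_table(catch: pd.DataFrame, env: pd.DataFrame, season: str, species: str) -> pd.DataFrame:
    """One row per station for a (season, species): env joined with yield.

    Stations with no catch record for the species get yield 0 — absence is a
    real observation from a fixed-station survey.
    """
    env_s = env[env["season"] == season].drop_duplicates("station_id")
    cs = catch[(catch["season"] == season) & (catch["species"] == species)]
    y = cs.groupby("station_id")["yield_gph"].sum()
    out = env_s.copy()
    out["yield_gph"] = out["station_id"].map(y).fillna(0.0)
    return out.reset_index(drop=True)


@dataclass
class SpeciesSeasonResult:
    species: str
    season: str
    curves: dict
    weights: ImportanceWeights
    cv_amm: object
    cv_gmm: object
    chosen_model: str
    stations: pd.DataFrame  # with hsi and observed_si columns
    surface: HsiSurface
    threshold_surface: HsiSurface  # surface the optimal-habitat cutoff is applied to


@dataclass
class PipelineResult:
    config: PipelineConfig
    dominance: pd.DataFrame
    env: pd.DataFrame
    per_species: list[SpeciesSeasonResult]
    masks_by_season: dict[str, list[OptimalMask]]
    summaries: list
    report: pd.DataFrame
    intersections: pd.DataFrame
    outputs: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _analyze_species_season(
    catch: pd.DataFrame,
    env: pd.DataFrame,
    season: str,
    species: str,
    cfg: PipelineConfig,
) -> SpeciesSeasonResult:
    st = station_table(catch, env, season, species)
    yields = st["yield_gph"].to_numpy(dtype=float)

    curves = {
        f: fit_si_curve(
            yields,
            st[FACTOR_COLUMNS[f]].to_numpy(dtype=float),
            species=species,
            season=season,
            factor=f,
            span=cfg.loess_span,
            degree=cfg.loess_degree,
            n_grid=cfg.si_n_grid,
        )
        for f in FACTORS
    }
    weights = fit_brt_importance(
        yields,
        st,
        params=cfg.brt,
        seed=derive_seed(cfg.seed, "brt", season, species),
        species=species,
        season=season,
    )
    cv_seed = derive_seed(cfg.seed, "cv", season, species)
    cv_kwargs = dict(
        n_rep=cfg.cv_n_rep,
        train_frac=cfg.cv_train_frac,
        seed=cv_seed,
        refit_curves=cfg.cv_refit_curves,
        span=cfg.loess_span,
        degree=cfg.loess_degree,
        n_grid=cfg.si_n_grid,
    )
    cv_amm = cross_validate(st, weights, "AMM", **cv_kwargs)
    cv_gmm = cross_validate(st, weights, "GMM", **cv_kwargs)
    chosen = select_model(cv_amm, cv_gmm)

    si_matrix = np.column_stack(
        [si_at(curves[f], st[FACTOR_COLUMNS[f]].to_numpy(dtype=float)) for f in FACTORS]
    )
    st = st.assign(
        hsi=composite_hsi(si_matrix, weights.as_array(), chosen),
        observed_si=observed_si(yields),
        model=chosen,
    )
    grid_spec = GridSpec(resolution=cfg.kriging_resolution)
    surface = classify_hsi(
        krige_hsi(
            st,
            grid_spec=grid_spec,
            variogram_model=cfg.kriging_variogram,
            species=species,
            season=season,
            value_col="hsi",
        )
    )
    if cfg.overlap_target == "si":
        threshold_surface = classify_hsi(
            krige_hsi(
                st,
                grid_spec=grid_spec,
                variogram_model=cfg.kriging_variogram,
                species=species,
                season=season,
                value_col="observed_si",
            )
        )
    else:
        threshold_surface = surface
    return SpeciesSeasonResult(
        species=species,
        season=season,
        curves=curves,
        weights=weights,
        cv_amm=cv_amm,
        cv_gmm=cv_gmm,
        chosen_model=chosen,
        stations=st,
        surface=surface,
        threshold_surface=threshold_surface,
    )


def run_pipeline(
    config: PipelineConfig,
    catch: pd.DataFrame | None = None,
    env: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full analysis and write every stage's output.

    ``catch``/``env`` may be passed in memory; otherwise they are read from
    the configured paths.  Outputs (all CSV + one JSON manifest) land under
    ``config.outdir``.
    """
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        log.info("stage=%s", name)
        return name

    stage = _stage("read")
    try:
        if catch is None:
            if not cfg.catch_path or not Path(cfg.catch_path).exists():
                raise FileNotFoundError(f"catch table not found: {cfg.catch_path}")
            catch = read_catch(cfg.catch_path)
        if env is None:
            if not cfg.env_path or not Path(cfg.env_path).exists():
                raise FileNotFoundError(f"env table not found: {cfg.env_path}")
            env = read_env(cfg.env_path)
        catch = add_yield(catch)

        stage = _stage("impute")
        env = impute_env(env, method=cfg.impute_method)

        stage = _stage("screen")
        dominance = screen_species(catch, threshold=cfg.screening_threshold)

        per_species: list[SpeciesSeasonResult] = []
        seasons = [s for s in SEASONS if s in set(catch["season"])]
        for season in seasons:
            kept = dominance.loc[dominance["season"] == season, "species"]
            for species in kept:
                stage = _stage(f"model:{season}:{species}")
                log.info("stage=model season=%s species=%s", season, species)
                per_species.append(
                    _analyze_species_season(catch, env, season, species, cfg)
                )

        stage = _stage("overlap")
        masks_by_season: dict[str, list[OptimalMask]] = {}
        for r in per_species:
            mask = extract_optimal(
                r.threshold_surface,
                threshold=cfg.overlap_threshold,
                min_cells=cfg.overlap_min_cells,
            )
            if mask is None:
                log.info(
                    "overlap: %s/%s excluded (optimal range below min_cells)",
                    r.season,
                    r.species,
                )
                continue
            masks_by_season.setdefault(r.season, []).append(mask)
        summaries, inter_frames = [], []
        for season in seasons:
            masks = masks_by_season.get(season, [])
            if not masks:
                continue
            summaries.append(summarize_overlap(masks, cfg.overlap_weights))
            _, inter = overlap_levels(masks)
            inter.insert(0, "season", season)
            inter_frames.append(inter)
        intersections = (
            pd.concat(inter_frames, ignore_index=True)
            if inter_frames
            else pd.DataFrame(columns=["season", "subset", "n_species", "count"])
        )
        report = seasonal_report(summaries) if summaries else pd.DataFrame()

        stage = _stage("write")
        result = PipelineResult(
            config=cfg,
            dominance=dominance,
            env=env,
            per_species=per_species,
            masks_by_season=masks_by_season,
            summaries=summaries,
            report=report,
            intersections=intersections,
        )
        _write_outputs(result, outdir)
        return result
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    cfg = result.config
    frames: dict[str, pd.DataFrame] = {}
    frames["dominance.csv"] = result.dominance
    frames["env_imputed.csv"] = result.env

    curve_rows, weight_rows, cv_rows, hsi_rows, surf_rows, mask_rows = [], [], [], [], [], []
    for r in result.per_species:
        for f, c in r.curves.items():
            curve_rows.append(
                pd.DataFrame(
                    {
                        "species": r.species,
                        "season": r.season,
                        "factor": f,
                        "factor_value": c.eval_grid,
                        "y_hat": c.y_hat,
                        "si": c.si,
                    }
                )
            )
        weight_rows.append(
            {
                "species": r.species,
                "season": r.season,
                "w_temp": r.weights.w["temp"],
                "w_sal": r.weights.w["sal"],
                "w_depth": r.weights.w["depth"],
                "seed": r.weights.seed,
            }
        )
        for cv in (r.cv_amm, r.cv_gmm):
            d = cv.reps.copy()
            d.insert(0, "species", r.species)
            d.insert(1, "season", r.season)
            d.insert(2, "model", cv.model)
            d["mean_aic"] = cv.mean_aic
            d["n_skipped"] = cv.n_skipped
            cv_rows.append(d)
        hsi_rows.append(
            r.stations[["station_id", "season", "model", "hsi", "observed_si"]].assign(
                species=r.species
            )
        )
        sc = r.surface.cells.copy()
        sc.insert(0, "species", r.species)
        sc.insert(1, "season", r.season)
        if r.surface.variogram is not None:
            sc["variogram"] = r.surface.variogram.model
        surf_rows.append(sc)
    for season, masks in result.masks_by_season.items():
        for m in masks:
            mask_rows.append(
                pd.DataFrame(
                    {
                        "season": season,
                        "species": m.species,
                        "cell_id": sorted(m.cells),
                        "threshold": m.threshold,
                    }
                )
            )

    frames["si_curves.csv"] = pd.concat(curve_rows, ignore_index=True)
    frames["importance.csv"] = pd.DataFrame(weight_rows)
    frames["cv_results.csv"] = pd.concat(cv_rows, ignore_index=True)
    frames["hsi_stations.csv"] = pd.concat(hsi_rows, ignore_index=True)
    frames["hsi_surface.csv"] = pd.concat(surf_rows, ignore_index=True)
    frames["optimal_masks.csv"] = (
        pd.concat(mask_rows, ignore_index=True)
        if mask_rows
        else pd.DataFrame(columns=["season", "species", "cell_id", "threshold"])
    )
    frames["intersections.csv"] = result.intersections
    frames["overlap_summary.csv"] = pd.DataFrame(
        [
            {
                "season": s.season,
                "count_area": s.count_area,
                "n_single": s.level_counts["single"],
                "n_pair": s.level_counts["pair"],
                "n_multi": s.level_counts["multi"],
                "a_single": s.a["single"],
                "a_pair": s.a["pair"],
                "a_multi": s.a["multi"],
                "overlap_index": s.index,
            }
            for s in result.summaries
        ]
    )
    frames["seasonal_report.csv"] = result.report

    checksums = {}
    for name, df in frames.items():
        path = outdir / name
        df.to_csv(path, index=False)
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
        result.outputs[name] = path

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "checksums": checksums,
        "n_species_season": len(result.per_species),
        "seasons": sorted({r.season for r in result.per_species}),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result.outputs["manifest.json"] = manifest_path
    result.manifest = manifest
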