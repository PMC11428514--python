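"""Pipeline configuration: defaults, YAML loading, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from habsuit.importance import BrtParams
from habsuit.overlap import DEFAULT_LEVEL_WEIGHTS, LEVELS
from habsuit.spatial import VARIOGRAM_MODELS


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the analysis pipeline, with field-conventional defaults.

    YAML layout mirrors the stage structure, e.g.::

        seed: 42
        screening: {threshold: 0.05}
        loess: {span: 0.75, degree: 2}
        si: {n_grid: 100}
        brt: {n_trees: 1000, learning_rate: 0.01, tree_depth: 3, bag_fraction: 0.75}
        cv: {n_rep: 100, train_frac: 0.8, refit_curves: true}
        kriging: {variogram: spherical, resolution: 0.1}
        overlap: {threshold: 0.7, min_cells: 0, target: hsi,
                  weights: {single: -0.5, pair: 1, multi: 2}}
    """

    seed: int = 42
    catch_path: str | None = None
    env_path: str | None = None
    outdir: str = "habsuit_out"
    screening_threshold: float = 0.05
    loess_span: float = 0.75
    loess_degree: int = 2
    si_n_grid: int = 100
    brt: BrtParams = field(default_factory=BrtParams)
    cv_n_rep: int = 100
    cv_train_frac: float = 0.8
    cv_refit_curves: bool = True
    kriging_variogram: str = "spherical"
    kriging_resolution: float = 0.1
    impute_method: str = "idw"
    overlap_threshold: float = 0.7
    overlap_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_WEIGHTS)
    )
    overlap_min_cells: int = 0
    overlap_target: str = "hsi"  # threshold kriged HSI, or kriged observed SI

    def __post_init__(self) -> None:
        for name, v in (
            ("screening.threshold", self.screening_threshold),
            ("loess.span", self.loess_span),
            ("cv.train_frac", self.cv_train_frac),
            ("overlap.threshold", self.overlap_threshold),
        ):
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.kriging_variogram not in VARIOGRAM_MODELS:
            raise ValueError(f"unknown variogram model {self.kriging_variogram!r}")
        if self.overlap_target not in ("hsi", "si"):
            raise ValueError("overlap.target must be 'hsi' or 'si'")
        if set(self.overlap_weights) != set(LEVELS):
            raise ValueError(f"overlap.weights must have exactly the levels {LEVELS}")
        if self.impute_method not in ("idw", "nearest"):
            raise ValueError("impute.method must be 'idw' or 'nearest'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        paths = d.get("paths", {})
        brt = d.get("brt", {})
        return cls(
            seed=d.get("seed", 42),
            catch_path=paths.get("catch"),
            env_path=paths.get("env"),
            outdir=paths.get("outdir", "habsuit_out"),
            screening_threshold=d.get("screening", {}).get("threshold", 0.05),
            loess_span=d.get("loess", {}).get("span", 0.75),
            loess_degree=d.get("loess", {}).get("degree", 2),
            si_n_grid=d.get("si", {}).get("n_grid", 100),
            brt=BrtParams(
                n_trees=brt.get("n_trees", 1000),
                learning_rate=brt.get("learning_rate", 0.01),
                tree_depth=brt.get("tree_depth", 3),
                bag_fraction=brt.get("bag_fraction", 0.75),
            ),
            cv_n_rep=d.get("cv", {}).get("n_rep", 100),
            cv_train_frac=d.get("cv", {}).get("train_frac", 0.8),
            cv_refit_curves=d.get("cv", {}).get("refit_curves", True),
            kriging_variogram=d.get("kriging", {}).get("variogram", "spherical"),
            kriging_resolution=d.get("kriging", {}).get("resolution", 0.1),
            impute_method=d.get("impute", {}).get("method", "idw"),
            overlap_threshold=d.get("overlap", {}).get("threshold", 0.7),
            overlap_weights=d.get("overlap", {}).get(
                "weights", dict(DEFAULT_LEVEL_WEIGHTS)
            ),
            overlap_min_cells=d.get("overlap", {}).get("min_cells", 0),
            overlap_target=d.get("overlap", {}).get("target", "hsi"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["brt"] = asdict(self.brt)
        return d
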