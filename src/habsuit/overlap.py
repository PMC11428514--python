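"""Optimal-habitat extraction, overlap levels and the seasonal overlap index.

A species' optimal habitat is the set of in-hull grid cells whose suitability
strictly exceeds a cutoff (default 0.7).  Each cell occupied by at least one
species is then labelled by how many species' optimal habitats contain it —
single (1), pair (2) or multi (>= 3) — and the seasonal overlap index is the
weighted sum of level area fractions:

    I_overlap = sum_i w_i A_i,   w = {single: -0.5, pair: 1, multi: 2}

where A_i is level i's share of all occupied cells (so sum A_i = 1 and the
index is bounded in [-0.5, 2]): -0.5 means every optimal cell belongs to
exactly one species (fully separated niches), 2 means every optimal cell is
shared by three or more species.  Area is measured in grid-cell counts.
Exact per-species-subset intersection counts (upset-diagram semantics:
disjoint subset partition) are exported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from habsuit.spatial import HsiSurface

LEVELS = ("single", "pair", "multi")
DEFAULT_LEVEL_WEIGHTS = {"single": -0.5, "pair": 1.0, "multi": 2.0}


@dataclass(frozen=True)
class OptimalMask:
    species: str
    season: str
    cells: frozenset[int]  # in-hull cell ids with suitability > threshold
    grid_id: tuple
    threshold: float


@dataclass(frozen=True)
class OverlapSummary:
    season: str
    level_counts: dict[str, int]
    a: dict[str, float]  # level -> area fraction of occupied cells
    count_area: int  # occupied cells (union of all masks)
    index: float
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LEVEL_WEIGHTS))


def extract_optimal(
    surface: HsiSurface, threshold: float = 0.7, min_cells: int = 0
) -> OptimalMask | None:
    """Cells with interpolated suitability strictly greater than ``threshold``.

    Only in-hull cells count.  If the mask has fewer than ``min_cells`` cells
    the species is dropped from overlap analysis (returns None) — a species
    whose optimal range is negligibly small would only dilute level fractions.
    """
    c = surface.cells
    sel = c.loc[c["in_hull"] & (c["value"] > threshold), "cell_id"]
    cells = frozenset(int(i) for i in sel)
    if len(cells) < min_cells:
        return None
    return OptimalMask(
        species=surface.species,
        season=surface.season,
        cells=cells,
        grid_id=surface.grid_id,
        threshold=threshold,
    )


def overlap_levels(
    masks: list[OptimalMask],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label occupied cells by overlap level and count exact subset intersections.

    Returns (cell_levels, intersection_counts): cell_levels has one row per
    occupied cell (cell_id, n_species, level); intersection_counts has one row
    per non-empty species subset (subset as '&'-joined sorted names, count),
    using disjoint-partition (upset) semantics so the counts sum to the number
    of occupied cells.
    """
    if not masks:
        raise ValueError("need at least one optimal mask")
    grid_ids = {m.grid_id for m in masks}
    if len(grid_ids) > 1:
        raise ValueError("masks are on mismatched grids")
    membership: dict[int, list[str]] = {}
    for m in masks:
        for cell in m.cells:
            membership.setdefault(cell, []).append(m.species)
    rows = []
    subset_counts: dict[tuple[str, ...], int] = {}
    for cell, species in sorted(membership.items()):
        k = len(species)
        level = "single" if k == 1 else ("pair" if k == 2 else "multi")
        rows.append({"cell_id": cell, "n_species": k, "level": level})
        key = tuple(sorted(species))
        subset_counts[key] = subset_counts.get(key, 0) + 1
    cell_levels = pd.DataFrame(rows, columns=["cell_id", "n_species", "level"])
    inter = pd.DataFrame(
        [{"subset": "&".join(k), "n_species": len(k), "count": v} for k, v in sorted(subset_counts.items())]
    )
    return cell_levels, inter


def overlap_index(
    a: dict[str, float], weights: dict[str, float] | None = None
) -> float:
    """Weighted sum of overlap-level area fractions.

    ``a`` maps level -> fraction of occupied cells; fractions must sum to 1
    (or all be zero — no occupied cells — which yields 0 with a warning).
    """
    weights = weights or DEFAULT_LEVEL_WEIGHTS
    vals = np.array([a.get(lv, 0.0) for lv in LEVELS], dtype=float)
    if (vals < 0).any():
        raise ValueError("area fractions must be nonnegative")
    total = vals.sum()
    if total == 0:
        warnings.warn("no occupied cells: overlap index defined as 0", stacklevel=2)
        return 0.0
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"area fractions must sum to 1, got {total}")
    return float(sum(weights[lv] * a.get(lv, 0.0) for lv in LEVELS))


def summarize_overlap(
    masks: list[OptimalMask],
    weights: dict[str, float] | None = None,
) -> OverlapSummary:
    """Level counts, area fractions and the overlap index for one season."""
    weights = weights or DEFAULT_LEVEL_WEIGHTS
    season = masks[0].season if masks else ""
    cell_levels, _ = overlap_levels(masks)
    counts = {lv: int((cell_levels["level"] == lv).sum()) for lv in LEVELS}
    count_area = int(sum(counts.values()))
    if count_area:
        a = {lv: counts[lv] / count_area for lv in LEVELS}
    else:
        a = {lv: 0.0 for lv in LEVELS}
    idx = overlap_index(a, weights) if count_area else 0.0
    return OverlapSummary(
        season=season,
        level_counts=counts,
        a=a,
        count_area=count_area,
        index=idx,
        weights=dict(weights),
    )


def seasonal_report(summaries: list[OverlapSummary]) -> pd.DataFrame:
    """Seasons ranked by overlap index (ascending; equal indices keep input
    order).  Columns mirror the seasonal summary: season, count_area, level
    counts, area fractions and index."""
    rows = [
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
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    return df.sort_values("overlap_index", kind="stable").reset_index(drop=True)
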