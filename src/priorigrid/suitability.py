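"""Post-processing of species habitat-suitability surfaces.

The distribution-model fit itself is external; this module consumes its
continuous per-species rasters (values in [0, 1]) and implements everything
downstream: the minimum-record modeling filter, the replication-plan rule,
the pairwise-correlation predictor screen, suitability thresholding
(values below tau = 0.75 rejected, the rest superposed into a community
suitability map), suitable-habitat-area (SHA) masks, climate-stability
intersection, and overlays of coarse analysis cells with the fine SHA
rasters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asciigrid import AsciiGrid
from .grid import GridSpec
from .occurrences import OccurrenceTable, SpeciesCatalog

__all__ = [
    "SuitabilityStack",
    "ReplicationPlan",
    "ShaOverlap",
    "min_occurrence_filter",
    "replication_plan",
    "screen_predictors",
    "threshold_and_superpose",
    "hotspot_sha_overlap",
    "stable_sha",
    "overlay_classes",
]

DEFAULT_TAU = 0.75
CV_BREAKPOINT = 30


class SuitabilityStack:
    """Aligned per-species suitability rasters for one climate scenario."""

    def __init__(self, scenario: str, rasters: dict[str, AsciiGrid], tau: float = DEFAULT_TAU):
        if not rasters:
            raise ValueError("empty suitability stack")
        if not 0 < tau <= 1:
            raise ValueError(f"tau must be in (0, 1], got {tau}")
        ref = next(iter(rasters.values()))
        for sp, g in rasters.items():
            if not g.aligned_with(ref):
                raise ValueError(f"raster for {sp!r} is not aligned with the stack")
            if np.nanmin(g.data) < -1e-9 or np.nanmax(g.data) > 1 + 1e-9:
                raise ValueError(f"raster for {sp!r} has values outside [0, 1]")
        self.scenario = scenario
        self.rasters = dict(rasters)
        self.tau = tau
        self.reference = ref

    @property
    def species(self) -> list[str]:
        return list(self.rasters)

    def __len__(self) -> int:
        return len(self.rasters)


def min_occurrence_filter(
    occ: OccurrenceTable,
    catalog: SpeciesCatalog,
    n_min: int = 5,
    group: str = "THREATENED",
) -> list[str]:
    """Species of ``group`` with at least ``n_min`` retained records.

    Species below the floor are excluded from distribution modeling (too few
    points for a reliable fit).
    """
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    counts = occ.records_per_species()
    members = set(catalog.group_members(group))
    return sorted(sp for sp, n in counts.items() if sp in members and n >= n_min)


@dataclass(frozen=True)
class ReplicationPlan:
    """Resampling plan exported to the external modeling tool."""

    species_records: int
    method: str  # "jackknife" | "cross-validation"
    replicates: int


def replication_plan(n_records: int, cv_breakpoint: int = CV_BREAKPOINT) -> ReplicationPlan:
    """Replication rule by record count.

    Sparse species (fewer than ``cv_breakpoint`` records) get leave-one-out
    jackknife with one replicate per record; the rest get 10-replicate
    cross-validation.  The default breakpoint assigns 30 records to the
    cross-validation branch.
    """
    if n_records < 5:
        raise ValueError(f"modeling requires >= 5 records, got {n_records}")
    if n_records < cv_breakpoint:
        return ReplicationPlan(n_records, "jackknife", n_records)
    return ReplicationPlan(n_records, "cross-validation", 10)


def screen_predictors(table: pd.DataFrame, cutoff: float = 0.70) -> list[str]:
    """Drop collinear predictors until max pairwise |r| <= cutoff.

    While any pair exceeds the cutoff (strictly), the member of the worst
    pair with the larger mean absolute correlation to all remaining
    variables is removed (ties: the later column).  Deterministic; the
    result is a subset of the input columns in their original order.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 predictor variables")
    if table.columns.duplicated().any():
        raise ValueError("duplicate variable names")
    stds = table.std(ddof=0)
    constant = stds[stds == 0].index.tolist()
    if constant:
        raise ValueError(
            f"constant variables have undefined correlations: {constant}"
        )
    corr = table.corr().abs()
    keep = list(table.columns)
    while len(keep) > 1:
        sub = corr.loc[keep, keep].to_numpy().copy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff + 1e-12:  # strict '>' triggers removal; guard roundoff
            break
        mean_i = sub[i].sum() / (len(keep) - 1)
        mean_j = sub[j].sum() / (len(keep) - 1)
        drop = keep[j] if mean_j >= mean_i else keep[i]
        keep.remove(drop)
    return keep


def threshold_and_superpose(stack: SuitabilityStack) -> tuple[AsciiGrid, np.ndarray]:
    """Reject sub-threshold suitability and sum the rest across species.

    Per pixel, species with suitability >= tau contribute their value to the
    community map V; the SHA mask is V > 0 (at least one species retained).
    Returns ``(V, sha_mask)``.
    """
    ref = stack.reference
    v = np.zeros_like(ref.data)
    for g in stack.rasters.values():
        d = g.data
        v += np.where(d >= stack.tau, d, 0.0)
    return ref.like(v), v > 0


def _cell_block(grid: GridSpec, cell_id: int, raster: AsciiGrid) -> tuple[slice, slice]:
    """Fine-raster (row, col) slices covering one coarse cell."""
    ratio = grid.resolution / raster.cellsize
    if abs(ratio - round(ratio)) > 1e-6:
        raise ValueError(
            f"fine cellsize {raster.cellsize} does not divide resolution "
            f"{grid.resolution}"
        )
    off_x = (grid.lon_min - raster.xllcorner) / raster.cellsize
    off_y = (grid.lat_min - raster.yllcorner) / raster.cellsize
    if abs(off_x - round(off_x)) > 1e-6 or abs(off_y - round(off_y)) > 1e-6:
        raise ValueError("fine raster is not aligned with the coarse grid origin")
    ratio = int(round(ratio))
    off_x, off_y = int(round(off_x)), int(round(off_y))
    row, col = grid.rowcol(cell_id)
    c0 = off_x + col * ratio
    # rows count from the top (north) of the raster
    r_bot = off_y + row * ratio  # from the raster's south edge
    r0 = raster.nrows - (r_bot + ratio)
    if r0 < 0 or c0 < 0 or c0 + ratio > raster.ncols or r0 + ratio > raster.nrows:
        raise ValueError(f"cell {cell_id} falls outside the fine raster")
    return slice(r0, r0 + ratio), slice(c0, c0 + ratio)


def _classify_cells(
    cells, mask: np.ndarray, grid: GridSpec, raster: AsciiGrid, rule
) -> dict[int, str]:
    out = {}
    for cid in cells:
        rs, cs = _cell_block(grid, cid, raster)
        block = mask[rs, cs]
        frac = float(block.mean())
        if rule == "all":
            cls = "complete" if frac == 1.0 else ("none" if frac == 0.0 else "partial")
        else:  # fractional threshold: complete when coverage >= rule
            cls = "complete" if frac >= rule else ("none" if frac == 0.0 else "partial")
        out[cid] = cls
    return out


@dataclass
class ShaOverlap:
    """Per coarse cell, SHA coverage class under each scenario plus stability.

    ``classes`` is indexed by cell_id with one column per scenario and a
    boolean ``stable`` column (complete coverage by the stable mask).
    """

    classes: pd.DataFrame
    rule: object = "all"

    def counts(self, scenario: str) -> dict[str, int]:
        c = self.classes[scenario].value_counts()
        return {k: int(c.get(k, 0)) for k in ("complete", "partial", "none")}

    @property
    def stable_cells(self) -> list[int]:
        return self.classes.index[self.classes["stable"]].tolist()


def hotspot_sha_overlap(
    cells,
    sha_masks: dict[str, np.ndarray],
    grid: GridSpec,
    raster: AsciiGrid,
    rule="all",
) -> ShaOverlap:
    """Classify coarse cells against fine SHA masks, scenario by scenario.

    A cell is *complete* when every fine pixel inside it is SHA-positive
    (``rule='all'``; a fraction in (0, 1] may be passed instead), *partial*
    when at least one is, *none* otherwise.  A ``stable`` flag marks cells
    completely covered by the intersection of all scenario masks.
    """
    if isinstance(rule, str) and rule != "all":
        raise ValueError(f"unknown sub-cell rule {rule!r}")
    cells = sorted(int(c) for c in cells)
    cols = {}
    for scenario, mask in sha_masks.items():
        if mask.shape != raster.data.shape:
            raise ValueError(f"mask for {scenario!r} does not match the raster shape")
        cols[scenario] = _classify_cells(cells, mask, grid, raster, rule)
    stable_mask = stable_sha(*sha_masks.values())
    stable_cls = _classify_cells(cells, stable_mask, grid, raster, rule)
    df = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    for scenario, mapping in cols.items():
        df[scenario] = [mapping[c] for c in cells]
    df["stable"] = [stable_cls[c] == "complete" for c in cells]
    return ShaOverlap(df, rule)


def stable_sha(*masks: np.ndarray) -> np.ndarray:
    """Pixelwise intersection of SHA masks (area suitable under every scenario)."""
    if not masks:
        raise ValueError("need at least one mask")
    out = masks[0].astype(bool)
    for m in masks[1:]:
        if m.shape != out.shape:
            raise ValueError("misaligned masks")
        out = out & m.astype(bool)
    return out


def overlay_classes(overlap: ShaOverlap, cell_sets: dict[str, set[int]]) -> pd.DataFrame:
    """Cross-tabulate SHA stability of cells against named cell sets.

    ``cell_sets`` maps a label (e.g. 'gaps_nnr_pnr', 'covered_nnr') to cells;
    rows report how many of each set's cells are stable / unstable, counting
    only cells present in the overlap classification.
    """
    rows = []
    stable = set(overlap.stable_cells)
    classified = set(overlap.classes.index)
    for label, cells in cell_sets.items():
        cells = set(cells) & classified
        rows.append(
            {
                "set": label,
                "n_cells": len(cells),
                "stable": len(cells & stable),
                "not_stable": len(cells - stable),
            }
        )
    return pd.DataFrame(rows)
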