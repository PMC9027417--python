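"""Synthetic study-system generator.

Emulates the ingredients of a national herbarium-scale prioritization
study so every pipeline stage can run end to end without external data:

* a species catalog with overlapping conservation-group memberships drawn
  at the study's reported rates (endemic 32.9%, threatened 6.4%, CITES
  3.5%, national-protected 0.8%);
* clustered multi-species occurrence records with *planted* high-diversity
  cells whose identity is retained for recovery scoring;
* reserve polygons of configurable union coverage, split into national and
  provincial tiers;
* paired current/future suitability surfaces per species (Gaussian niche
  bumps) with a northward habitat shift under the future scenario.

A single integer seed drives independent sub-streams per stage, so
regenerating one product never perturbs the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .asciigrid import AsciiGrid
from .grid import GridSpec, make_grid
from .occurrences import OccurrenceTable, SpeciesCatalog
from .reserves import Reserve, ReserveSet
from .suitability import SuitabilityStack

__all__ = ["SimConfig", "PlantedTruth", "gen_catalog", "gen_occurrences",
           "gen_reserves", "gen_suitability"]

# sub-stream indices (fixed so stages stay independent)
_STREAMS = {"catalog": 0, "occurrences": 1, "reserves": 2, "suitability": 3}


@dataclass
class SimConfig:
    """Parameters of the synthetic study system.

    Group proportions reproduce the study's catalog composition.  The
    record-count distribution is log-uniform with bounds calibrated so the
    simulated range-size quantiles match the reported ones (about 9% of
    species in fewer than 5 grid cells, about 66% in more than 20).
    """

    seed: int = 0
    n_species: int = 2000
    p_endemic: float = 0.329
    p_threatened: float = 0.064
    p_cites: float = 0.035
    p_national_protected: float = 0.008
    extent: tuple[float, float, float, float] = (100.0, 20.0, 110.0, 30.0)
    resolution: float = 0.5
    n_planted_hotspots: int = 10
    hotspot_boost: float = 10.0
    records_lo: int = 3
    records_hi: int = 2500
    range_sd: float = 1.0
    future_shift_north: float = 2.0
    reserve_coverage_fraction: float = 0.3
    fine_divisor: int = 6
    niche_sd_range: tuple[float, float] = (0.8, 1.5)
    niche_peak_range: tuple[float, float] = (0.8, 1.0)

    def __post_init__(self):
        for name in ("p_endemic", "p_threatened", "p_cites", "p_national_protected"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.reserve_coverage_fraction <= 1.0:
            raise ValueError("reserve_coverage_fraction must be in [0, 1]")
        if self.n_species < 10:
            raise ValueError("n_species must be >= 10")

    def grid(self) -> GridSpec:
        return make_grid(self.extent, self.resolution)

    def rng(self, stage: str) -> np.random.Generator:
        child = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[_STREAMS[stage]]
        return np.random.default_rng(child)


def _spaced_planted_cells(rng, grid: GridSpec, n_p: int, min_sep: int = 3) -> np.ndarray:
    """Planted hotspot cells with pairwise row/col separation >= min_sep.

    Hotspots model distinct biogeographic centers, so they are kept apart;
    the separation relaxes automatically if the grid is too small to honor
    it.
    """
    sep = min_sep
    while sep >= 0:
        chosen: list[int] = []
        rows_cols: list[tuple[int, int]] = []
        # enough proposals to fill n_p at this separation, w.h.p.
        proposals = rng.permutation(grid.n_cells)
        for cid in proposals:
            r, c = grid.rowcol(int(cid))
            if all(
                max(abs(r - r2), abs(c - c2)) >= sep for r2, c2 in rows_cols
            ):
                chosen.append(int(cid))
                rows_cols.append((r, c))
                if len(chosen) == n_p:
                    return np.sort(np.array(chosen))
        sep -= 1
    raise ValueError(f"cannot place {n_p} planted cells on a {grid.n_cells}-cell grid")


@dataclass
class PlantedTruth:
    """Ground truth retained for recovery scoring."""

    planted_cells: list[int]
    species: pd.DataFrame  # species_id, center_lon, center_lat, planted, n_records
    niches: pd.DataFrame | None = None  # species_id, lon, lat, sd, peak


def gen_catalog(config: SimConfig) -> SpeciesCatalog:
    """Draw group memberships independently per species at the configured rates."""
    rng = config.rng("catalog")
    n = config.n_species
    width = len(str(n))
    ids = [f"sp{i + 1:0{width}d}" for i in range(n)]
    endemic = rng.random(n) < config.p_endemic
    threatened = rng.random(n) < config.p_threatened
    cites = rng.random(n) < config.p_cites
    protected = rng.random(n) < config.p_national_protected
    cats = rng.choice(["VU", "EN", "CR"], size=n)
    df = pd.DataFrame(
        {
            "species_id": ids,
            "endemic": endemic,
            "threatened": threatened,
            "threat_category": np.where(threatened, cats, "none"),
            "cites": cites,
            "national_protected": protected,
        }
    )
    return SpeciesCatalog(df)


def gen_occurrences(
    catalog: SpeciesCatalog, config: SimConfig
) -> tuple[OccurrenceTable, PlantedTruth]:
    """Clustered occurrence records with planted high-diversity cells.

    Each species gets a range center drawn uniformly over the extent and a
    log-uniform record count; records scatter isotropically around the
    center (sd = ``range_sd``) and wrap at the extent boundary (toroidal
    edges), so with no planted boost the expected record density is exactly
    uniform.  Planted hotspot cells carry a relative record-sampling weight
    of ``hotspot_boost`` (ordinary area has weight 1), emulating the
    collection bias of heavily surveyed localities: every species whose
    range touches a planted cell concentrates records there, so planted
    cells accumulate species of all groups and end far above the non-planted
    richness distribution.
    """
    grid = config.grid()
    rng = config.rng("occurrences")
    n_p = config.n_planted_hotspots
    boost = float(config.hotspot_boost)
    if n_p == 0 and boost > 1:
        raise ValueError("hotspot_boost > 1 requires at least one planted hotspot")
    planted_cells = (
        _spaced_planted_cells(rng, grid, n_p) if n_p > 0 else np.array([], dtype=int)
    )
    planted_bounds = np.array([grid.cell_bounds(int(c)) for c in planted_cells])

    n = len(catalog)
    centers = np.empty((n, 2))
    centers[:, 0] = rng.uniform(grid.lon_min, grid.lon_max, n)
    centers[:, 1] = rng.uniform(grid.lat_min, grid.lat_max, n)
    n_rec = np.exp(
        rng.uniform(np.log(config.records_lo), np.log(config.records_hi), n)
    ).astype(int)
    n_rec = np.clip(n_rec, 1, None)

    # per-species wrapped-Gaussian mass inside each planted cell
    if n_p > 0 and boost != 1.0:
        from scipy.stats import norm

        sd = config.range_sd
        span_x = grid.lon_max - grid.lon_min
        span_y = grid.lat_max - grid.lat_min

        def wrapped_mass(lo, hi, c, span):
            m = np.zeros((n, n_p))
            for k in (-1.0, 0.0, 1.0):  # wrap copies; sd << span makes 3 enough
                m += norm.cdf((hi[None, :] + k * span - c[:, None]) / sd) - norm.cdf(
                    (lo[None, :] + k * span - c[:, None]) / sd
                )
            return m

        mass = wrapped_mass(
            planted_bounds[:, 0], planted_bounds[:, 2], centers[:, 0], span_x
        ) * wrapped_mass(
            planted_bounds[:, 1], planted_bounds[:, 3], centers[:, 1], span_y
        )
        z = 1.0 + (boost - 1.0) * mass.sum(axis=1)
        q = boost * mass / z[:, None]  # P(record boosted into planted cell j)
    else:
        q = np.zeros((n, max(n_p, 1)))

    sp_idx = np.repeat(np.arange(n), n_rec)
    total = len(sp_idx)
    span = np.array(
        [grid.lon_max - grid.lon_min, grid.lat_max - grid.lat_min]
    )
    origin = np.array([grid.lon_min, grid.lat_min])

    def wrapped_scatter(rows):
        raw = centers[rows] + rng.normal(0.0, config.range_sd, (len(rows), 2))
        return origin + np.mod(raw - origin, span)

    pts = wrapped_scatter(sp_idx)
    if n_p > 0 and boost != 1.0:
        u = rng.random(total)
        cum = np.cumsum(q[sp_idx], axis=1)
        comp = (u[:, None] < cum).argmax(axis=1)
        boosted = u < cum[:, -1]
        # boosted records land uniformly inside their planted cell
        j = comp[boosted]
        b = planted_bounds[j]
        pts[boosted, 0] = b[:, 0] + rng.random(boosted.sum()) * (b[:, 2] - b[:, 0])
        pts[boosted, 1] = b[:, 1] + rng.random(boosted.sum()) * (b[:, 3] - b[:, 1])
        # ordinary records avoid planted cells (their mass moved into the boost)
        from .grid import assign_cells as _assign

        planted_set = set(int(c) for c in planted_cells)
        for _ in range(64):
            cells = _assign(pts[:, 0], pts[:, 1], grid)
            redo = ~boosted & np.isin(cells, planted_cells)
            if not redo.any():
                break
            pts[redo] = wrapped_scatter(sp_idx[redo])

    records = pd.DataFrame(
        {
            "species_id": catalog.species_ids.to_numpy()[sp_idx],
            "lon": pts[:, 0],
            "lat": pts[:, 1],
        }
    )
    occ = OccurrenceTable(
        records,
        {
            "records_read": len(records),
            "retained": len(records),
            "dropped_no_coordinates": 0,
            "dropped_unknown_species": 0,
            "dropped_out_of_extent": 0,
        },
    )
    truth = PlantedTruth(
        planted_cells=[int(c) for c in planted_cells],
        species=pd.DataFrame(
            {
                "species_id": catalog.species_ids,
                "center_lon": centers[:, 0],
                "center_lat": centers[:, 1],
                "n_records": n_rec,
            }
        ),
    )
    return occ, truth


def _fit_rectangle(rng, grid: GridSpec, current, target_area: float, tol: float):
    """Propose one rectangle; shrink it about its center if the union overshoots."""
    span_lon = grid.lon_max - grid.lon_min
    span_lat = grid.lat_max - grid.lat_min
    w = rng.uniform(0.5, max(0.6, span_lon / 4))
    h = rng.uniform(0.5, max(0.6, span_lat / 4))
    cx = rng.uniform(grid.lon_min + w / 2, grid.lon_max - w / 2)
    cy = rng.uniform(grid.lat_min + h / 2, grid.lat_max - h / 2)

    def rect(scale):
        return box(cx - scale * w / 2, cy - scale * h / 2,
                   cx + scale * w / 2, cy + scale * h / 2)

    full = current.union(rect(1.0)) if current is not None else rect(1.0)
    if full.area <= target_area + tol:
        return rect(1.0), full
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = (lo + hi) / 2
        u = current.union(rect(mid)) if current is not None else rect(mid)
        if u.area > target_area:
            hi = mid
        else:
            lo = mid
    r = rect(lo) if lo > 0 else None
    return r, (current.union(r) if (current is not None and r is not None) else (r or current))


def gen_reserves(grid: GridSpec, config: SimConfig) -> ReserveSet:
    """Random reserve rectangles until the union covers the requested fraction.

    Rectangles alternate between the national and provincial tiers; the
    final union area lands within about 1% of the target fraction of the
    extent area.
    """
    rng = config.rng("reserves")
    f = config.reserve_coverage_fraction
    if f <= 0:
        return ReserveSet([])
    extent_area = (grid.lon_max - grid.lon_min) * (grid.lat_max - grid.lat_min)
    if f >= 1:
        return ReserveSet(
            [Reserve("reserve_1", "national",
                     box(grid.lon_min, grid.lat_min, grid.lon_max, grid.lat_max))]
        )
    target = f * extent_area
    tol = 0.01 * extent_area
    union = None
    reserves: list[Reserve] = []
    i = 0
    while union is None or union.area < target - tol:
        rect, union = _fit_rectangle(rng, grid, union, target, tol)
        if rect is None:
            continue
        tier = "national" if i % 2 == 0 else "provincial"
        reserves.append(Reserve(f"reserve_{i + 1}", tier, rect))
        i += 1
        if i > 10000:  # pragma: no cover - safety valve
            raise RuntimeError("reserve generation failed to reach target coverage")
    return ReserveSet(reserves)


def gen_suitability(
    species_ids,
    grid: GridSpec,
    config: SimConfig,
    tau: float = 0.75,
) -> tuple[SuitabilityStack, SuitabilityStack, PlantedTruth]:
    """Paired current/future suitability stacks with a northward shift.

    Each species' suitability is an isotropic Gaussian bump around a niche
    center with peak in ``niche_peak_range``; the future surface is the same
    bump shifted ``future_shift_north`` degrees north.  Niche centers are
    drawn from an inset margin of the extent so neither the current nor the
    shifted bump is truncated at the boundary, keeping the planted shift
    measurable from the rasters.
    """
    rng = config.rng("suitability")
    species_ids = list(species_ids)
    cs = grid.resolution / config.fine_divisor
    nrows = grid.n_rows * config.fine_divisor
    ncols = grid.n_cols * config.fine_divisor
    lon = grid.lon_min + (np.arange(ncols) + 0.5) * cs
    lat = grid.lat_max - (np.arange(nrows) + 0.5) * cs  # row 0 = north
    lon2, lat2 = np.meshgrid(lon, lat)

    sd_lo, sd_hi = config.niche_sd_range
    pk_lo, pk_hi = config.niche_peak_range
    # widest possible SHA disc radius, used to inset the niche centers
    max_r = sd_hi * np.sqrt(max(0.0, 2.0 * np.log(max(pk_hi, tau + 1e-9) / tau)))
    margin = min(max_r + 0.1, (grid.lon_max - grid.lon_min) / 4)
    n_margin = min(margin + config.future_shift_north,
                   (grid.lat_max - grid.lat_min) / 2.5)
    lo_lon, hi_lon = grid.lon_min + margin, grid.lon_max - margin
    lo_lat, hi_lat = grid.lat_min + margin, grid.lat_max - n_margin
    if hi_lat <= lo_lat or hi_lon <= lo_lon:
        warnings.warn("extent too small to inset niche centers; using full extent")
        lo_lon, hi_lon = grid.lon_min, grid.lon_max
        lo_lat, hi_lat = grid.lat_min, grid.lat_max

    rows = []
    cur: dict[str, AsciiGrid] = {}
    fut: dict[str, AsciiGrid] = {}
    shift = config.future_shift_north
    if shift >= grid.lat_max - grid.lat_min:
        warnings.warn("future shift pushes niches outside the extent")
    for sp in species_ids:
        cx = rng.uniform(lo_lon, hi_lon)
        cy = rng.uniform(lo_lat, hi_lat)
        sd = rng.uniform(sd_lo, sd_hi)
        pk = rng.uniform(pk_lo, pk_hi)
        d2 = (lon2 - cx) ** 2 + (lat2 - cy) ** 2
        cur_v = np.clip(pk * np.exp(-d2 / (2 * sd**2)), 0.0, 1.0)
        d2f = (lon2 - cx) ** 2 + (lat2 - (cy + shift)) ** 2
        fut_v = np.clip(pk * np.exp(-d2f / (2 * sd**2)), 0.0, 1.0)
        cur[sp] = AsciiGrid(cur_v, grid.lon_min, grid.lat_min, cs)
        fut[sp] = AsciiGrid(fut_v, grid.lon_min, grid.lat_min, cs)
        rows.append({"species_id": sp, "lon": cx, "lat": cy, "sd": sd, "peak": pk})
    niches = pd.DataFrame(rows)
    truth = PlantedTruth(planted_cells=[], species=pd.DataFrame(), niches=niches)
    return (
        SuitabilityStack("current", cur, tau),
        SuitabilityStack("future", fut, tau),
        truth,
    )
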