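"""Reserve-network overlay, conservation effectiveness, and gap analysis.

Reserves are (multi)polygons in WGS84 with a tier attribute (national or
provincial).  A grid cell counts as covered when its box has positive-area
intersection with any reserve of the chosen tiers (a centroid-in-reserve
rule is available for sensitivity runs).  Hotspot cells without reserve
cover are conservation gaps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union
from shapely.strtree import STRtree
from shapely.validation import make_valid

from .grid import GridSpec
from .occurrences import GROUPS, IncidenceMatrix, SpeciesCatalog
from .prioritization import FinalHotspots

__all__ = [
    "TIERS",
    "Reserve",
    "ReserveSet",
    "read_reserves",
    "write_reserves",
    "covered_cells",
    "gap_analysis",
    "coverage_report",
    "CoverageReport",
    "composition_partition",
    "CompositionPartition",
    "percentage",
    "format_percent",
]

TIERS = ("national", "provincial")


@dataclass
class Reserve:
    name: str
    tier: str
    geometry: object  # shapely (Multi)Polygon


class ReserveSet:
    def __init__(self, reserves: list[Reserve]):
        for r in reserves:
            if r.tier not in TIERS:
                raise ValueError(
                    f"reserve {r.name!r} has tier {r.tier!r}; expected {TIERS}"
                )
        self.reserves = list(reserves)

    def __len__(self) -> int:
        return len(self.reserves)

    def by_tier(self, tiers) -> list[Reserve]:
        if isinstance(tiers, str):
            tiers = (tiers,)
        unknown = set(tiers) - set(TIERS)
        if unknown:
            raise ValueError(f"unknown tiers {sorted(unknown)}")
        return [r for r in self.reserves if r.tier in tiers]

    def union(self, tiers=TIERS):
        geoms = [r.geometry for r in self.by_tier(tiers)]
        return unary_union(geoms) if geoms else None

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"name": r.name, "tier": r.tier},
                    "geometry": mapping(r.geometry),
                }
                for r in self.reserves
            ],
        }


def read_reserves(path) -> ReserveSet:
    """Read a GeoJSON FeatureCollection of (Multi)Polygon reserves.

    Each feature needs a ``tier`` property (national|provincial, any case).
    Invalid rings are repaired with shapely's make_valid; a feature that
    cannot be repaired to polygonal geometry is rejected.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    reserves = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        tier = props.get("tier")
        if tier is None:
            raise ValueError(f"feature {i} has no 'tier' property")
        tier = str(tier).lower()
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
        if geom.geom_type == "GeometryCollection":
            polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            if not polys:
                raise ValueError(f"feature {i}: no polygonal geometry after repair")
            geom = unary_union(polys)
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"feature {i}: expected polygonal geometry, got {geom.geom_type}"
            )
        reserves.append(Reserve(props.get("name", f"reserve_{i}"), tier, geom))
    return ReserveSet(reserves)


def write_reserves(reserves: ReserveSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(reserves.to_geojson(), fh)


def covered_cells(
    grid: GridSpec,
    reserves: ReserveSet,
    tiers=TIERS,
    rule: str = "intersects",
) -> set[int]:
    """Grid cells covered by reserves of the chosen tiers.

    ``rule='intersects'``: positive-area overlap between the cell box and
    any reserve.  ``rule='centroid'``: the cell centroid lies inside one.
    """
    if rule not in ("intersects", "centroid"):
        raise ValueError(f"unknown coverage rule {rule!r}")
    selected = reserves.by_tier(tiers)
    if not selected:
        warnings.warn("empty reserve set for the requested tiers; nothing covered")
        return set()
    tree = STRtree([r.geometry for r in selected])
    covered: set[int] = set()
    from shapely.geometry import Point

    for cid in range(grid.n_cells):
        lon0, lat0, lon1, lat1 = grid.cell_bounds(cid)
        cell_box = box(lon0, lat0, lon1, lat1)
        probe = cell_box if rule == "intersects" else Point(grid.cell_center(cid))
        for j in tree.query(probe):
            geom = selected[int(j)].geometry
            if rule == "centroid":
                if geom.covers(probe):
                    covered.add(cid)
                    break
            elif cell_box.intersection(geom).area > 0:
                covered.add(cid)
                break
    return covered


def gap_analysis(hotspots, covered: set[int]) -> tuple[list[int], list[int]]:
    """Partition hotspot cells into (protected, gap) lists, sorted by id."""
    cells = hotspots.cells if isinstance(hotspots, FinalHotspots) else set(hotspots)
    protected = sorted(cells & set(covered))
    gaps = sorted(cells - set(covered))
    return protected, gaps


def percentage(num: int, den: int, decimals: int = 0) -> float:
    """Percentage of num/den rounded to the printed precision."""
    if den == 0:
        return float("nan")
    return round(100.0 * num / den, decimals) if decimals else float(
        round(100.0 * num / den)
    )


def format_percent(num: int, den: int, decimals: int = 0) -> str:
    """'count/percent%' rendering used in the coverage table."""
    p = percentage(num, den, decimals)
    return f"{num}/{p:.{decimals}f}%"


@dataclass
class CoverageReport:
    """Species and cell counts per area class, mirroring the effectiveness table.

    ``species_counts``: DataFrame rows = groups, columns = area classes,
    entries = species present in at least one member cell.
    ``cell_counts``: Series per area class.  ``group_totals`` and
    ``n_occupied`` hold the ratio denominators.
    """

    species_counts: pd.DataFrame
    cell_counts: pd.Series
    group_totals: dict[str, int]
    n_occupied: int

    def species_percent(self, group: str, area: str, decimals: int = 0) -> float:
        return percentage(
            int(self.species_counts.loc[group, area]),
            self.group_totals[group],
            decimals,
        )

    def cell_percent(self, area: str, decimals: int = 0) -> float:
        return percentage(int(self.cell_counts[area]), self.n_occupied, decimals)

    def to_table(self, decimals: int = 0) -> pd.DataFrame:
        """'count/percent' table: group rows plus a bottom cell-count row."""
        out = {}
        for area in self.species_counts.columns:
            col = [
                format_percent(
                    int(self.species_counts.loc[g, area]),
                    self.group_totals[g],
                    decimals,
                )
                for g in self.species_counts.index
            ]
            col.append(
                format_percent(int(self.cell_counts[area]), self.n_occupied, decimals)
            )
            out[area] = col
        return pd.DataFrame(
            out, index=list(self.species_counts.index) + ["grid_cells"]
        )

    def to_csv(self, path, decimals: int = 0) -> None:
        self.to_table(decimals).to_csv(path)


def coverage_report(
    incidence: IncidenceMatrix,
    catalog: SpeciesCatalog,
    hotspots: FinalHotspots,
    covers: dict[str, set[int]],
    rankings: dict[str, set[int]] | None = None,
) -> CoverageReport:
    """Species composition per area class.

    ``covers`` maps tier keys ('national', 'provincial', and optionally
    'union', defaulting to their union) to covered cell sets over the whole
    grid.  Area classes reported: all occupied cells; final hotspots;
    hotspots covered by each tier and their union; the corresponding
    conservation gaps; and all occupied cells covered by each tier.
    Optional ``rankings`` adds per-algorithm hotspot columns.
    """
    nat = set(covers.get("national", set()))
    prov = set(covers.get("provincial", set()))
    uni = set(covers.get("union", nat | prov))
    hot = hotspots.cells
    occupied = set(int(c) for c in incidence.occupied_cells())
    areas: dict[str, set[int]] = {}
    areas["china"] = occupied
    if rankings:
        for name, cells in rankings.items():
            areas[f"hotspots_{name}"] = set(cells)
    areas["hotspots"] = hot
    areas["hotspots_nnr"] = hot & nat
    areas["hotspots_pnr"] = hot & prov
    areas["hotspots_nnr_pnr"] = hot & uni
    areas["gaps_nnr"] = hot - nat
    areas["gaps_pnr"] = hot - prov
    areas["gaps_nnr_pnr"] = hot - uni
    areas["all_cells_nnr"] = occupied & nat
    areas["all_cells_pnr"] = occupied & prov
    areas["all_cells_nnr_pnr"] = occupied & uni

    order = catalog.df.index.get_indexer(incidence.species_ids)
    masks = {g: catalog.group_mask(g)[order] for g in GROUPS}
    counts = {}
    for area, cells in areas.items():
        if cells:
            cols = sorted(cells)
            present = np.asarray(incidence.matrix[:, cols].sum(axis=1)).ravel() > 0
        else:
            present = np.zeros(incidence.n_species, dtype=bool)
        counts[area] = [int((present & masks[g]).sum()) for g in GROUPS]
    species_counts = pd.DataFrame(counts, index=list(GROUPS))
    cell_counts = pd.Series({a: len(c) for a, c in areas.items()})
    return CoverageReport(
        species_counts, cell_counts, catalog.group_totals(), len(occupied)
    )


@dataclass
class CompositionPartition:
    """Three disjoint conservation-priority sets partitioning the catalog."""

    threatened: pd.Index
    endemic_not_threatened: pd.Index
    remaining: pd.Index

    def sizes(self) -> tuple[int, int, int]:
        return (
            len(self.threatened),
            len(self.endemic_not_threatened),
            len(self.remaining),
        )


def composition_partition(catalog: SpeciesCatalog) -> CompositionPartition:
    """Split all species into threatened / endemic-excluding-threatened / rest."""
    th = catalog.group_mask("THREATENED")
    en = catalog.group_mask("ENDEMIC")
    ids = catalog.species_ids
    return CompositionPartition(
        threatened=ids[th],
        endemic_not_threatened=ids[en & ~th],
        remaining=ids[~th & ~en],
    )
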