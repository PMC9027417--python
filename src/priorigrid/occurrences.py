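"""Species catalog, occurrence records, and the species x cell incidence matrix.

The catalog assigns each species to conservation groups.  Five analysis
groups are used throughout: ALL (every species, implicit), ENDEMIC,
THREATENED (red-list categories VU/EN/CR), CITES (appendix-listed) and
NATIONAL_PROTECTED.  Memberships may overlap.

Occurrence records are point localities (decimal degrees).  Records without
parseable coordinates, for unknown species, or outside the analysis extent
are dropped with provenance counters, mirroring the usual cleaning of
herbarium specimen data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .grid import GridSpec, assign_cells, nominal_cell_area_km2

__all__ = [
    "GROUPS",
    "THREAT_CATEGORIES",
    "SpeciesCatalog",
    "OccurrenceTable",
    "IncidenceMatrix",
    "read_catalog",
    "read_occurrences",
    "build_incidence",
    "range_size",
]

GROUPS = ("ALL", "ENDEMIC", "THREATENED", "CITES", "NATIONAL_PROTECTED")
THREAT_CATEGORIES = ("VU", "EN", "CR")

_BOOL_MAP = {
    "0": False, "1": True,
    "false": False, "true": True,
    "False": False, "True": True,
    0: False, 1: True, False: False, True: True,
}

_CATALOG_COLUMNS = [
    "species_id", "endemic", "threatened", "threat_category", "cites",
    "national_protected",
]

_GROUP_COLUMN = {
    "ENDEMIC": "endemic",
    "THREATENED": "threatened",
    "CITES": "cites",
    "NATIONAL_PROTECTED": "national_protected",
}


class SpeciesCatalog:
    """Catalog of species with conservation-group memberships.

    Wraps a DataFrame indexed by ``species_id`` with boolean columns
    ``endemic``, ``threatened``, ``cites``, ``national_protected`` and a
    string column ``threat_category`` in {'VU', 'EN', 'CR', 'none'}.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if df.index.name != "species_id":
            if "species_id" not in df.columns:
                raise ValueError("catalog needs a species_id column or index")
            df = df.set_index("species_id")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species_id values: {dups[:5]}")
        for col in ("endemic", "threatened", "cites", "national_protected"):
            if col not in df.columns:
                raise ValueError(f"catalog missing column {col!r}")
            df[col] = df[col].astype(bool)
        if "threat_category" not in df.columns:
            df["threat_category"] = np.where(df["threatened"], "VU", "none")
        cat = df["threat_category"].fillna("none").astype(str)
        bad = ~cat.isin(list(THREAT_CATEGORIES) + ["none"])
        if bad.any():
            raise ValueError(
                f"unknown threat_category values: {sorted(cat[bad].unique())}"
            )
        mismatch = (cat != "none") != df["threatened"]
        if mismatch.any():
            who = df.index[mismatch].tolist()
            raise ValueError(
                "threat_category inconsistent with threatened flag for "
                f"{who[:5]}"
            )
        df["threat_category"] = cat
        self._df = df

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def species_ids(self) -> pd.Index:
        return self._df.index

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, species_id) -> bool:
        return species_id in self._df.index

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean membership vector over the catalog's species order."""
        if group == "ALL":
            return np.ones(len(self._df), dtype=bool)
        try:
            return self._df[_GROUP_COLUMN[group]].to_numpy()
        except KeyError:
            raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")

    def group_members(self, group: str) -> pd.Index:
        return self._df.index[self.group_mask(group)]

    def group_totals(self) -> dict[str, int]:
        """Species count N_g for each analysis group (the ratio denominators)."""
        return {g: int(self.group_mask(g).sum()) for g in GROUPS}

    def groups_of(self, species_id) -> set[str]:
        row = self._df.loc[species_id]
        out = {"ALL"}
        for g, col in _GROUP_COLUMN.items():
            if bool(row[col]):
                out.add(g)
        return out

    def to_csv(self, path) -> None:
        self._df.reset_index()[_CATALOG_COLUMNS].assign(
            endemic=lambda d: d.endemic.astype(int),
            threatened=lambda d: d.threatened.astype(int),
            cites=lambda d: d.cites.astype(int),
            national_protected=lambda d: d.national_protected.astype(int),
        ).to_csv(path, index=False)


def _parse_bool_column(s: pd.Series, col: str) -> pd.Series:
    mapped = s.map(_BOOL_MAP)
    if mapped.isna().any():
        bad = s[mapped.isna()].unique()
        raise ValueError(f"unparseable boolean flags in column {col!r}: {bad[:5]}")
    return mapped.astype(bool)


def read_catalog(path) -> SpeciesCatalog:
    """Read a species catalog CSV (strict 0/1 or true/false flags)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog CSV missing columns {missing}")
    for col in ("endemic", "threatened", "cites", "national_protected"):
        df[col] = _parse_bool_column(df[col], col)
    df["threat_category"] = df["threat_category"].fillna("none")
    return SpeciesCatalog(df)


@dataclass
class OccurrenceTable:
    """Cleaned occurrence records plus provenance counters."""

    records: pd.DataFrame  # columns species_id, lon, lat
    counters: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_retained(self) -> int:
        return len(self.records)

    def records_per_species(self) -> pd.Series:
        return self.records.groupby("species_id").size()

    def to_csv(self, path) -> None:
        self.records.rename(
            columns={"lon": "decimal_longitude", "lat": "decimal_latitude"}
        ).to_csv(path, index=False)


def read_occurrences(path, catalog: SpeciesCatalog, grid: GridSpec) -> OccurrenceTable:
    """Read and clean an occurrence CSV.

    Required headers: ``species_id``, ``decimal_longitude``,
    ``decimal_latitude`` (extra columns are ignored).  Records with
    missing/non-numeric coordinates, unknown species, or coordinates outside
    the grid extent are dropped and counted.
    """
    df = pd.read_csv(path, dtype={"species_id": str})
    required = ["species_id", "decimal_longitude", "decimal_latitude"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing columns {missing}")
    n_read = len(df)
    lon = pd.to_numeric(df["decimal_longitude"], errors="coerce")
    lat = pd.to_numeric(df["decimal_latitude"], errors="coerce")
    has_coords = (
        lon.notna() & lat.notna()
        & lon.between(-180.0, 180.0) & lat.between(-90.0, 90.0)
    )
    n_no_coords = int((~has_coords).sum())
    known = df["species_id"].isin(catalog.species_ids)
    n_unknown = int((has_coords & ~known).sum())
    keep = has_coords & known
    in_extent = keep & lon.between(grid.lon_min, grid.lon_max) & lat.between(
        grid.lat_min, grid.lat_max
    )
    n_out = int((keep & ~in_extent).sum())
    if n_out:
        warnings.warn(f"dropped {n_out} records outside the grid extent")
    out = pd.DataFrame(
        {
            "species_id": df.loc[in_extent, "species_id"],
            "lon": lon[in_extent],
            "lat": lat[in_extent],
        }
    ).reset_index(drop=True)
    counters = {
        "records_read": n_read,
        "retained": len(out),
        "dropped_no_coordinates": n_no_coords,
        "dropped_unknown_species": n_unknown,
        "dropped_out_of_extent": n_out,
    }
    return OccurrenceTable(out, counters)


class IncidenceMatrix:
    """Boolean species x cell occupancy on a grid.

    Stored sparse (CSR); duplicate records collapse, so incidence is
    idempotent and order-independent.
    """

    def __init__(self, matrix: sparse.csr_matrix, species_ids: pd.Index, grid: GridSpec):
        if matrix.shape != (len(species_ids), grid.n_cells):
            raise ValueError("matrix shape inconsistent with species list / grid")
        self.matrix = matrix.astype(bool).tocsr()
        self.species_ids = pd.Index(species_ids, name="species_id")
        self.grid = grid

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def occupied_cells(self) -> np.ndarray:
        """Sorted ids of cells holding at least one species."""
        counts = np.asarray(self.matrix.sum(axis=0)).ravel()
        return np.flatnonzero(counts > 0)

    @property
    def n_occupied(self) -> int:
        return len(self.occupied_cells())

    def species_in_cell(self, cell_id: int) -> pd.Index:
        col = self.matrix.getcol(cell_id)
        return self.species_ids[col.indices]

    def cells_of(self, species_id) -> np.ndarray:
        i = self.species_ids.get_loc(species_id)
        return np.sort(self.matrix.indices[
            self.matrix.indptr[i]:self.matrix.indptr[i + 1]
        ])

    def richness_per_cell(self) -> np.ndarray:
        """Species count per cell over all grid cells."""
        return np.asarray(self.matrix.sum(axis=0)).ravel().astype(int)

    def to_triplets(self) -> pd.DataFrame:
        coo = self.matrix.tocoo()
        return pd.DataFrame(
            {
                "species_id": self.species_ids[coo.row],
                "cell_id": coo.col,
            }
        ).sort_values(["species_id", "cell_id"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_triplets().to_csv(path, index=False)


def build_incidence(occ: OccurrenceTable, grid: GridSpec) -> IncidenceMatrix:
    """Collapse occurrence points into a boolean species x cell matrix."""
    species = pd.Index(sorted(occ.records["species_id"].unique()), name="species_id")
    if len(occ.records) == 0:
        m = sparse.csr_matrix((0, grid.n_cells), dtype=bool)
        return IncidenceMatrix(m, species, grid)
    cells = assign_cells(occ.records["lon"].to_numpy(), occ.records["lat"].to_numpy(), grid)
    rows = species.get_indexer(occ.records["species_id"])
    data = np.ones(len(rows), dtype=bool)
    m = sparse.coo_matrix(
        (data, (rows, cells)), shape=(len(species), grid.n_cells)
    ).tocsr()
    m.data[:] = True  # collapse duplicates
    return IncidenceMatrix(m, species, grid)


def range_size(
    incidence: IncidenceMatrix, species_id, km_per_degree: float = 110.0
) -> tuple[int, float]:
    """Occupied-cell count and nominal range area (km^2) for one species."""
    if species_id not in incidence.species_ids:
        raise KeyError(f"species {species_id!r} not in incidence matrix")
    n = len(incidence.cells_of(species_id))
    return n, n * nominal_cell_area_km2(incidence.grid, km_per_degree)
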