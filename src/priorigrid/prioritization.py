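"""Hotspot identification: composite richness, greedy complementarity, integration.

Two hotspot rules are implemented and then combined:

* the *top-5% richness* rule scores every occupied cell with the composite
  index ``R_c = sum_g S_gc / N_g`` (per-group richness ratios summed over
  the five analysis groups) and keeps the top fraction;
* the *greedy complementarity* rule repeatedly selects the cell holding the
  most not-yet-covered species until all species are covered, valuing each
  selected cell by its composite gain ``G_c`` (ratio sum over its newly
  covered species).

Final hotspots merge the two rankings: cells found by both algorithms are
first-class (ordered by the sum of their two rank positions), cells found
by only one fill the remainder (ordered by their single rank position).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occurrences import GROUPS, IncidenceMatrix, SpeciesCatalog

__all__ = [
    "RichnessPattern",
    "ComplementarityStep",
    "ComplementaritySolution",
    "HotspotRanking",
    "FinalHotspots",
    "group_richness",
    "top_richness_hotspots",
    "greedy_complementarity",
    "top_complementarity_hotspots",
    "integrate_hotspots",
]


@dataclass
class RichnessPattern:
    """Per-cell group richness counts, ratios, and the composite index R_c.

    ``table`` is indexed by cell_id (occupied cells only) with columns
    ``S_<group>``, ``r_<group>`` and ``R``.  Unoccupied cells implicitly
    score zero.
    """

    table: pd.DataFrame
    group_totals: dict[str, int]
    n_cells: int  # total grid cells

    @property
    def n_occupied(self) -> int:
        return len(self.table)

    def composite(self, cell_id: int) -> float:
        return float(self.table["R"].get(cell_id, 0.0))

    def ratio_vector(self, group: str) -> np.ndarray:
        """Group ratio r_gc over ALL grid cells (absent cells zero-filled)."""
        v = np.zeros(self.n_cells)
        v[self.table.index.to_numpy()] = self.table[f"r_{group}"].to_numpy()
        return v


@dataclass
class ComplementarityStep:
    order: int  # 1-based selection order
    cell_id: int
    new_species: pd.Index  # species first covered at this step
    new_per_group: dict[str, int]
    gain: float  # composite ratio sum over the newly covered species
    uncovered_after: int


@dataclass
class ComplementaritySolution:
    steps: list[ComplementarityStep]
    group_totals: dict[str, int]
    n_cells: int
    criterion: str = "all_species"

    @property
    def cell_ids(self) -> list[int]:
        return [s.cell_id for s in self.steps]

    @property
    def gains(self) -> dict[int, float]:
        return {s.cell_id: s.gain for s in self.steps}

    def total_gain(self) -> float:
        return float(sum(s.gain for s in self.steps))

    def gain_component(self, group: str) -> dict[int, float]:
        """Per selected cell, the group's share of its gain: |new in g| / N_g."""
        n_g = self.group_totals[group]
        if n_g == 0:
            return {s.cell_id: 0.0 for s in self.steps}
        return {s.cell_id: s.new_per_group[group] / n_g for s in self.steps}


@dataclass
class HotspotRanking:
    """An ordered hotspot list from one algorithm.

    Orders are consecutive 1-based rank positions; scores are non-increasing
    along the order.  ``k`` is the nominal cutoff; ties at the k-th score are
    extended, so ``len(cell_ids)`` may exceed ``k``.
    """

    algorithm: str  # "richness" | "complementarity"
    cell_ids: list[int]
    scores: list[float]
    k: int
    tie_extended: bool = False

    def __post_init__(self):
        if any(b > a + 1e-12 for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing along the ranking")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def orders(self) -> dict[int, int]:
        return {c: i + 1 for i, c in enumerate(self.cell_ids)}

    def score_of(self) -> dict[int, float]:
        return dict(zip(self.cell_ids, self.scores))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "order": np.arange(1, len(self.cell_ids) + 1),
                "score": self.scores,
                "algorithm": self.algorithm,
            }
        )


@dataclass
class FinalHotspots:
    """First/second-class hotspot cells from rank integration."""

    first_class: list[int]  # in both rankings, sorted by o_R + o_C
    second_class: list[int]  # in exactly one ranking, sorted by its order
    k_total: int
    order_sum: dict[int, int] = field(default_factory=dict)

    @property
    def cells(self) -> set[int]:
        return set(self.first_class) | set(self.second_class)

    def __len__(self) -> int:
        return len(self.first_class) + len(self.second_class)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cell_id": c, "hotspot_class": "first", "rank": i + 1}
            for i, c in enumerate(self.first_class)
        ] + [
            {"cell_id": c, "hotspot_class": "second", "rank": i + 1}
            for i, c in enumerate(self.second_class)
        ]
        return pd.DataFrame(rows, columns=["cell_id", "hotspot_class", "rank"])


def group_richness(incidence: IncidenceMatrix, catalog: SpeciesCatalog) -> RichnessPattern:
    """Compute S_gc, r_gc = S_gc / N_g and R_c = sum_g r_gc per occupied cell."""
    if incidence.n_species == 0:
        raise ValueError("empty incidence matrix")
    missing = incidence.species_ids.difference(catalog.species_ids)
    if len(missing):
        raise ValueError(f"incidence species missing from catalog: {list(missing)[:5]}")
    totals = catalog.group_totals()
    # membership masks aligned to the incidence species order
    order = catalog.df.index.get_indexer(incidence.species_ids)
    occupied = incidence.occupied_cells()
    sub = incidence.matrix[:, occupied]  # species x occupied cells
    data = {}
    r_sum = np.zeros(len(occupied))
    for g in GROUPS:
        mask = catalog.group_mask(g)[order]
        s_g = np.asarray(sub[mask].sum(axis=0)).ravel().astype(int)
        n_g = totals[g]
        if n_g == 0:
            warnings.warn(f"group {g} is empty; it contributes 0 to the index")
            r_g = np.zeros(len(occupied))
        else:
            r_g = s_g / n_g
        data[f"S_{g}"] = s_g
        data[f"r_{g}"] = r_g
        r_sum += r_g
    data["R"] = r_sum
    table = pd.DataFrame(data, index=pd.Index(occupied, name="cell_id"))
    return RichnessPattern(table, totals, incidence.grid.n_cells)


def _ranked_with_ties(cell_ids: np.ndarray, scores: np.ndarray, k: int):
    """Sort by score desc then cell_id asc; extend the cut at ties with rank k."""
    order = np.lexsort((cell_ids, -scores))
    cell_ids = cell_ids[order]
    scores = scores[order]
    if k >= len(cell_ids):
        return cell_ids.tolist(), scores.tolist(), False
    cut_score = scores[k - 1]
    n = k
    while n < len(scores) and scores[n] == cut_score:
        n += 1
    return cell_ids[:n].tolist(), scores[:n].tolist(), n > k


def top_richness_hotspots(
    pattern: RichnessPattern,
    fraction: float = 0.05,
    k_override: int | None = None,
) -> HotspotRanking:
    """Top-fraction cells by composite richness R_c, ties at the cut extended."""
    if pattern.n_occupied < 1:
        raise ValueError("no occupied cells")
    if k_override is None:
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        k = max(1, int(round(fraction * pattern.n_occupied)))
    else:
        if k_override < 1:
            raise ValueError("k_override must be >= 1")
        k = int(k_override)
    cells, scores, tied = _ranked_with_ties(
        pattern.table.index.to_numpy(), pattern.table["R"].to_numpy(), k
    )
    return HotspotRanking("richness", cells, scores, k, tied)


def greedy_complementarity(
    incidence: IncidenceMatrix,
    catalog: SpeciesCatalog,
    criterion: str = "all_species",
) -> ComplementaritySolution:
    """Greedy set-cover selection of grid cells until every species is covered.

    ``criterion='all_species'`` (default) picks, each step, the cell holding
    the largest number of still-uncovered species, as a literal reading of
    the selection rule; ``criterion='composite_gain'`` instead maximizes the
    composite ratio gain directly.  Ties break by larger composite gain,
    then smaller cell id.
    """
    if criterion not in ("all_species", "composite_gain"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if incidence.n_species == 0:
        raise ValueError("empty incidence matrix")
    per_species_cells = np.diff(incidence.matrix.indptr)
    if (per_species_cells == 0).any():
        bad = incidence.species_ids[per_species_cells == 0].tolist()
        raise ValueError(f"species with zero occurrences cannot be covered: {bad[:5]}")

    totals = catalog.group_totals()
    order = catalog.df.index.get_indexer(incidence.species_ids)
    masks = {g: catalog.group_mask(g)[order] for g in GROUPS}
    # composite weight of a species: its summed 1/N_g over the groups it is in
    w = np.zeros(incidence.n_species)
    for g in GROUPS:
        if totals[g] > 0:
            w += masks[g] / totals[g]

    cells_by_species = incidence.matrix.tocsc().T.tocsr()  # species x cells csr
    by_cell = incidence.matrix.T.tocsr()  # cells x species
    uncovered = np.ones(incidence.n_species, dtype=bool)
    steps: list[ComplementarityStep] = []
    k = 0
    while uncovered.any():
        counts = by_cell @ uncovered.astype(np.int64)
        gains = by_cell @ (uncovered * w)
        primary = counts if criterion == "all_species" else gains
        best = primary.max()
        cand = np.flatnonzero(primary == best)
        # gains are ratio sums; 1e-9 absorbs float summation-order noise
        cand = cand[gains[cand] >= gains[cand].max() - 1e-9]
        cell = int(cand.min())
        row = by_cell[cell]
        new_idx = row.indices[uncovered[row.indices]]
        new_idx = np.sort(new_idx)
        uncovered[new_idx] = False
        k += 1
        steps.append(
            ComplementarityStep(
                order=k,
                cell_id=cell,
                new_species=incidence.species_ids[new_idx],
                new_per_group={
                    g: int(masks[g][new_idx].sum()) for g in GROUPS
                },
                gain=float(w[new_idx].sum()),
                uncovered_after=int(uncovered.sum()),
            )
        )
    return ComplementaritySolution(steps, totals, incidence.grid.n_cells, criterion)


def top_complementarity_hotspots(
    solution: ComplementaritySolution, k: int = 150
) -> HotspotRanking:
    """Selected cells ranked by composite gain G_c, ties at the cut extended."""
    if not solution.steps:
        raise ValueError("empty complementarity solution")
    if k < 1:
        raise ValueError("k must be >= 1")
    cells = np.array([s.cell_id for s in solution.steps])
    gains = np.array([s.gain for s in solution.steps])
    ranked, scores, tied = _ranked_with_ties(cells, gains, k)
    return HotspotRanking("complementarity", ranked, scores, k, tied)


def integrate_hotspots(
    rank_R: HotspotRanking, rank_C: HotspotRanking, k_total: int = 150
) -> FinalHotspots:
    """Merge the two hotspot rankings into first/second-class final hotspots.

    First-class cells appear in both rankings and are ordered by the sum of
    their two rank positions (ties: larger summed score, then smaller cell
    id).  Second-class cells appear in exactly one ranking and fill up to
    ``k_total``, ordered by their single rank position (same tie rule).
    """
    if k_total < 1:
        raise ValueError("k_total must be >= 1")
    if not len(rank_R) or not len(rank_C):
        raise ValueError("both rankings must be nonempty")
    o_R, o_C = rank_R.orders(), rank_C.orders()
    s_R, s_C = rank_R.score_of(), rank_C.score_of()
    both = set(o_R) & set(o_C)
    first = sorted(both, key=lambda c: (o_R[c] + o_C[c], -(s_R[c] + s_C[c]), c))
    order_sum = {c: o_R[c] + o_C[c] for c in both}
    if len(first) >= k_total:
        return FinalHotspots(first[:k_total], [], k_total, order_sum)
    only = set(o_R) ^ set(o_C)

    def single_key(c):
        if c in o_R:
            return (o_R[c], -s_R[c], c)
        return (o_C[c], -s_C[c], c)

    second = sorted(only, key=single_key)[: k_total - len(first)]
    return FinalHotspots(first, second, k_total, order_sum)
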