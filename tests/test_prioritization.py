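import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from priorigrid.grid import make_grid
from priorigrid.occurrences import GROUPS
from priorigrid.prioritization import (
    greedy_complementarity,
    group_richness,
    integrate_hotspots,
    top_complementarity_hotspots,
    top_richness_hotspots,
    HotspotRanking,
)

from conftest import incidence_from_sets, make_catalog, random_catalog


def greedy_oracle(cell_species: dict[int, set], group_members: dict[str, set]):
    """Independent step-by-step simulation of the greedy selection rule.

    Selects the cell with most uncovered species (ties: larger composite
    gain, then smaller cell id) until every species is covered.  Returns
    [(cell, newly_covered_set, gain)].
    """
    from fractions import Fraction

    universe = set().union(*cell_species.values())
    uncovered = set(universe)
    nonzero = {g: m for g, m in group_members.items() if m}

    def gain_of(new):
        # exact rational arithmetic so tie comparisons are unambiguous
        return sum(
            (Fraction(len(new & m), len(m)) for m in nonzero.values()),
            Fraction(0),
        )

    trace = []
    while uncovered:
        best = None
        for cell in sorted(cell_species):
            new = cell_species[cell] & uncovered
            key = (len(new), gain_of(new), -cell)
            if best is None or key > best[0]:
                best = (key, cell, new)
        _, cell, new = best
        trace.append((cell, new, float(gain_of(new))))
        uncovered -= new
    return trace


def random_instance(rng, max_cells=12, max_species=20):
    n_sp = rng.integers(2, max_species + 1)
    n_cells = rng.integers(1, max_cells + 1)
    species = [f"s{i}" for i in range(n_sp)]
    grid = make_grid((0, 0, max(n_cells, 2) * 0.5, 0.5), 0.5)
    cell_species = {}
    # every species somewhere; extra random memberships
    for i, sp in enumerate(species):
        cell_species.setdefault(int(rng.integers(n_cells)), set()).add(sp)
    for _ in range(int(rng.integers(0, 3 * n_sp))):
        cell_species.setdefault(int(rng.integers(n_cells)), set()).add(
            species[rng.integers(n_sp)]
        )
    cell_species = {c: s for c, s in cell_species.items() if s}
    catalog = random_catalog(rng, species)
    inc = incidence_from_sets(cell_species, grid, species)
    return cell_species, catalog, inc


def catalog_group_members(catalog):
    return {g: set(catalog.group_members(g)) for g in GROUPS}


class TestGroupRichness:
    def test_cell_with_every_species_scores_five(self, unit_grid, catalog10):
        inc = incidence_from_sets({0: set(catalog10.species_ids)}, unit_grid)
        pat = group_richness(inc, catalog10)
        assert pat.composite(0) == pytest.approx(5.0)

    def test_unoccupied_cell_scores_zero(self, unit_grid, catalog10):
        inc = incidence_from_sets({0: {"sp01"}}, unit_grid)
        pat = group_richness(inc, catalog10)
        assert pat.composite(3) == 0.0

    def test_hand_ratio_sum(self, unit_grid):
        # 2/10 of ALL and 1/4 of ENDEMIC, nothing else -> R = 0.2 + 0.25
        catalog = make_catalog(
            [("e1", 1, 0, "none", 0, 0)]
            + [(f"e{i}", 1, 0, "none", 0, 0) for i in range(2, 5)]
            + [(f"x{i}", 0, 0, "none", 0, 0) for i in range(6)]
        )
        inc = incidence_from_sets({0: {"e1", "x0"}, 1: set(catalog.species_ids)}, unit_grid)
        pat = group_richness(inc, catalog)
        assert pat.composite(0) == pytest.approx(0.45)

    def test_adding_a_species_never_decreases_composite(self, unit_grid, catalog10):
        base = {0: {"sp01", "sp08"}, 1: {"sp05"}}
        inc0 = incidence_from_sets(base, unit_grid, list(catalog10.species_ids))
        r0 = group_richness(inc0, catalog10).composite(0)
        richer = {0: {"sp01", "sp08", "sp07"}, 1: {"sp05"}}
        inc1 = incidence_from_sets(richer, unit_grid, list(catalog10.species_ids))
        r1 = group_richness(inc1, catalog10).composite(0)
        assert r1 >= r0


class TestTopRichness:
    def make_pattern(self, scores, grid=None):
        grid = grid or make_grid((0, 0, 0.5 * len(scores), 0.5), 0.5)
        cells = {i: {f"s{i}"} for i in range(len(scores))}
        # build via a catalog of singleton species, then overwrite R by stacking
        import pandas as pd

        table = pd.DataFrame(
            {"R": scores}, index=pd.Index(range(len(scores)), name="cell_id")
        )
        from priorigrid.prioritization import RichnessPattern

        return RichnessPattern(table, {g: 1 for g in GROUPS}, grid.n_cells)

    def test_five_percent_of_hundred(self):
        pat = self.make_pattern(list(np.linspace(10, 1, 100)))
        rank = top_richness_hotspots(pat, fraction=0.05)
        assert len(rank) == 5 and rank.k == 5

    def test_tie_extension_at_cut(self):
        pat = self.make_pattern([9, 8, 7, 7, 7, 1, 0.5])
        rank = top_richness_hotspots(pat, k_override=4)
        assert len(rank) == 5 and rank.tie_extended
        assert rank.scores[-1] == 7

    def test_fraction_out_of_range(self):
        pat = self.make_pattern([1, 2, 3])
        with pytest.raises(ValueError):
            top_richness_hotspots(pat, fraction=1.5)

    def test_orders_consecutive_scores_nonincreasing(self):
        pat = self.make_pattern([3, 1, 4, 1, 5, 9, 2, 6])
        rank = top_richness_hotspots(pat, k_override=5)
        assert list(rank.orders().values()) == list(range(1, len(rank) + 1))
        assert all(a >= b for a, b in zip(rank.scores, rank.scores[1:]))


class TestGreedy:
    def test_single_cell_holding_all_species(self, unit_grid, catalog10):
        inc = incidence_from_sets({2: set(catalog10.species_ids)}, unit_grid)
        sol = greedy_complementarity(inc, catalog10)
        assert [s.cell_id for s in sol.steps] == [2]
        assert sol.steps[0].gain == pytest.approx(5.0)

    def test_subsumed_cell_never_selected(self, unit_grid):
        catalog = make_catalog([(f"s{i}", 0, 0, "none", 0, 0) for i in range(1, 5)])
        cells = {0: {"s1", "s2", "s3"}, 1: {"s3", "s4"}, 2: {"s4"}}
        inc = incidence_from_sets(cells, unit_grid, [f"s{i}" for i in range(1, 5)])
        sol = greedy_complementarity(inc, catalog)
        assert sol.cell_ids == [0, 1]

    def test_disjoint_cells_selected_in_richness_order(self, unit_grid):
        catalog = make_catalog([(f"s{i}", 0, 0, "none", 0, 0) for i in range(6)])
        cells = {0: {"s0", "s1", "s2"}, 1: {"s3", "s4"}, 2: {"s5"}}
        inc = incidence_from_sets(cells, unit_grid, [f"s{i}" for i in range(6)])
        sol = greedy_complementarity(inc, catalog)
        assert sol.cell_ids == [0, 1, 2]

    def test_species_without_occurrence_rejected(self, unit_grid, catalog10):
        inc = incidence_from_sets(
            {0: {"sp01"}}, unit_grid, ["sp01", "sp02"]
        )
        with pytest.raises(ValueError, match="zero occurrences"):
            greedy_complementarity(inc, catalog10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cell_species, catalog, inc = random_instance(rng)
        sol = greedy_complementarity(inc, catalog)
        oracle = greedy_oracle(cell_species, catalog_group_members(catalog))
        assert sol.cell_ids == [c for c, _, _ in oracle]
        for step, (_, new, gain) in zip(sol.steps, oracle):
            assert set(step.new_species) == new
            assert step.gain == pytest.approx(gain, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_covers_universe_and_gains_sum_to_nonempty_groups(self, seed):
        rng = np.random.default_rng(seed)
        _, catalog, inc = random_instance(rng)
        sol = greedy_complementarity(inc, catalog)
        covered = set().union(*(set(s.new_species) for s in sol.steps))
        assert covered == set(inc.species_ids)
        # newly-covered sets pairwise disjoint
        assert sum(len(s.new_species) for s in sol.steps) == len(covered)
        occurring = set(inc.species_ids)
        n_nonempty = sum(
            1 for g in GROUPS if set(catalog.group_members(g)) & occurring
        )
        assert sol.total_gain() == pytest.approx(n_nonempty, abs=1e-9)


class TestTopComplementarity:
    def make_solution(self, gains):
        from priorigrid.prioritization import ComplementarityStep, ComplementaritySolution
        import pandas as pd

        steps = [
            ComplementarityStep(i + 1, i, pd.Index([f"s{i}"]), {g: 0 for g in GROUPS}, g_, 0)
            for i, g_ in enumerate(gains)
        ]
        return ComplementaritySolution(steps, {g: 1 for g in GROUPS}, 100)

    def test_k_exceeding_pool_returns_all(self):
        rank = top_complementarity_hotspots(self.make_solution([1.0, 0.5, 0.2]), k=150)
        assert len(rank) == 3

    def test_no_tie_at_cut(self):
        rank = top_complementarity_hotspots(self.make_solution([1.0, 0.5, 0.5, 0.1]), k=3)
        assert len(rank) == 3 and not rank.tie_extended

    def test_tie_at_cut_extends(self):
        rank = top_complementarity_hotspots(self.make_solution([1.0, 0.5, 0.3, 0.3]), k=3)
        assert len(rank) == 4 and rank.tie_extended


def ranking(algorithm, cells, scores=None, k=None):
    scores = scores if scores is not None else list(range(len(cells), 0, -1))
    return HotspotRanking(algorithm, list(cells), [float(s) for s in scores], k or len(cells))


class TestIntegration:
    def test_identical_rankings_all_first_class(self):
        cells = list(range(150))
        fh = integrate_hotspots(ranking("richness", cells), ranking("complementarity", cells), 150)
        assert len(fh.first_class) == 150 and fh.second_class == []

    def test_spec_example_first_and_second(self):
        # R = [a, b, c], C = [c, d, e] as cells 1..5; k_total 4
        r = ranking("richness", [1, 2, 3], [9, 8, 7])
        c = ranking("complementarity", [3, 4, 5], [6, 5, 4])
        fh = integrate_hotspots(r, c, 4)
        assert fh.first_class == [3]
        # second class sorted by single order: a(1), d(2... wait d has order 2), b(2)
        assert set(fh.second_class) == {1, 4, 2}
        assert fh.second_class[0] == 1  # order 1 beats order 2

    def test_disjoint_rankings_interleave_by_order(self):
        r = ranking("richness", [0, 1, 2], [9, 8, 7])
        c = ranking("complementarity", [10, 11, 12], [9.5, 8.5, 7.5])
        fh = integrate_hotspots(r, c, 4)
        assert fh.first_class == []
        # orders: 0->1, 10->1, 1->2, 11->2 ; ties broken by larger score
        assert fh.second_class == [10, 0, 11, 1]

    def test_first_class_overflow_truncated_by_order_sum(self):
        r = ranking("richness", [5, 6, 7], [3, 2, 1])
        c = ranking("complementarity", [7, 6, 5], [3, 2, 1])
        fh = integrate_hotspots(r, c, 2)
        # order sums: 5->1+3=4, 6->2+2=4, 7->3+1=4; tie by larger summed score
        assert len(fh.first_class) == 2 and fh.second_class == []

    def test_conservation_and_disjointness_randomized(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            pool = rng.permutation(200)
            a = pool[: rng.integers(1, n + 1)].tolist()
            b = rng.permutation(200)[: rng.integers(1, n + 1)].tolist()
            k_total = int(rng.integers(1, n + 1))
            fh = integrate_hotspots(
                ranking("richness", a), ranking("complementarity", b), k_total
            )
            assert not (set(fh.first_class) & set(fh.second_class))
            expected = min(k_total, len(set(a) | set(b)))
            assert len(fh) == expected
            assert fh.cells <= set(a) | set(b)
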