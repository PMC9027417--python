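import pandas as pd
import pytest
from scipy import sparse

from priorigrid.grid import make_grid
from priorigrid.occurrences import IncidenceMatrix, SpeciesCatalog


def make_catalog(rows):
    """Catalog from (species_id, endemic, threatened, category, cites, protected)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "species_id", "endemic", "threatened", "threat_category",
            "cites", "national_protected",
        ],
    )
    return SpeciesCatalog(df)


def incidence_from_sets(cell_species: dict[int, set], grid, species_order=None):
    """IncidenceMatrix from a {cell_id: species set} mapping."""
    if species_order is None:
        species_order = sorted(set().union(*cell_species.values()))
    index = pd.Index(species_order, name="species_id")
    m = sparse.lil_matrix((len(index), grid.n_cells), dtype=bool)
    for cell, species in cell_species.items():
        for sp in species:
            m[index.get_loc(sp), cell] = True
    return IncidenceMatrix(m.tocsr(), index, grid)


def random_catalog(rng, species_ids, p=(0.4, 0.25, 0.2, 0.15)):
    """Random group memberships over given species ids."""
    rows = []
    for sp in species_ids:
        th = rng.random() < p[1]
        rows.append(
            (
                sp,
                int(rng.random() < p[0]),
                int(th),
                rng.choice(["VU", "EN", "CR"]) if th else "none",
                int(rng.random() < p[2]),
                int(rng.random() < p[3]),
            )
        )
    return make_catalog(rows)


@pytest.fixture
def unit_grid():
    """2 x 2 grid of 0.5-degree cells over (0, 0, 1, 1)."""
    return make_grid((0.0, 0.0, 1.0, 1.0), 0.5)


@pytest.fixture
def catalog10():
    """10 species: 4 endemic, 3 threatened (2 of them endemic), 1 CITES, 1 protected."""
    return make_catalog(
        [
            ("sp01", 1, 1, "VU", 0, 0),
            ("sp02", 1, 1, "EN", 0, 0),
            ("sp03", 1, 0, "none", 0, 0),
            ("sp04", 1, 0, "none", 0, 0),
            ("sp05", 0, 1, "CR", 0, 0),
            ("sp06", 0, 0, "none", 1, 0),
            ("sp07", 0, 0, "none", 0, 1),
            ("sp08", 0, 0, "none", 0, 0),
            ("sp09", 0, 0, "none", 0, 0),
            ("sp10", 0, 0, "none", 0, 0),
        ]
    )
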