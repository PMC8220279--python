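"""Shared fixtures: small synthetic datasets built fresh per session."""

import numpy as np
import pandas as pd
import pytest

from eggsig import SimulationConfig, generate_species_dataset, generate_tree
from eggsig.schema import METRIC_COLUMNS


@pytest.fixture(scope="session")
def small_dataset():
    """Seven-species, two-family dataset (~100 clutches), with immaculate species."""
    cfg = SimulationConfig(
        seed=42,
        n_species_per_family=(3, 4),
        clutch_count_per_species=(14, 22),
        n_immaculate_species=1,
    )
    return generate_species_dataset(cfg)


@pytest.fixture(scope="session")
def big_dataset():
    """Study-scale dataset at the generator defaults (25 species, ~800 clutches)."""
    return generate_species_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def yule_tree_30():
    return generate_tree(30, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_eggs(clutch_sizes, values=None, species="spA", family="warbler"):
    """Hand-built egg table with given clutch sizes; metrics default to zeros."""
    rows = []
    k = 0
    for c, size in enumerate(clutch_sizes):
        for e in range(size):
            row = {
                "species": species,
                "family": family,
                "clutch_id": f"{species}_c{c}",
                "egg_id": f"{species}_c{c}_e{e}",
                "parasitized": False,
                "parasitized_elsewhere": False,
            }
            vec = np.zeros(len(METRIC_COLUMNS)) if values is None else np.asarray(values[k])
            row.update(dict(zip(METRIC_COLUMNS, vec)))
            rows.append(row)
            k += 1
    return pd.DataFrame(rows)
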