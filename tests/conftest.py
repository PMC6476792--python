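import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import funcrare as fr

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_community():
    """A compact but realistic synthetic community shared across tests."""
    cfg = fr.SyntheticConfig(seed=42, n_species=40, n_plots=2,
                             stems_per_plot=200, n_individuals=3)
    inv, traits, wd, truth = fr.generate_community(cfg)
    return inv, traits, wd, truth


@pytest.fixture(scope="session")
def small_space(small_community):
    _, traits, _, _ = small_community
    return fr.build_functional_space(fr.TraitTable(traits))


@pytest.fixture
def toy_inventory():
    """Hand-enumerable inventory: 3 species, unequal stem counts and sizes."""
    rows = []
    for i in range(50):
        rows.append(("P1", f"a{i}", "A", 20.0))
    for i in range(25):
        rows.append(("P1", f"b{i}", "B", 30.0))
    for i in range(5):
        rows.append(("P1", f"c{i}", "C", 40.0))
    df = pd.DataFrame(rows, columns=["plot", "tree", "species", "dbh_cm"])
    df["height_m"] = np.nan
    df["forest_type"] = "toy"
    return df


def random_space(rng, n_species=None, k=None):
    """Random (not z-scored) coordinates wrapped as a FunctionalSpace."""
    s = n_species or int(rng.integers(2, 51))
    kk = k or int(rng.integers(1, 7))
    axes = rng.normal(size=(s, kk))
    return fr.FunctionalSpace(species=[f"sp{i}" for i in range(s)], axes=axes,
                              trait_names=tuple(f"t{j}" for j in range(kk)),
                              params={})
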