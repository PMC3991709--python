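import dendropy
import numpy as np
import pandas as pd
import pytest

from phyloturn.census_io import CensusPair
from phyloturn.phylo import patristic_matrix
from phyloturn.synthetic import (
    SyntheticConfig,
    simulate_census_pair,
    simulate_phylogeny_traits,
)


def tree_from(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)


@pytest.fixture(scope="session")
def small_synthetic():
    """One small neutral synthetic dataset shared across tests."""
    cfg = SyntheticConfig(n_species=20, n_stems=2500)
    rng = np.random.default_rng(42)
    tree, traits = simulate_phylogeny_traits(cfg, rng)
    pair, sp_table, truth = simulate_census_pair(tree, traits, cfg, rng)
    return {"config": cfg, "tree": tree, "traits": traits, "pair": pair,
            "species_table": sp_table, "truth": truth,
            "D": patristic_matrix(tree)}


@pytest.fixture()
def toy_pair():
    """Hand-built 2-census plot: A survives, B dies, C recruits."""
    c1 = pd.DataFrame({
        "tag": ["A", "B"], "species": ["sp1", "sp2"],
        "x": [1.0, 2.0], "y": [1.0, 2.0], "dbh": [5.0, 10.0],
        "status": ["alive", "alive"]})
    c2 = pd.DataFrame({
        "tag": ["A", "B", "C"], "species": ["sp1", "sp2", "sp1"],
        "x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0],
        "dbh": [5.5, np.nan, 1.2], "status": ["alive", "dead", "alive"]})
    return CensusPair(c1, c2, plot_dims=(10.0, 10.0))
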