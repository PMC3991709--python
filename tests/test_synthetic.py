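import dataclasses

import numpy as np
import pytest
from scipy import stats

from phyloturn.census_io import classify_demographics
from phyloturn.nullmodels import NullModelConfig, measure_dispersal
from phyloturn.phylo import patristic_matrix
from phyloturn.synthetic import (
    SyntheticConfig,
    environment_field,
    nm2_generated_pair,
    scenario_config,
    simulate_census_pair,
    simulate_phylogeny_traits,
)


class TestSimulatePhylogenyTraits:
    def test_unit_depth_ultrametric(self):
        rng = np.random.default_rng(0)
        tree, _ = simulate_phylogeny_traits(SyntheticConfig(n_species=25), rng)
        depths = []
        for tip in tree.leaf_node_iter():
            d, nd = 0.0, tip
            while nd.parent_node is not None:
                d += nd.edge.length
                nd = nd.parent_node
            depths.append(d)
        assert np.allclose(depths, 1.0, atol=1e-9)
        assert len(depths) == 25

    def test_bit_reproducible(self):
        cfg = SyntheticConfig(n_species=15, n_stems=1500)
        a = simulate_phylogeny_traits(cfg, np.random.default_rng(3))
        b = simulate_phylogeny_traits(cfg, np.random.default_rng(3))
        assert a[1].equals(b[1])
        assert a[0].as_string(schema="newick") == b[0].as_string(schema="newick")

    def test_sister_tip_bm_covariance(self):
        """Under Brownian motion, cov(trait_i, trait_j) over replicates
        equals the shared path length from the root."""
        rng = np.random.default_rng(1)
        cfg = SyntheticConfig(n_species=10)
        tree, _ = simulate_phylogeny_traits(cfg, rng)
        from phyloturn.signal import bm_covariance
        C, labels = bm_covariance(tree)
        # resimulate traits on the same topology many times
        vals = []
        sigma = 1.0
        for _ in range(3000):
            state = {id(tree.seed_node): 0.0}
            tips = {}
            for node in tree.preorder_node_iter():
                if node.parent_node is not None:
                    state[id(node)] = state[id(node.parent_node)] + \
                        sigma * np.sqrt(node.edge.length) * rng.standard_normal()
                if node.is_leaf():
                    tips[node.taxon.label] = state[id(node)]
            vals.append([tips[lb] for lb in labels])
        emp = np.cov(np.array(vals).T)
        assert np.allclose(emp, C, atol=0.12)

    def test_white_traits_lack_signal(self):
        rng = np.random.default_rng(2)
        cfg = SyntheticConfig(n_species=40, trait_model="white")
        from phyloturn.signal import blomberg_k
        ks = []
        for _ in range(40):
            tree, traits = simulate_phylogeny_traits(cfg, rng)
            ks.append(blomberg_k(tree, traits["trait"].to_dict()))
        assert np.mean(ks) < 0.6

    def test_multivariate_traits_columns(self):
        rng = np.random.default_rng(3)
        cfg = SyntheticConfig(n_species=10, n_traits=4)
        _, traits = simulate_phylogeny_traits(cfg, rng)
        assert list(traits.columns) == ["trait", "trait2", "trait3", "trait4"]


class TestSimulateCensusPair:
    def test_stem_counts_and_validity(self, small_synthetic):
        pair = small_synthetic["pair"]
        cfg = small_synthetic["config"]
        assert len(pair.census1) == cfg.n_stems
        assert (pair.census1.dbh >= 1.0).all()
        w, h = cfg.plot_dims
        assert pair.census1.x.between(0, w).all()
        assert pair.census1.y.between(0, h).all()

    def test_truth_record_consistency(self, small_synthetic):
        truth = small_synthetic["truth"]
        demo = classify_demographics(small_synthetic["pair"])
        assert truth.stems.died.sum() == len(demo.deaths)
        assert len(truth.recruits) == len(demo.recruits)
        assert (truth.recruits.distance >= 0).all()

    def test_dispersal_kernel_recovery(self):
        """Dp measured on synthetic recruits tracks the configured kernel:
        species with larger dispersal scales have larger median Dp."""
        cfg = SyntheticConfig(n_species=12, n_stems=6000,
                              dispersal_sdlog=1.0, recruit_rate=1.5)
        rng = np.random.default_rng(9)
        tree, traits = simulate_phylogeny_traits(cfg, rng)
        pair, sp_table, truth = simulate_census_pair(tree, traits, cfg, rng)
        rec = measure_dispersal(pair, sp_table, NullModelConfig())
        merged = rec.merge(truth.recruits[["tag", "distance"]], on="tag")
        with_dp = merged.dropna(subset=["Dp"])
        # Dp is the nearest mature conspecific, never farther than the parent
        parent_mature = with_dp.Dp <= with_dp.distance + 1e-9
        assert parent_mature.mean() > 0.9
        rho = stats.spearmanr(with_dp.Dp, with_dp.distance).statistic
        assert rho > 0.3

    def test_filtering_kills_mismatched_stems(self):
        cfg = scenario_config("filtering")
        cfg = dataclasses.replace(cfg, plot_dims=(200.0, 100.0), n_stems=8000,
                                  n_species=30)
        rng = np.random.default_rng(4)
        tree, traits = simulate_phylogeny_traits(cfg, rng)
        pair, sp_table, truth = simulate_census_pair(tree, traits, cfg, rng)
        # survival probability decreases with trait-environment mismatch
        assert stats.pearsonr(truth.stems.p_survival,
                              truth.stems.died.astype(float)).statistic < 0

    def test_density_dependence_raises_related_mortality(self):
        cfg = scenario_config("density")
        cfg = dataclasses.replace(cfg, n_stems=4000, n_species=20)
        rng = np.random.default_rng(5)
        tree, traits = simulate_phylogeny_traits(cfg, rng)
        pair, sp_table, truth = simulate_census_pair(tree, traits, cfg, rng)
        neutral = dataclasses.replace(cfg, delta=0.0)
        rng2 = np.random.default_rng(5)
        tree2, traits2 = simulate_phylogeny_traits(neutral, rng2)
        _, _, truth2 = simulate_census_pair(tree2, traits2, neutral, rng2)
        # forcing spreads the survival probabilities
        assert truth.stems.p_survival.std() > truth2.stems.p_survival.std()

    def test_nm2_generated_pair_is_valid(self, small_synthetic):
        pair = small_synthetic["pair"]
        out = nm2_generated_pair(pair, small_synthetic["species_table"],
                                 NullModelConfig(), np.random.default_rng(0))
        demo = classify_demographics(out)
        n_alive1 = (pair.census1.status == "alive").sum()
        assert len(demo.survivors) + len(demo.deaths) == n_alive1
        # plot-level abundances preserved exactly
        obs = pair.census2.loc[pair.census2.status == "alive"].species.value_counts()
        sim = out.census2.species.value_counts()
        assert obs.sort_index().equals(sim.sort_index())
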