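import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phyloturn.census_io import CensusPair, classify_demographics
from phyloturn.nullmodels import (
    DEFAULT_SIZE_CLASS_EDGES,
    NM2Sampler,
    NullModelConfig,
    estimate_survival_table,
    measure_dispersal,
    nm1_permute,
    size_class,
)


class TestSizeClasses:
    def test_printed_bins(self):
        dbh = np.array([1.0, 1.9, 19.9, 20.0, 24.9, 25.0, 54.9, 55.0, 200.0])
        cls = size_class(dbh)
        assert list(cls) == [0, 0, 18, 19, 19, 20, 22, 23, 23]

    def test_below_threshold_error(self):
        with pytest.raises(ValueError):
            size_class(np.array([0.5]))


class TestNm1Permute:
    def test_two_species_balance(self):
        rng = np.random.default_rng(0)
        n_swap = sum(nm1_permute(2, rng)[0] == 1 for _ in range(499))
        # identity vs swap each with probability 1/2
        chi2 = (n_swap - 249.5) ** 2 / 249.5 + (499 - n_swap - 249.5) ** 2 / 249.5
        assert stats.chi2.sf(chi2, df=1) > 0.01

    def test_is_permutation(self):
        rng = np.random.default_rng(1)
        p = nm1_permute(20, rng)
        assert sorted(p) == list(range(20))


class TestSurvivalTable:
    def test_rates_from_counts(self, toy_pair):
        tab = estimate_survival_table(toy_pair)
        # sp1 stem of 5 cm survived; sp2 stem of 10 cm died
        assert tab.loc[("sp1", 4), "survival_rate"] == 1.0
        assert tab.loc[("sp2", 9), "survival_rate"] == 0.0

    def test_parameter_recovery_within_binomial_envelope(self, small_synthetic):
        """Estimated per-cell survival rates must sit inside 99% binomial
        envelopes of the generator's realized survival probabilities."""
        pair = small_synthetic["pair"]
        truth = small_synthetic["truth"]
        tab = estimate_survival_table(pair)
        tr = truth.stems.set_index("tag")
        c1 = pair.census1.loc[pair.census1.status == "alive"]
        cls = size_class(c1.dbh.to_numpy())
        df = pd.DataFrame({"species": c1.species.to_numpy(), "size_class": cls,
                           "p": c1.tag.map(tr.p_survival).to_numpy()})
        mean_p = df.groupby(["species", "size_class"])["p"].mean()
        violations = 0
        n_checked = 0
        for key, row in tab.iterrows():
            n = int(row.n_alive_c1)
            if n < 5:
                continue
            n_checked += 1
            lo, hi = stats.binom.ppf([0.005, 0.995], n, mean_p.loc[key])
            if not lo <= row.n_surviving <= hi:
                violations += 1
        assert n_checked > 20
        assert violations <= max(3, 0.05 * n_checked)


class TestMeasureDispersal:
    def test_nearest_mature_conspecific(self):
        c1 = pd.DataFrame({
            "tag": ["p1", "p2", "q1"], "species": ["sp1", "sp1", "sp2"],
            "x": [10.0, 50.0, 30.0], "y": [10.0, 10.0, 10.0],
            "dbh": [20.0, 20.0, 20.0], "status": "alive"})
        c2 = pd.DataFrame({
            "tag": ["p1", "p2", "q1", "r1"], "species": ["sp1", "sp1", "sp2", "sp1"],
            "x": [10.0, 50.0, 30.0, 13.0], "y": [10.0, 10.0, 10.0, 14.0],
            "dbh": [21.0, 21.0, 21.0, 1.1], "status": "alive"})
        pair = CensusPair(c1, c2, (100.0, 100.0))
        sp = pd.DataFrame({"species": ["sp1", "sp2"],
                           "growth_form": ["tree", "tree"]}).set_index("species")
        rec = measure_dispersal(pair, sp)
        assert len(rec) == 1
        assert rec.Dp.iloc[0] == pytest.approx(5.0)

    def test_no_parent_within_radius(self):
        c1 = pd.DataFrame({"tag": ["p1"], "species": ["sp1"], "x": [0.0],
                           "y": [0.0], "dbh": [20.0], "status": "alive"})
        c2 = pd.DataFrame({
            "tag": ["p1", "r1"], "species": ["sp1", "sp1"],
            "x": [0.0, 80.0], "y": [0.0, 0.0], "dbh": [21.0, 1.1],
            "status": "alive"})
        pair = CensusPair(c1, c2, (100.0, 100.0))
        sp = pd.DataFrame({"species": ["sp1"], "growth_form": ["tree"]}).set_index("species")
        rec = measure_dispersal(pair, sp)
        assert np.isnan(rec.Dp.iloc[0])

    def test_matches_exhaustive_nearest_neighbor(self, small_synthetic):
        pair = small_synthetic["pair"]
        sp_table = small_synthetic["species_table"]
        cfg = NullModelConfig()
        rec = measure_dispersal(pair, sp_table, cfg)
        c1 = pair.census1
        from phyloturn.nullmodels import mature_mask
        mat = c1.loc[mature_mask(c1, sp_table)]
        rng = np.random.default_rng(0)
        for _, r in rec.sample(min(len(rec), 40), random_state=7).iterrows():
            cand = mat.loc[mat.species == r.species]
            d = np.hypot(cand.x - r.x, cand.y - r.y)
            expect = d.min() if len(d) and d.min() <= cfg.parent_radius else np.nan
            if np.isnan(expect):
                assert np.isnan(r.Dp)
            else:
                assert r.Dp == pytest.approx(expect)


@pytest.fixture(scope="module")
def sampler(small_synthetic):
    return NM2Sampler(small_synthetic["pair"],
                      small_synthetic["species_table"],
                      NullModelConfig())


class TestNM2Replicate:

    def test_exact_count_conserves_species_deaths(self, small_synthetic, sampler):
        pair = small_synthetic["pair"]
        demo = classify_demographics(pair)
        obs_alive2 = (pair.census2.loc[pair.census2.status == "alive"]
                      .species.value_counts())
        for k in range(3):
            sim = sampler.replicate(np.random.default_rng(k))
            sim_counts = pd.Series(sim.species).value_counts()
            pd.testing.assert_series_equal(
                sim_counts.sort_index(), obs_alive2.sort_index(),
                check_names=False)

    def test_recruits_exactly_dp_from_mature_conspecific(self, small_synthetic, sampler):
        pair = small_synthetic["pair"]
        sp_table = small_synthetic["species_table"]
        cfg = NullModelConfig()
        rec = measure_dispersal(pair, sp_table, cfg)
        from phyloturn.nullmodels import mature_mask
        c1 = pair.census1
        mat = c1.loc[mature_mask(c1, sp_table, cfg.mature_dbh)]
        for k in range(3):
            sim = sampler.replicate(np.random.default_rng(100 + k))
            assert sim.log["uniform_fallbacks"] == 0
            df = sim.to_dataframe().set_index("tag")
            with_dp = rec.loc[rec.Dp.notna()]
            for _, r in with_dp.sample(min(len(with_dp), 25),
                                       random_state=k).iterrows():
                pos = df.loc[r.tag]
                cand = mat.loc[mat.species == r.species]
                d = np.hypot(cand.x - pos.x, cand.y - pos.y)
                assert np.min(np.abs(d - r.Dp)) < 1e-8

    def test_survivors_keep_positions(self, small_synthetic, sampler):
        pair = small_synthetic["pair"]
        c1 = pair.census1.set_index("tag")
        sim = sampler.replicate(np.random.default_rng(5))
        df = sim.to_dataframe()
        demo = classify_demographics(pair)
        surv = df.loc[df.tag.isin(demo.survivors)].set_index("tag")
        assert np.allclose(surv.x, c1.loc[surv.index, "x"])
        assert np.allclose(surv.y, c1.loc[surv.index, "y"])

    def test_full_survival_cell_always_survives(self):
        # one species, one stem, survived: identity on census 2 modulo recruits
        c1 = pd.DataFrame({"tag": ["a"], "species": ["sp1"], "x": [1.0],
                           "y": [1.0], "dbh": [5.0], "status": "alive"})
        c2 = c1.assign(dbh=[5.5])
        pair = CensusPair(c1, c2, (10.0, 10.0))
        sp = pd.DataFrame({"species": ["sp1"], "growth_form": ["shrub"]}).set_index("species")
        sim = NM2Sampler(pair, sp, NullModelConfig()).replicate(np.random.default_rng(0))
        assert list(sim.tags) == ["a"]
        assert sim.x[0] == 1.0 and sim.y[0] == 1.0
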