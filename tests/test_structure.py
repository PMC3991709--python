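import itertools

import numpy as np
import pytest
from scipy import stats

from phyloturn.community import CommunityMatrix, QuadratGrid
from phyloturn.phylo import PatristicMatrix
from phyloturn.structure import independent_swap, mpd, nri


def random_distance_matrix(rng, k, scale=10.0):
    D = rng.random((k, k)) * scale
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    return D


class TestMpd:
    def test_two_species(self):
        D = np.array([[0.0, 8.0], [8.0, 0.0]])
        assert mpd([1, 1], D) == 8.0

    def test_three_species_mean_of_pairs(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = 2
        D[0, 2] = D[2, 0] = 4
        D[1, 2] = D[2, 1] = 6
        assert mpd([1, 1, 1], D) == pytest.approx(4.0)

    def test_matches_exhaustive_pair_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(5, 15)
            D = random_distance_matrix(rng, k)
            row = rng.random(k) < 0.5
            if row.sum() < 2:
                continue
            idx = np.flatnonzero(row)
            pairs = list(itertools.combinations(idx, 2))
            expect = np.mean([D[i, j] for i, j in pairs])
            assert mpd(row, D) == pytest.approx(expect)

    def test_richness_below_two(self):
        with pytest.raises(ValueError):
            mpd([1, 0, 0], np.zeros((3, 3)))


class TestIndependentSwap:
    def test_two_by_two_only_move(self):
        m = np.array([[1, 0], [0, 1]])
        out = independent_swap(m, 1, np.random.default_rng(0))
        assert np.array_equal(out, np.array([[0, 1], [1, 0]]))

    def test_margins_preserved(self):
        rng = np.random.default_rng(1)
        m = (rng.random((30, 15)) < 0.3).astype(int)
        for seed in range(5):
            out = independent_swap(m, 200, np.random.default_rng(seed))
            assert np.array_equal(out.sum(0), m.sum(0))
            assert np.array_equal(out.sum(1), m.sum(1))

    def test_no_checkerboard_warns(self):
        m = np.ones((3, 3), dtype=int)
        with pytest.warns(UserWarning, match="checkerboard"):
            out = independent_swap(m, 5, np.random.default_rng(0))
        assert np.array_equal(out, m)

    def test_stationary_distribution_uniform(self):
        """On a small matrix the swap chain is doubly stochastic, so the
        long-run state distribution over the reachable set is uniform."""
        rng = np.random.default_rng(7)
        m0 = np.array([[1, 0, 1, 0],
                       [0, 1, 0, 1],
                       [1, 1, 0, 0],
                       [0, 0, 1, 1]])
        # enumerate reachable states by BFS over single swaps
        def neighbors(m):
            out = []
            for r1, r2 in itertools.combinations(range(4), 2):
                for c1, c2 in itertools.combinations(range(4), 2):
                    sub = m[np.ix_([r1, r2], [c1, c2])]
                    if sub[0, 0] == sub[1, 1] and sub[0, 1] == sub[1, 0] \
                            and sub[0, 0] != sub[0, 1]:
                        m2 = m.copy()
                        m2[np.ix_([r1, r2], [c1, c2])] = sub[::-1]
                        out.append(m2)
            return out

        seen = {m0.tobytes(): 0}
        frontier = [m0]
        while frontier:
            nxt = []
            for m in frontier:
                for m2 in neighbors(m):
                    key = m2.tobytes()
                    if key not in seen:
                        seen[key] = len(seen)
                        nxt.append(m2)
            frontier = nxt
        n_states = len(seen)
        assert n_states > 2
        counts = np.zeros(n_states)
        m = m0
        n_samples = 4000
        for _ in range(n_samples):
            m = independent_swap(m, 50, rng, count_attempts=True)
            counts[seen[m.tobytes()]] += 1
        chi2 = ((counts - n_samples / n_states) ** 2 / (n_samples / n_states)).sum()
        assert stats.chi2.sf(chi2, df=n_states - 1) > 0.01


def make_community(counts, s=10.0):
    counts = np.asarray(counts)
    q = counts.shape[0]
    nx = q
    grid = QuadratGrid(s=s, nx=nx, ny=1, plot_dims=(nx * s, s))
    return CommunityMatrix(counts=counts, grid=grid,
                           species=tuple(f"sp{i}" for i in range(counts.shape[1])))


class TestNri:
    def test_full_row_degenerate(self):
        rng = np.random.default_rng(0)
        D = random_distance_matrix(rng, 5)
        counts = (rng.random((8, 5)) < 0.5).astype(int)
        counts[0] = 1  # fully occupied quadrat: identical in every null
        cm = make_community(counts)
        pm = PatristicMatrix(D, cm.species)
        res = nri(cm, pm, n_rand=49, rng=rng)
        assert res.flag.iloc[0] == "degenerate_null"

    def test_null_consistency_random_assembly(self, small_synthetic):
        """Quadrats assembled uniformly at random from the pool should show
        no phylogenetic structure: mean NRI within +/- 0.15."""
        rng = np.random.default_rng(5)
        D = small_synthetic["D"]
        k = len(D.species)
        pres = (rng.random((220, k)) < 0.35).astype(int)
        cm = make_community(pres)
        res = nri(cm, PatristicMatrix(D.matrix, cm.species), n_rand=99, rng=rng)
        ok = res.flag == "ok"
        assert ok.sum() >= 200
        assert abs(res.loc[ok, "NRI"].mean()) < 0.15

    def test_branch_length_scale_invariance(self, small_synthetic):
        rng_a = np.random.default_rng(11)
        rng_b = np.random.default_rng(11)
        D = small_synthetic["D"]
        k = len(D.species)
        pres = (np.random.default_rng(1).random((30, k)) < 0.4).astype(int)
        cm = make_community(pres)
        res_a = nri(cm, PatristicMatrix(D.matrix, cm.species),
                    n_rand=99, rng=rng_a)
        res_b = nri(cm, PatristicMatrix(D.matrix * 7.5, cm.species),
                    n_rand=99, rng=rng_b)
        ok = (res_a.flag == "ok") & (res_b.flag == "ok")
        assert np.allclose(res_a.loc[ok, "NRI"], res_b.loc[ok, "NRI"], atol=1e-9)

    def test_clustering_sign_convention(self):
        """Quadrats of close relatives must get positive NRI."""
        # two clades far apart; quadrats hold species from one clade only
        k = 8
        D = np.full((k, k), 100.0)
        D[:4, :4] = 1.0
        D[4:, 4:] = 1.0
        np.fill_diagonal(D, 0)
        rng = np.random.default_rng(3)
        rows = []
        for q in range(30):
            row = np.zeros(k, dtype=int)
            clade = slice(0, 4) if q % 2 == 0 else slice(4, 8)
            row[clade] = rng.random(4) < 0.8
            if row.sum() < 2:
                row[clade] = 1
            rows.append(row)
        cm = make_community(np.array(rows))
        res = nri(cm, PatristicMatrix(D, cm.species), n_rand=99, rng=rng)
        ok = res.flag == "ok"
        assert res.loc[ok, "NRI"].mean() > 1.0
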