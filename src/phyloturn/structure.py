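"""Phylogenetic similarity per quadrat: MPD and the net relatedness index.

NRI for a quadrat is the negated z-score of its observed mean pairwise
patristic distance (MPD, unweighted over all distinct species pairs present)
against MPDs of null communities produced by the independent-swap
randomization — sequences of 2x2 checkerboard submatrix swaps that preserve
every quadrat's richness and every species' occurrence frequency exactly:

    NRI = -(MPD_sample - mean(MPD_null)) / sd(MPD_null)

Positive NRI means co-occurring species are more closely related than the
null expects (phylogenetic clustering).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from numba import njit

from .community import CommunityMatrix
from .phylo import PatristicMatrix


def mpd(presence: np.ndarray, D: np.ndarray) -> float:
    """Unweighted mean of d_ij over all unordered pairs of present species."""
    idx = np.flatnonzero(np.asarray(presence))
    k = len(idx)
    if k < 2:
        raise ValueError("MPD needs at least 2 species present")
    sub = D[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


@njit(cache=True)
def _swap_loop(m, n_swaps, seed, count_attempts):  # pragma: no cover - numba
    np.random.seed(seed)
    nr, nc = m.shape
    done = 0
    attempts = 0
    max_attempts = 500 * n_swaps + 10_000 if not count_attempts else n_swaps
    while (attempts if count_attempts else done) < n_swaps \
            and attempts < max_attempts:
        attempts += 1
        r1 = np.random.randint(nr)
        r2 = np.random.randint(nr)
        c1 = np.random.randint(nc)
        c2 = np.random.randint(nc)
        if r1 == r2 or c1 == c2:
            continue
        a, b = m[r1, c1], m[r1, c2]
        c, d = m[r2, c1], m[r2, c2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            m[r1, c1] = 0
            m[r2, c2] = 0
            m[r1, c2] = 1
            m[r2, c1] = 1
            done += 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            m[r1, c1] = 1
            m[r2, c2] = 1
            m[r1, c2] = 0
            m[r2, c1] = 0
            done += 1
    return done


def independent_swap(
    presence: np.ndarray,
    n_successful_swaps: int,
    rng: np.random.Generator,
    count_attempts: bool = False,
) -> np.ndarray:
    """Randomize a binary matrix by checkerboard swaps, preserving all row
    and column sums exactly.  Returns a new matrix; warns and returns an
    unchanged copy if no checkerboard unit exists.

    With ``count_attempts=True`` the budget counts proposals rather than
    successful swaps.  The attempt-counting (lazy) chain has a uniform
    stationary distribution over reachable matrices; counting successes
    gives the jump chain, whose stationary weight of a matrix is
    proportional to its number of swappable 2x2 units.
    """
    m = np.ascontiguousarray(np.asarray(presence, dtype=np.int8).copy())
    if m.ndim != 2 or not np.isin(m, (0, 1)).all():
        raise ValueError("presence must be a binary 2-D matrix")
    seed = int(rng.integers(0, 2**31 - 1))
    done = _swap_loop(m, int(n_successful_swaps), seed, count_attempts)
    if done == 0 and n_successful_swaps > 0 and not count_attempts:
        warnings.warn("no checkerboard unit found; matrix returned unchanged")
    return m.astype(np.int64)


def nri(
    community: CommunityMatrix,
    D: PatristicMatrix,
    n_rand: int = 499,
    swaps_per_null: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """NRI per quadrat against the independent-swap null.

    Quadrats with fewer than 2 species are flagged ``low_richness``;
    quadrats whose null MPDs are all identical (e.g. all species present)
    are flagged ``degenerate_null``.  ``swaps_per_null`` defaults to twice
    the number of presences in the matrix, with independent chains started
    from the observed matrix for each of the ``n_rand`` nulls.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if list(community.species) != list(D.species):
        D = D.reorder(list(community.species))
    Dm = D.matrix
    P = community.presence()
    occupied = P.sum(axis=1) >= 2
    if swaps_per_null is None:
        swaps_per_null = 2 * int(P.sum())

    def mpd_rows(mat: np.ndarray) -> np.ndarray:
        k = mat.sum(axis=1).astype(float)
        tot = ((mat @ Dm) * mat).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(k >= 2, tot / np.maximum(k * (k - 1), 1), np.nan)

    obs = mpd_rows(P.astype(float))
    null_mpd = np.empty((n_rand, P.shape[0]))
    for r in range(n_rand):
        null_mpd[r] = mpd_rows(independent_swap(P, swaps_per_null, rng).astype(float))
    null_mean = null_mpd.mean(axis=0)
    null_sd = null_mpd.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nri_vals = -(obs - null_mean) / null_sd
    flags = np.where(occupied, "ok", "low_richness").astype(object)
    flags[occupied & (null_sd <= 1e-12)] = "degenerate_null"
    ok = flags == "ok"
    centroids = community.grid.centroids()
    return pd.DataFrame(
        {
            "quadrat": np.arange(P.shape[0]),
            "cx": centroids[:, 0],
            "cy": centroids[:, 1],
            "scale": community.grid.s,
            "richness": P.sum(axis=1),
            "MPD_sample": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "NRI": np.where(ok, nri_vals, np.nan),
            "n_rand": n_rand,
            "flag": flags,
        }
    )
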