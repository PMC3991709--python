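"""Rao quadratic-entropy temporal turnover and its standardized effect size.

For one quadrat, turnover between census times A and B is

    RaoD = sum_i sum_j  pA_i * pB_j * d_ij

— the expected patristic distance between one stem drawn at time A and one
drawn at time B of the same quadrat (conspecific pairs contribute 0).  The
observed value is standardized against a null ensemble:

    ses.RaoD = (RaoD_obs - mean(RaoD_null)) / sd(RaoD_null)

with the null RaoD values computed per quadrat from replicate data sets of
the chosen null model (NM-I species-name shuffling, or NM-II demographic
simulation; see :mod:`phyloturn.nullmodels`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .census_io import CensusPair
from .community import community_matrix, gridify
from .nullmodels import NM2Sampler, NullModelConfig, nm1_permute
from .phylo import PatristicMatrix

FLAG_OK = "ok"
FLAG_EMPTY_A = "empty_at_A"
FLAG_EMPTY_B = "empty_at_B"
FLAG_DEGENERATE = "degenerate_null"


def rao_turnover(
    pA: np.ndarray, pB: np.ndarray, D: np.ndarray, normalized: bool = False
) -> float:
    """Expected phylogenetic distance between a time-A and a time-B stem.

    ``pA`` and ``pB`` are relative-abundance vectors over a shared species
    index; ``D`` is the aligned patristic matrix.  With ``normalized=True``
    the mean within-census Rao diversity is subtracted (a beta-diversity
    style variant for sensitivity analysis; the plain cross term is the
    default and the quantity used throughout the pipeline).
    """
    pA = np.asarray(pA, dtype=float)
    pB = np.asarray(pB, dtype=float)
    if pA.sum() == 0 or pB.sum() == 0:
        raise ValueError("empty community at one census: RaoD undefined")
    cross = float(pA @ D @ pB)
    if normalized:
        cross -= 0.5 * (float(pA @ D @ pA) + float(pB @ D @ pB))
    return cross


def ses(obs: float, nulls: np.ndarray) -> float:
    """Standardized effect size (obs - mean) / sd with the n-1 denominator.

    Returns NaN when the null ensemble is degenerate (sd = 0).
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size < 2 or not np.all(np.isfinite(nulls)):
        raise ValueError("need >= 2 finite null values")
    sd = nulls.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((obs - nulls.mean()) / sd)


def _rao_rows(PA_D: np.ndarray, PB: np.ndarray) -> np.ndarray:
    """Per-quadrat RaoD given PA @ D (precomputed) and PB, both (Q, S)."""
    return np.einsum("qs,qs->q", PA_D, PB)


def turnover_analysis(
    pair: CensusPair,
    D: PatristicMatrix,
    s: float,
    null_model: NullModelConfig,
    species_table: pd.DataFrame | None = None,
    n_rep: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-quadrat RaoD, null mean/sd and ses.RaoD at quadrat scale ``s``.

    Returns a DataFrame with one row per quadrat: quadrat id, centroid,
    RaoD_obs, null_mean, null_sd, ses_RaoD, n_null, flag.  Deterministic
    for a given ``seed`` (each replicate uses an independently derived
    substream).
    """
    n_rep = int(n_rep if n_rep is not None else null_model.n_rep)
    pool = pair.species_pool()
    Dm = D.reorder(pool).matrix
    grid, _ = gridify(np.empty(0), np.empty(0), pair.plot_dims, s)
    A = community_matrix(pair.census1, grid, pool, "census1")
    B = community_matrix(pair.census2, grid, pool, "census2")
    PA, PB = A.relative_abundance(), B.relative_abundance()
    occ_A = A.counts.sum(axis=1) > 0
    occ_B = B.counts.sum(axis=1) > 0
    PA_D = PA @ Dm
    rao_obs = _rao_rows(PA_D, PB)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_rngs = [np.random.default_rng(c) for c in ss.spawn(n_rep)]
    Q = grid.n_quadrats
    nulls = np.empty((n_rep, Q))
    if null_model.kind == "NM1":
        for r, rng in enumerate(child_rngs):
            perm = nm1_permute(len(pool), rng)
            Dp = Dm[np.ix_(perm, perm)]
            nulls[r] = _rao_rows(PA @ Dp, PB)
    else:
        if species_table is None:
            raise ValueError("NM-II requires a species table with growth forms")
        sampler = NM2Sampler(pair, species_table, null_model)
        pool_index = pd.Index(pool)
        for r, rng in enumerate(child_rngs):
            sim = sampler.replicate(rng)
            _, qid = gridify(sim.x, sim.y, pair.plot_dims, s)
            sp = pool_index.get_indexer(sim.species)
            counts = np.zeros((Q, len(pool)))
            keep = qid >= 0
            np.add.at(counts, (qid[keep], sp[keep]), 1.0)
            tot = counts.sum(axis=1, keepdims=True)
            PBr = np.divide(counts, np.maximum(tot, 1.0))
            nulls[r] = _rao_rows(PA_D, PBr)

    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ses_vals = (rao_obs - null_mean) / null_sd
    flags = np.full(Q, FLAG_OK, dtype=object)
    flags[~occ_B] = FLAG_EMPTY_B
    flags[~occ_A] = FLAG_EMPTY_A
    degenerate = occ_A & occ_B & (null_sd <= 1e-12)
    flags[degenerate] = FLAG_DEGENERATE
    ok = flags == FLAG_OK
    centroids = grid.centroids()
    return pd.DataFrame(
        {
            "quadrat": np.arange(Q),
            "cx": centroids[:, 0],
            "cy": centroids[:, 1],
            "scale": s,
            "RaoD_obs": np.where(occ_A & occ_B, rao_obs, np.nan),
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ses_RaoD": np.where(ok, ses_vals, np.nan),
            "n_null": n_rep,
            "flag": flags,
            "null_model": null_model.kind,
        }
    )
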