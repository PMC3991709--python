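"""Synthetic mapped-plot datasets with known demographic parameters.

Real repeat-census plot data are not redistributable, so every stage of the
pipeline is exercised on data generated here: a pure-birth phylogeny with
Brownian (or signal-free) traits; a first census with a lognormal species
abundance distribution, Thomas-process clustered stem positions and
lognormal DBH; and a second census produced by species- and size-specific
survival — optionally forced by habitat filtering (mortality rises with the
mismatch between a species' trait and a smooth environment field) or by
phylogenetic density dependence (mortality rises with the density of closely
related neighbors) — plus recruitment around surviving mature conspecifics
at exponential-kernel distances with species-specific dispersal scales.

A truth record retains every realized survival probability, death, parent
assignment and dispersal distance, so estimators can be checked against the
generating process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .census_io import CensusPair
from .nullmodels import DEFAULT_MATURE_DBH, size_class


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters; defaults give a desk-scale plot (minutes to
    analyze) with realistic structure: ~40 species, 200 m x 100 m,
    ~8,000 stems, ~15% five-year mortality."""

    n_species: int = 40
    plot_dims: tuple[float, float] = (200.0, 100.0)
    n_stems: int = 8000
    abundance_sdlog: float = 1.2          # lognormal SAD spread
    trait_model: str = "brownian"         # | "white"
    trait_sigma2: float = 1.0
    n_traits: int = 1                     # independent traits (filtering uses all)
    prop_tree: float = 0.7                # fraction of species with tree growth form
    dbh_meanlog: float = float(np.log(2.0))   # DBH = 1 + lognormal (cm)
    dbh_sdlog: float = 1.2
    cluster_size: float = 25.0            # mean stems per Thomas cluster
    cluster_sd: float = 8.0               # cluster spread (m)
    dispersal_meanlog: float = float(np.log(8.0))  # per-species kernel scale (m)
    dispersal_sdlog: float = 0.6
    survival_logit_mean: float = 2.0      # per-species baseline, logit scale
    survival_logit_sd: float = 0.5
    size_coef: float = 0.08               # logit survival increase per size class
    recruit_rate: float = 0.8             # expected recruits per surviving mature stem
    phi: float = 0.0                      # habitat-filtering strength
    delta: float = 0.0                    # phylogenetic density-dependence strength
    dd_radius: float = 10.0               # neighborhood radius for density dependence (m)
    env_field: str = "linear"             # | "patches"
    patch_scale: float = 40.0             # correlation length of patchy habitat (m)
    prefilter_phi: float = 0.0            # habitat sorting already present at census 1


def species_codes(n: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(n)]


def simulate_phylogeny_traits(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Pure-birth tree (unit root depth) and one trait per species.

    ``brownian`` traits evolve along branches with rate ``trait_sigma2``;
    ``white`` traits are i.i.d. normal at the tips (no signal).
    """
    if config.n_species < 3:
        raise ValueError("need at least 3 species")
    tree = _pure_birth(config.n_species, rng)
    labels = species_codes(config.n_species)
    for leaf, lb in zip(tree.leaf_node_iter(), labels):
        leaf.taxon.label = lb
    sigma = np.sqrt(config.trait_sigma2)
    k = config.n_traits
    values: dict[str, np.ndarray] = {}
    state = {id(tree.seed_node): np.zeros(k)}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            step = sigma * np.sqrt(node.edge.length) * rng.standard_normal(k)
            state[id(node)] = state[id(node.parent_node)] + step
        if node.is_leaf():
            values[node.taxon.label] = state[id(node)]
    if config.trait_model == "white":
        values = {lb: sigma * rng.standard_normal(k) for lb in labels}
    elif config.trait_model != "brownian":
        raise ValueError(f"unknown trait model {config.trait_model!r}")
    cols = {"trait" if j == 0 else f"trait{j + 1}":
            [float(values[lb][j]) for lb in labels] for j in range(k)}
    traits = pd.DataFrame({"species": labels, **cols})
    return tree, traits.set_index("species")


def _pure_birth(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Yule tree grown by uniform lineage splitting; depth rescaled to 1."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.birth = 0.0
    tips = [root]
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / len(tips))
        parent = tips.pop(int(rng.integers(len(tips))))
        parent.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth = t
            parent.add_child(child)
            tips.append(child)
    t_end = t + rng.exponential(1.0 / len(tips))
    for i, tip in enumerate(tips):
        tip.taxon = taxa[i]
        tip.split_time = t_end
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.split_time - node.birth
    # rescale so the root (first split) is at depth 1
    depth = max(t_end - root.split_time, 1e-12)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree


def trait_matrix(traits: pd.DataFrame) -> np.ndarray:
    """(n_species, n_traits) array from a trait table."""
    cols = [c for c in traits.columns if c.startswith("trait")]
    return traits[cols].to_numpy(dtype=float)


def environment_field(config: SyntheticConfig, traits: pd.DataFrame,
                      rng: np.random.Generator | None = None):
    """Map (x, y) -> environmental optimum vector on the trait scale.

    ``linear``: each trait gets a smooth monotone gradient along its own
    plot direction (x, y, the diagonals, ...).  ``patches``: each trait gets
    a random smooth field (sum of Gaussian bumps with correlation length
    ``patch_scale``) — habitat mosaic rather than a single gradient.  Either
    way values are mapped through the trait's empirical quantiles so every
    position has species whose traits match it.  Returns
    ``env(x, y) -> (n_points, n_traits)``.
    """
    from scipy.stats import norm as _norm

    T = trait_matrix(traits)
    width, height = config.plot_dims
    k = T.shape[1]
    if config.env_field == "linear":
        dirs = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, -1.0]])
        dirs = np.vstack([dirs] * (1 + k // 4))[:k]

        def env(x, y):
            pts = np.column_stack([np.asarray(x, float).ravel() / width,
                                   np.asarray(y, float).ravel() / height])
            out = np.empty((len(pts), k))
            for j in range(k):
                proj = pts @ dirs[j]
                lo, hi = (0.0, 1.0) if dirs[j].min() >= 0 else (-1.0, 1.0)
                frac = (proj - lo) / (hi - lo)
                srt = np.sort(T[:, j])
                out[:, j] = np.interp(frac, np.linspace(0, 1, len(srt)), srt)
            return out
    elif config.env_field == "patches":
        rng = rng if rng is not None else np.random.default_rng(0)
        sd = config.patch_scale
        n_b = max(6, int(round(4 * width * height / (np.pi * sd**2))))
        ctrs = rng.random((k, n_b, 2)) * np.array([width, height])
        amps = rng.standard_normal((k, n_b))
        # evaluate each bump field once on a lattice (resolution sd/4),
        # standardize, quantile-map, then look points up by bilinear
        # interpolation — smooth at the patch scale and O(1) per point
        res = max(2.0, sd / 4.0)
        gxv = np.arange(0, width + res, res)
        gyv = np.arange(0, height + res, res)
        gx, gy = np.meshgrid(gxv, gyv)
        ref = np.column_stack([gx.ravel(), gy.ravel()])
        F = np.empty((k, len(gyv), len(gxv)))
        for j in range(k):
            d2 = ((ref[:, None, :] - ctrs[j][None]) ** 2).sum(-1)
            g = np.exp(-d2 / (2 * sd**2)) @ amps[j]
            z = (g - g.mean()) / (g.std() or 1.0)
            srt = np.sort(T[:, j])
            F[j] = np.interp(_norm.cdf(z), np.linspace(0, 1, len(srt)),
                             srt).reshape(len(gyv), len(gxv))

        def env(x, y):
            xf = np.clip(np.asarray(x, float).ravel() / res, 0, len(gxv) - 1.001)
            yf = np.clip(np.asarray(y, float).ravel() / res, 0, len(gyv) - 1.001)
            x0 = xf.astype(np.int64)
            y0 = yf.astype(np.int64)
            tx = (xf - x0)[None, :]
            ty = (yf - y0)[None, :]
            v = (F[:, y0, x0] * (1 - tx) * (1 - ty) + F[:, y0, x0 + 1] * tx * (1 - ty)
                 + F[:, y0 + 1, x0] * (1 - tx) * ty + F[:, y0 + 1, x0 + 1] * tx * ty)
            return v.T
    else:
        raise ValueError(f"unknown env field {config.env_field!r}")
    return env


def trait_mismatch(T_stems: np.ndarray, env_vals: np.ndarray) -> np.ndarray:
    """Mean absolute trait-environment deviation per stem."""
    return np.abs(np.atleast_2d(T_stems) - env_vals).mean(axis=1)


@dataclass
class TruthRecord:
    stems: pd.DataFrame      # census-1 stems: survival prob, died flag
    recruits: pd.DataFrame   # recruit tag, parent tag, dispersal distance
    params: dict = field(default_factory=dict)


def simulate_census_pair(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[CensusPair, pd.DataFrame, TruthRecord]:
    """Generate the two-census dataset.

    Returns ``(pair, species_table, truth)`` where the species table carries
    growth forms and the trait, and the truth record carries the realized
    survival probabilities, deaths, parent assignments and dispersal
    distances.
    """
    width, height = config.plot_dims
    labels = list(traits.index)
    n_sp = len(labels)
    T = trait_matrix(traits)
    growth_form = np.where(rng.random(n_sp) < config.prop_tree, "tree", "shrub")
    sp_table = pd.concat(
        [pd.DataFrame({"species": labels, "growth_form": growth_form}).set_index("species"),
         traits], axis=1)
    env = environment_field(config, traits, rng)

    # --- census 1: SAD, clustered positions, sizes -----------------------
    weights = rng.lognormal(0.0, config.abundance_sdlog, n_sp)
    n_k = rng.multinomial(config.n_stems, weights / weights.sum())
    dispersal = rng.lognormal(config.dispersal_meanlog, config.dispersal_sdlog, n_sp)
    baseline_logit = rng.normal(config.survival_logit_mean,
                                config.survival_logit_sd, n_sp)
    sp_idx = np.repeat(np.arange(n_sp), n_k)
    xs = np.empty(len(sp_idx))
    ys = np.empty(len(sp_idx))
    pos = 0
    for k in range(n_sp):
        nk = n_k[k]
        if nk == 0:
            continue
        n_par = max(1, int(round(nk / config.cluster_size)))
        centers = _cluster_centers(n_par, k, T, env, config, rng)
        assign = rng.integers(0, n_par, nk)
        pts = centers[assign] + rng.normal(0, config.cluster_sd, (nk, 2))
        pts[:, 0] %= width   # torus wrap keeps intensity uniform
        pts[:, 1] %= height
        xs[pos:pos + nk], ys[pos:pos + nk] = pts[:, 0], pts[:, 1]
        pos += nk
    dbh = 1.0 + rng.lognormal(config.dbh_meanlog, config.dbh_sdlog, len(sp_idx))
    tags = np.array([f"s{i:06d}" for i in range(len(sp_idx))])
    census1 = pd.DataFrame({"tag": tags, "species": np.array(labels)[sp_idx],
                            "x": xs, "y": ys, "dbh": dbh, "status": "alive"})

    # --- mortality -------------------------------------------------------
    cls = size_class(dbh)
    logit = baseline_logit[sp_idx] + config.size_coef * cls
    p_surv = 1.0 / (1.0 + np.exp(-logit))
    if config.phi > 0:
        mism = trait_mismatch(T[sp_idx], env(xs, ys))
        # centered so phi steers who dies more than how many die
        p_surv = np.minimum(p_surv * np.exp(-config.phi * (mism - mism.mean())), 1.0)
    if config.delta > 0:
        z = _related_density(tree, labels, sp_idx, xs, ys, config.dd_radius)
        p_surv = np.minimum(p_surv * np.exp(-config.delta * z), 1.0)
    survives = rng.random(len(sp_idx)) < p_surv
    if survives.sum() == 0:
        raise ValueError("parameterization killed every stem; lower phi/delta")

    # --- recruitment around surviving mature conspecifics ---------------
    thresh = pd.Series(growth_form, index=labels).map(DEFAULT_MATURE_DBH).to_numpy()
    mature_surv = survives & (dbh >= thresh[sp_idx])
    rec_sp_l, rec_x_l, rec_y_l, rec_parent_l, rec_dist_l = [], [], [], [], []
    for k in np.flatnonzero(np.bincount(sp_idx[mature_surv], minlength=n_sp)):
        pidx = np.flatnonzero(mature_surv & (sp_idx == k))
        n_rec = rng.poisson(config.recruit_rate * len(pidx))
        if n_rec == 0:
            continue
        parent = pidx[rng.integers(0, len(pidx), n_rec)]
        cx = np.empty(n_rec)
        cy = np.empty(n_rec)
        dist = np.empty(n_rec)
        pending = np.arange(n_rec)
        for _attempt in range(50):
            d = rng.exponential(dispersal[k], len(pending))
            theta = rng.random(len(pending)) * 2 * np.pi
            px = xs[parent[pending]] + d * np.cos(theta)
            py = ys[parent[pending]] + d * np.sin(theta)
            ok = (px >= 0) & (px <= width) & (py >= 0) & (py <= height)
            cx[pending] = px
            cy[pending] = py
            dist[pending] = d
            pending = pending[~ok]
            if len(pending) == 0:
                break
        cx[pending] = np.clip(cx[pending], 0, width)
        cy[pending] = np.clip(cy[pending], 0, height)
        rec_sp_l.append(np.full(n_rec, k))
        rec_x_l.append(cx)
        rec_y_l.append(cy)
        rec_parent_l.append(parent)
        rec_dist_l.append(dist)
    rec_sp = (np.concatenate(rec_sp_l).astype(np.int64)
              if rec_sp_l else np.array([], dtype=np.int64))
    rec_x = np.concatenate(rec_x_l) if rec_x_l else np.array([])
    rec_y = np.concatenate(rec_y_l) if rec_y_l else np.array([])
    rec_parent = (np.concatenate(rec_parent_l).astype(np.int64)
                  if rec_parent_l else np.array([], dtype=np.int64))
    rec_dist = np.concatenate(rec_dist_l) if rec_dist_l else np.array([])
    rec_tags = np.array([f"r{i:06d}" for i in range(len(rec_sp))])
    rec_dbh = 1.0 + rng.exponential(0.35, len(rec_sp))

    surv_rows = pd.DataFrame({
        "tag": tags[survives], "species": np.array(labels)[sp_idx[survives]],
        "x": xs[survives], "y": ys[survives],
        "dbh": dbh[survives] + np.abs(rng.normal(0.2, 0.2, int(survives.sum()))),
        "status": "alive"})
    dead_rows = pd.DataFrame({
        "tag": tags[~survives], "species": np.array(labels)[sp_idx[~survives]],
        "x": xs[~survives], "y": ys[~survives], "dbh": np.nan, "status": "dead"})
    rec_rows = pd.DataFrame({
        "tag": rec_tags, "species": np.array(labels)[rec_sp],
        "x": rec_x, "y": rec_y, "dbh": rec_dbh, "status": "alive"})
    census2 = pd.concat([surv_rows, dead_rows, rec_rows], ignore_index=True)
    if (census2.status == "alive").sum() == 0:
        raise ValueError("empty census 2; adjust demographic parameters")

    pair = CensusPair(census1=census1, census2=census2,
                      plot_dims=config.plot_dims)
    truth = TruthRecord(
        stems=pd.DataFrame({"tag": tags, "species": np.array(labels)[sp_idx],
                            "p_survival": p_surv, "died": ~survives,
                            "size_class": cls}),
        recruits=pd.DataFrame({"tag": rec_tags,
                               "species": np.array(labels)[rec_sp],
                               "parent_tag": tags[rec_parent]
                               if len(rec_parent) else np.array([], dtype=str),
                               "distance": rec_dist}),
        params={"baseline_logit": baseline_logit, "dispersal": dispersal,
                "size_coef": config.size_coef},
    )
    return pair, sp_table, truth


def _cluster_centers(n_par, k, T, env, config, rng):
    """Thomas cluster centers for species k; with habitat sorting
    (``prefilter_phi`` > 0) centers are placed by rejection sampling with
    acceptance exp(-prefilter_phi * mismatch), so species ranges already
    track the environment at census 1."""
    width, height = config.plot_dims
    if config.prefilter_phi <= 0:
        return np.column_stack([rng.random(n_par) * width,
                                rng.random(n_par) * height])
    out = np.empty((n_par, 2))
    filled = 0
    for _ in range(200):
        cand = np.column_stack([rng.random(4 * n_par) * width,
                                rng.random(4 * n_par) * height])
        m = trait_mismatch(np.broadcast_to(T[k], (len(cand), T.shape[1])),
                           env(cand[:, 0], cand[:, 1]))
        ok = cand[rng.random(len(cand)) < np.exp(-config.prefilter_phi * m)]
        take = min(len(ok), n_par - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
        if filled == n_par:
            return out
    out[filled:] = np.column_stack([rng.random(n_par - filled) * width,
                                    rng.random(n_par - filled) * height])
    return out


def _related_density(tree, labels, sp_idx, xs, ys, radius):
    """Per stem: neighbor count within ``radius`` weighted by phylogenetic
    proximity 1 - d_pq/max(d), standardized (mean 0, sd 1) so ``delta`` is
    a per-standard-deviation log-hazard."""
    from .phylo import patristic_matrix

    D = patristic_matrix(tree).reorder(list(labels)).matrix
    prox = 1.0 - D / D.max()
    kd = cKDTree(np.column_stack([xs, ys]))
    pairs = kd.query_pairs(radius, output_type="ndarray")
    dens = np.zeros(len(xs))
    if len(pairs):
        w = prox[sp_idx[pairs[:, 0]], sp_idx[pairs[:, 1]]]
        np.add.at(dens, pairs[:, 0], w)
        np.add.at(dens, pairs[:, 1], w)
    sd = dens.std() or 1.0
    return (dens - dens.mean()) / sd


def nm2_generated_pair(
    pair: CensusPair,
    species_table: pd.DataFrame,
    config,
    rng: np.random.Generator,
) -> CensusPair:
    """Replace census 2 with one draw from the NM-II generative process.

    Used for self-consistency checks: data whose second census *is* an
    NM-II replicate should, when analyzed under NM-II, give ses.RaoD values
    close to a standard normal across quadrats.
    """
    from .nullmodels import NM2Sampler

    sim = NM2Sampler(pair, species_table, config).replicate(rng)
    return CensusPair(census1=pair.census1, census2=sim.to_dataframe(),
                      plot_dims=pair.plot_dims, dates=pair.dates)


def scenario_config(kind: str, seed_free: bool = False) -> SyntheticConfig:
    """Preset study conditions.

    ``neutral``: no filtering, no density dependence.
    ``filtering``: strong habitat filtering on Brownian traits over a smooth
    gradient, census 1 pre-sorted by habitat (species already where their
    traits fit), so quadrats of distantly related species turn over most.
    ``density``: strong phylogenetic density dependence, so quadrats of
    closely related species turn over most.
    """
    base = SyntheticConfig()
    if kind == "neutral":
        return base
    if kind == "filtering":
        # mortality filtering on a quadrat-scale habitat mosaic, acting on a
        # four-trait Brownian vector (a trait vector tracks the phylogeny
        # much more tightly than any single Brownian trait), with species
        # ranges already habitat-sorted at census 1; the larger plot gives
        # the spatial regression enough quadrats at the 20 m scale
        return replace(base, n_species=60, plot_dims=(500.0, 250.0),
                       n_stems=50000, n_traits=12, trait_model="brownian",
                       phi=6.0, prefilter_phi=3.0,
                       env_field="patches", patch_scale=20.0)
    if kind == "density":
        # mortality rises with the local density of close relatives; the
        # larger plot gives the 10 m grid enough quadrats for a stable fit
        return replace(base, delta=1.5, phi=0.0,
                       plot_dims=(300.0, 150.0), n_stems=18000)
    raise ValueError(f"unknown scenario {kind!r}")
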