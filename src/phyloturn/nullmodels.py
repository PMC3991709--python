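"""Null models for temporal phylogenetic turnover.

Two nulls are provided:

* **NM-I** — species-name shuffling: one uniform permutation of species
  identities per replicate, applied to both censuses, so abundances,
  richness, occupancy and species turnover through time are preserved while
  phylogenetic identities are scrambled.

* **NM-II** — a demographic null.  Mortality: census-1 stems are grouped by
  species and DBH size class; within each (species, class) cell the observed
  number of deaths is reassigned uniformly at random among the cell's stems
  (``exact_count`` mode; a ``bernoulli`` mode draws deaths independently at
  the cell's observed rate instead).  Recruitment: each observed recruit's
  distance ``Dp`` to its nearest conspecific mature stem (within 50 m) is
  preserved — a parent is redrawn uniformly from all conspecific mature
  census-1 stems and the recruit is placed at a uniform angle on the circle
  of radius ``Dp`` around it; recruits with no mature conspecific within
  50 m are placed uniformly in the plot.  Species identities and per-species
  totals are untouched: only the spatial arrangement of deaths and recruits
  varies between replicates.

Mature means DBH >= 15 cm for trees and >= 5 cm for shrubs at census 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .census_io import CensusPair, classify_demographics

# Size-class bin edges in cm: 1-cm classes up to 20 cm, then 20-25, 25-35,
# 35-45, 45-55 and >=55 cm.
DEFAULT_SIZE_CLASS_EDGES = tuple(float(e) for e in range(1, 21)) + (25.0, 35.0, 45.0, 55.0, np.inf)

DEFAULT_MATURE_DBH = {"tree": 15.0, "shrub": 5.0}


@dataclass(frozen=True)
class NullModelConfig:
    kind: str = "NM2"  # "NM1" | "NM2"
    n_rep: int = 499
    mature_dbh: dict = field(default_factory=lambda: dict(DEFAULT_MATURE_DBH))
    parent_radius: float = 50.0
    size_class_edges: tuple = DEFAULT_SIZE_CLASS_EDGES
    mortality_mode: str = "exact_count"  # | "bernoulli"
    placement: str = "circle"  # | "disk" (uniform inside the disk)
    max_placement_retries: int = 100

    def __post_init__(self) -> None:
        if self.kind not in ("NM1", "NM2"):
            raise ValueError(f"unknown null model kind {self.kind!r}")
        edges = np.asarray(self.size_class_edges)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("size class edges must be strictly increasing")


def size_class(dbh: np.ndarray, edges=DEFAULT_SIZE_CLASS_EDGES) -> np.ndarray:
    """Bin DBH (cm) into size classes; class k covers [edges[k], edges[k+1])."""
    dbh = np.asarray(dbh, dtype=float)
    cls = np.searchsorted(np.asarray(edges), dbh, side="right") - 1
    if np.any(cls < 0):
        raise ValueError("DBH below the census threshold (1 cm)")
    return np.minimum(cls, len(edges) - 2)


def nm1_permute(n_species: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform random permutation of species identities."""
    return rng.permutation(n_species)


def estimate_survival_table(
    pair: CensusPair, edges=DEFAULT_SIZE_CLASS_EDGES
) -> pd.DataFrame:
    """Survival rate per (species, size class) from the observed interval.

    Returns a DataFrame indexed by (species, size_class) with columns
    ``n_alive_c1, n_surviving, survival_rate``; only occupied cells appear.
    Size class is taken from census-1 DBH.
    """
    demo = classify_demographics(pair)
    c1 = pair.census1.set_index("tag")
    alive1 = c1.loc[c1.status == "alive"]
    cls = size_class(alive1["dbh"].to_numpy(), edges)
    survived = alive1.index.isin(demo.survivors)
    tab = (
        pd.DataFrame({"species": alive1["species"].to_numpy(), "size_class": cls,
                      "survived": survived})
        .groupby(["species", "size_class"])
        .agg(n_alive_c1=("survived", "size"), n_surviving=("survived", "sum"))
    )
    tab["survival_rate"] = tab["n_surviving"] / tab["n_alive_c1"]
    return tab


def mature_mask(
    census1: pd.DataFrame, species_table: pd.DataFrame, mature_dbh=None
) -> np.ndarray:
    """Boolean mask over census-1 rows: alive and at/above the growth-form
    maturity threshold (tree 15 cm, shrub 5 cm by default)."""
    mature_dbh = mature_dbh or DEFAULT_MATURE_DBH
    if "growth_form" not in species_table.columns:
        raise ValueError("species table must have a growth_form column for NM-II")
    forms = census1["species"].map(species_table["growth_form"])
    if forms.isna().any():
        missing = sorted(set(census1.loc[forms.isna(), "species"]))
        raise ValueError(f"species without growth form: {missing[:5]}")
    thresh = forms.map(mature_dbh).to_numpy(dtype=float)
    return (census1["status"].to_numpy() == "alive") & (
        census1["dbh"].to_numpy(dtype=float) >= thresh
    )


def measure_dispersal(
    pair: CensusPair,
    species_table: pd.DataFrame,
    config: NullModelConfig = NullModelConfig(),
) -> pd.DataFrame:
    """Per recruit: distance Dp to the nearest conspecific mature census-1
    stem within ``config.parent_radius`` (NaN when none lies within it).

    Returns a DataFrame with columns ``tag, species, x, y, dbh, Dp``.
    """
    demo = classify_demographics(pair)
    c2 = pair.census2.set_index("tag")
    rec = c2.loc[demo.recruits].reset_index()
    c1 = pair.census1
    mat = c1.loc[mature_mask(c1, species_table, config.mature_dbh)]
    dp = np.full(len(rec), np.nan)
    for sp, grp in rec.groupby("species"):
        parents = mat.loc[mat["species"] == sp, ["x", "y"]].to_numpy(dtype=float)
        if len(parents) == 0:
            continue
        tree = cKDTree(parents)
        d, _ = tree.query(grp[["x", "y"]].to_numpy(dtype=float), k=1)
        d = np.atleast_1d(d)
        d[d > config.parent_radius] = np.nan
        dp[rec.index.get_indexer(grp.index)] = d
    out = rec[["tag", "species", "x", "y", "dbh"]].copy()
    out["Dp"] = dp
    return out


@dataclass
class SimulatedCensus:
    """One NM-II replicate of census 2: alive stems only, as flat arrays.

    Survivors keep their census-1 tags; recruits keep their observed tags,
    so a replicate can stand in for census 2 in a :class:`CensusPair`.
    """

    species: np.ndarray  # string codes
    x: np.ndarray
    y: np.ndarray
    dbh: np.ndarray
    tags: np.ndarray
    log: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tag": self.tags, "species": self.species,
             "x": self.x, "y": self.y, "dbh": self.dbh, "status": "alive"}
        )


class NM2Sampler:
    """Precomputed state for drawing NM-II replicate censuses efficiently.

    Everything that depends only on the observed pair — size classes,
    per-cell death counts, per-species mature stem coordinates, recruit Dp
    records — is computed once; :meth:`replicate` then draws one simulated
    census 2 using only vectorized random operations.
    """

    def __init__(
        self,
        pair: CensusPair,
        species_table: pd.DataFrame,
        config: NullModelConfig = NullModelConfig(),
        survival: pd.DataFrame | None = None,
        recruits: pd.DataFrame | None = None,
    ):
        self.config = config
        self.plot_dims = pair.plot_dims
        demo = classify_demographics(pair)
        c1 = pair.census1
        alive1 = c1.loc[c1.status == "alive"]
        self._tags = alive1["tag"].to_numpy()
        self._sp = alive1["species"].to_numpy()
        self._x = alive1["x"].to_numpy(dtype=float)
        self._y = alive1["y"].to_numpy(dtype=float)
        self._dbh = alive1["dbh"].to_numpy(dtype=float)
        cls = size_class(self._dbh, config.size_class_edges)
        # cell = (species, size class); stable integer coding
        sp_codes, self._sp_levels = pd.factorize(alive1["species"], sort=True)
        n_cls = len(config.size_class_edges) - 1
        cell = sp_codes * n_cls + cls
        self._order = np.argsort(cell, kind="stable")
        cell_sorted = cell[self._order]
        self._cell_sorted = cell_sorted
        # within-cell positional rank of each sorted stem
        starts = np.flatnonzero(np.r_[True, np.diff(cell_sorted) > 0])
        sizes = np.diff(np.r_[starts, len(cell_sorted)])
        self._rank_in_cell = np.arange(len(cell_sorted)) - np.repeat(starts, sizes)
        died = ~alive1["tag"].isin(demo.survivors).to_numpy()
        deaths_per_cell = np.bincount(cell_sorted[died[self._order]],
                                      minlength=int(cell_sorted.max()) + 1 if len(cell_sorted) else 0)
        self._deaths_in_cell_of = deaths_per_cell[cell_sorted]
        self._death_rate_of = self._deaths_in_cell_of / sizes.repeat(sizes)
        # mature stems per species (CSR layout over sorted species codes)
        mat = mature_mask(c1, species_table, config.mature_dbh)
        mat_alive = mat[c1.status.to_numpy() == "alive"]
        m_sp = sp_codes[mat_alive]
        m_order = np.argsort(m_sp, kind="stable")
        self._mat_xy = np.column_stack([self._x[mat_alive][m_order],
                                        self._y[mat_alive][m_order]])
        self._mat_counts = np.bincount(m_sp, minlength=len(self._sp_levels))
        self._mat_offsets = np.r_[0, np.cumsum(self._mat_counts)]
        # recruits
        rec = recruits if recruits is not None else measure_dispersal(pair, species_table, config)
        self._rec = rec
        has_dp = np.isfinite(rec["Dp"].to_numpy(dtype=float))
        self._rec_dp = rec.loc[has_dp]
        self._rec_free = rec.loc[~has_dp]
        self._rec_dp_sp = pd.Index(self._sp_levels).get_indexer(self._rec_dp["species"])
        if np.any(self._rec_dp_sp < 0) or np.any(self._mat_counts[self._rec_dp_sp] == 0):
            raise ValueError("recruit with Dp but no conspecific mature stem")
        self.survival = survival if survival is not None else estimate_survival_table(
            pair, config.size_class_edges)

    def _place_on_circles(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, dict]:
        cfg = self.config
        width, height = self.plot_dims
        sp = self._rec_dp_sp
        dp = self._rec_dp["Dp"].to_numpy(dtype=float)
        n = len(sp)
        x = np.empty(n)
        y = np.empty(n)
        todo = np.arange(n)
        log = {"parent_redraws": 0, "uniform_fallbacks": 0}
        for parent_round in range(2):
            if len(todo) == 0:
                break
            u = rng.random(len(todo))
            pidx = self._mat_offsets[sp[todo]] + np.floor(
                u * self._mat_counts[sp[todo]]).astype(np.int64)
            px, py = self._mat_xy[pidx, 0], self._mat_xy[pidx, 1]
            r = dp[todo]
            if cfg.placement == "disk":
                r = r * np.sqrt(rng.random(len(todo)))
            pending = np.arange(len(todo))
            for _ in range(cfg.max_placement_retries):
                theta = rng.random(len(pending)) * 2 * np.pi
                cx = px[pending] + r[pending] * np.cos(theta)
                cy = py[pending] + r[pending] * np.sin(theta)
                ok = (cx >= 0) & (cx <= width) & (cy >= 0) & (cy <= height)
                x[todo[pending[ok]]] = cx[ok]
                y[todo[pending[ok]]] = cy[ok]
                pending = pending[~ok]
                if len(pending) == 0:
                    break
            todo = todo[pending]
            if parent_round == 0:
                log["parent_redraws"] = len(todo)
        if len(todo):
            log["uniform_fallbacks"] = len(todo)
            x[todo] = rng.random(len(todo)) * width
            y[todo] = rng.random(len(todo)) * height
        return x, y, log

    def replicate(self, rng: np.random.Generator) -> SimulatedCensus:
        """Draw one simulated census 2 (survivor relocation of mortality +
        dispersal-preserving recruit placement)."""
        cfg = self.config
        width, height = self.plot_dims
        if cfg.mortality_mode == "exact_count":
            keys = rng.random(len(self._cell_sorted))
            order2 = np.lexsort((keys, self._cell_sorted))
            # after shuffling within cells, the first d_cell stems die
            die_sorted = np.empty(len(order2), dtype=bool)
            die_sorted[order2] = self._rank_in_cell < self._deaths_in_cell_of
            survives_sorted = ~die_sorted
        elif cfg.mortality_mode == "bernoulli":
            survives_sorted = rng.random(len(self._cell_sorted)) >= self._death_rate_of
        else:  # pragma: no cover
            raise ValueError(f"unknown mortality mode {cfg.mortality_mode!r}")
        surv_idx = self._order[survives_sorted]
        rx, ry, log = self._place_on_circles(rng)
        fx = rng.random(len(self._rec_free)) * width
        fy = rng.random(len(self._rec_free)) * height
        return SimulatedCensus(
            species=np.concatenate([self._sp[surv_idx],
                                    self._rec_dp["species"].to_numpy(),
                                    self._rec_free["species"].to_numpy()]),
            x=np.concatenate([self._x[surv_idx], rx, fx]),
            y=np.concatenate([self._y[surv_idx], ry, fy]),
            dbh=np.concatenate([self._dbh[surv_idx],
                                self._rec_dp["dbh"].to_numpy(dtype=float),
                                self._rec_free["dbh"].to_numpy(dtype=float)]),
            tags=np.concatenate([self._tags[surv_idx],
                                 self._rec_dp["tag"].to_numpy(),
                                 self._rec_free["tag"].to_numpy()]),
            log=log,
        )


def nm2_replicate(
    pair: CensusPair,
    species_table: pd.DataFrame,
    config: NullModelConfig,
    rng: np.random.Generator,
    survival: pd.DataFrame | None = None,
    recruits: pd.DataFrame | None = None,
) -> SimulatedCensus:
    """One NM-II replicate census 2 (convenience wrapper over NM2Sampler)."""
    return NM2Sampler(pair, species_table, config, survival, recruits).replicate(rng)
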