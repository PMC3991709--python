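"""Orchestrated per-scale analysis: gridding -> NRI -> turnover -> SAR -> varpart.

:func:`analyze_scale` runs the full chain for one quadrat scale and null
model on in-memory objects; :func:`run_pipeline` drives it across scales and
null models from a :class:`RunConfig`, writing the documented CSVs plus a
manifest that records seeds and configuration, so a run is reproducible
end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .census_io import CensusPair, classify_demographics
from .community import community_matrix, gridify
from .nullmodels import NullModelConfig, measure_dispersal
from .phylo import PatristicMatrix
from .spatial import SpatialError, lattice_weights, morans_i, sar_error_fit
from .structure import nri
from .turnover import FLAG_OK, turnover_analysis
from .varpart import detrend_poly3, forward_select, pcnm_basis, variation_partition

log = logging.getLogger("phyloturn")


@dataclass
class ScaleResult:
    scale: float
    null_model: str
    turnover: pd.DataFrame
    nri: pd.DataFrame
    joined: pd.DataFrame
    sar: object | None
    ols_moran: object | None
    sar_moran: object | None
    varpart: object | None

    def sar_summary(self) -> dict:
        out = {"scale": self.scale, "null_model": self.null_model,
               "n": len(self.joined)}
        if self.sar is not None:
            out.update(slope=self.sar.params[1], slope_se=self.sar.bse[1],
                       slope_z=self.sar.zvalues[1], slope_p=self.sar.pvalues[1],
                       lam=self.sar.lam, loglik=self.sar.loglik)
        if self.ols_moran is not None:
            out.update(ols_resid_moran_I=self.ols_moran.I,
                       ols_resid_moran_p=self.ols_moran.p)
        if self.sar_moran is not None:
            out.update(sar_resid_moran_I=self.sar_moran.I,
                       sar_resid_moran_p=self.sar_moran.p)
        return out


def analyze_scale(
    pair: CensusPair,
    D: PatristicMatrix,
    s: float,
    null_model: NullModelConfig,
    species_table: pd.DataFrame | None = None,
    n_rep: int | None = None,
    nri_n_rand: int = 499,
    moran_n_perm: int = 999,
    varpart_n_perm: int = 499,
    seed: int | None = None,
    do_varpart: bool = True,
    nri_census: str = "census1",
) -> ScaleResult:
    """Full analysis chain at one quadrat scale.

    NRI is computed on census 1 by default (the phylogenetic similarity
    preceding the turnover interval).  Quadrats flagged by either the
    turnover or the NRI stage are dropped listwise before the spatial
    regression and variation partitioning.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(4)
    turn = turnover_analysis(pair, D, s, null_model, species_table=species_table,
                             n_rep=n_rep, seed=seeds[0])
    pool = pair.species_pool()
    grid, _ = gridify(np.empty(0), np.empty(0), pair.plot_dims, s)
    if nri_census == "pooled":
        from dataclasses import replace as _dc_replace
        A1 = community_matrix(pair.census1, grid, pool, "census1")
        A2 = community_matrix(pair.census2, grid, pool, "census2")
        A = _dc_replace(A1, counts=A1.counts + A2.counts, census_label="pooled")
    else:
        census = pair.census1 if nri_census == "census1" else pair.census2
        A = community_matrix(census, grid, pool, nri_census)
    nri_df = nri(A, D.reorder(pool), n_rand=nri_n_rand,
                 rng=np.random.default_rng(seeds[1]))
    joined = turn.merge(
        nri_df[["quadrat", "richness", "MPD_sample", "NRI",
                "flag"]].rename(columns={"flag": "nri_flag"}),
        on="quadrat")
    valid = (joined["flag"] == FLAG_OK) & (joined["nri_flag"] == "ok")
    joined = joined.assign(valid=valid)
    sar = ols_moran = sar_moran = vp = None
    sub = joined.loc[valid]
    if valid.sum() >= 12:
        mask = np.zeros(grid.n_quadrats, dtype=bool)
        mask[sub["quadrat"].to_numpy()] = True
        try:
            w = lattice_weights(grid, include=mask)
            y = sub["ses_RaoD"].to_numpy()
            X = np.column_stack([np.ones(len(sub)), sub["NRI"].to_numpy()])
            sar = sar_error_fit(y, X, w, names=["intercept", "NRI"])
            rng_m = np.random.default_rng(seeds[2])
            beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
            keep = w.nonisolated()
            ols_moran = morans_i((y - X @ beta_ols)[keep], w.subset(keep),
                                 n_perm=moran_n_perm, rng=rng_m)
            sar_moran = morans_i(sar.resid, w.subset(keep),
                                 n_perm=moran_n_perm, rng=rng_m)
        except SpatialError as e:
            log.warning("scale %s: spatial stage skipped (%s)", s, e)
        if do_varpart:
            cents = sub[["cx", "cy"]].to_numpy()
            y_det = detrend_poly3(sub["ses_RaoD"].to_numpy(), cents)
            basis = pcnm_basis(cents, s)
            sel = forward_select(y_det, basis, n_perm=varpart_n_perm,
                                 rng=np.random.default_rng(seeds[3]))
            vp = variation_partition(y_det, sub["NRI"].to_numpy(),
                                     basis.vectors[:, sel] if sel else None,
                                     selected_axes=tuple(sel))
    else:
        log.warning("scale %s: only %d valid quadrats; spatial stages skipped",
                    s, int(valid.sum()))
    return ScaleResult(scale=s, null_model=null_model.kind, turnover=turn,
                       nri=nri_df, joined=joined, sar=sar, ols_moran=ols_moran,
                       sar_moran=sar_moran, varpart=vp)


@dataclass
class RunConfig:
    census1: str = ""
    census2: str = ""
    tree: str = ""
    species_table: str = ""
    out_dir: str = "phyloturn_out"
    plot_dims: tuple[float, float] = (200.0, 100.0)
    dates: tuple[str, str] = ("t1", "t2")
    scales: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0)
    null_models: tuple[str, ...] = ("NM1", "NM2")
    n_rep: int = 499
    nri_n_rand: int = 499
    moran_n_perm: int = 999
    varpart_n_perm: int = 499
    seed: int = 0
    prune_missing_species: bool = False   # drop stems absent from the phylogeny
    null_model_options: dict = field(default_factory=dict)


def run_pipeline(
    config: RunConfig,
    pair: CensusPair | None = None,
    D: PatristicMatrix | None = None,
    species_table: pd.DataFrame | None = None,
) -> dict:
    """Run the full pipeline and write results under ``config.out_dir``.

    Data may be passed in memory; otherwise the paths in the config are
    read.  Returns the manifest dictionary.
    """
    from .census_io import read_census_table, read_species_table
    from .phylo import patristic_matrix, read_tree

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if pair is None:
        c1 = read_census_table(config.census1, config.plot_dims)
        c2 = read_census_table(config.census2, config.plot_dims)
        pair = CensusPair(c1, c2, config.plot_dims, config.dates)
    if D is None:
        D = patristic_matrix(read_tree(config.tree))
    if species_table is None and config.species_table:
        species_table = read_species_table(config.species_table)
    missing = set(pair.species_pool()) - set(D.species)
    if missing and config.prune_missing_species:
        from .census_io import prune_to_species
        pair = prune_to_species(pair, set(D.species))
        log.info("pruned %d census-1 and %d census-2 stems of %d species "
                 "absent from the phylogeny",
                 pair.census1.attrs["n_pruned"], pair.census2.attrs["n_pruned"],
                 len(missing))
    elif missing:
        raise ValueError(f"census species missing from phylogeny: {sorted(missing)[:5]} "
                         "(set prune_missing_species to drop them)")
    if "NM2" in config.null_models:
        if species_table is None or "growth_form" not in species_table.columns:
            raise ValueError("NM-II requires a species table with a growth_form column")
        demo = classify_demographics(pair)
        disp = measure_dispersal(pair, species_table,
                                 NullModelConfig(kind="NM2", **config.null_model_options))
        n_orphan = int(disp["Dp"].isna().sum())
        log.info("deaths=%d recruits=%d recruits without 50 m parent=%d (%.1f%%)",
                 len(demo.deaths), len(demo.recruits), n_orphan,
                 100 * n_orphan / max(len(disp), 1))
        disp.to_csv(out / "dispersal_records.csv", index=False)
        from .nullmodels import estimate_survival_table
        estimate_survival_table(pair).to_csv(out / "survival_table.csv")

    ss = np.random.SeedSequence(config.seed)
    outputs: list[str] = []
    sar_rows, vp_rows = [], []
    for kind in config.null_models:
        nm = NullModelConfig(kind=kind, n_rep=config.n_rep,
                             **config.null_model_options)
        for s, child in zip(config.scales, ss.spawn(len(config.scales))):
            res = analyze_scale(pair, D, s, nm, species_table=species_table,
                                nri_n_rand=config.nri_n_rand,
                                moran_n_perm=config.moran_n_perm,
                                varpart_n_perm=config.varpart_n_perm,
                                seed=child)
            tag = f"{kind}_s{int(s)}"
            res.joined.to_csv(out / f"quadrats_{tag}.csv", index=False)
            outputs.append(f"quadrats_{tag}.csv")
            sar_rows.append(res.sar_summary())
            if res.varpart is not None:
                v = res.varpart
                vp_rows.append({"scale": s, "null_model": kind, "a": v.a,
                                "b": v.b, "c": v.c, "residual": v.d,
                                "a_plus_b": v.ab, "n": v.n,
                                "n_selected_axes": len(v.selected_axes)})
    pd.DataFrame(sar_rows).to_csv(out / "sar_summary.csv", index=False)
    pd.DataFrame(vp_rows).to_csv(out / "varpart_summary.csv", index=False)
    outputs += ["sar_summary.csv", "varpart_summary.csv"]
    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest(),
        "outputs": sorted(set(outputs)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
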