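"""Quadrat gridding and quadrat x species community matrices.

The plot is tiled with non-overlapping square quadrats of side ``s`` (the
analysis scales are typically 10-50 m).  Cells are half-open
``[i*s, (i+1)*s)`` with origin at the plot's lower-left corner; points on the
plot's upper/right boundary are clamped into the last cell, and stems falling
in partial edge cells (plot dimensions not divisible by ``s``) are excluded
and counted in the grid's log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QuadratGrid:
    """A complete-square-quadrat tiling of the plot at one analysis scale."""

    s: float
    nx: int
    ny: int
    plot_dims: tuple[float, float]
    log: dict = field(default_factory=dict, compare=False)

    @property
    def n_quadrats(self) -> int:
        return self.nx * self.ny

    def centroids(self) -> np.ndarray:
        """(n_quadrats, 2) array of cell-center coordinates, row-major in
        (row=y, col=x) order matching quadrat ids."""
        cols, rows = np.meshgrid(np.arange(self.nx), np.arange(self.ny))
        return np.column_stack(
            [(cols.ravel() + 0.5) * self.s, (rows.ravel() + 0.5) * self.s]
        )

    def quadrat_id(self, col: np.ndarray, row: np.ndarray) -> np.ndarray:
        return row * self.nx + col


@dataclass(frozen=True)
class CommunityMatrix:
    """Stem counts per quadrat and species for one census at one scale."""

    counts: np.ndarray  # (n_quadrats, n_species) integer
    grid: QuadratGrid
    species: tuple[str, ...]
    census_label: str = ""

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized counts; rows of empty quadrats are left at 0."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals > 0, self.counts / np.maximum(totals, 1), 0.0)
        return p

    def presence(self) -> np.ndarray:
        return (self.counts > 0).astype(np.int64)


def gridify(
    x: np.ndarray, y: np.ndarray, plot_dims: tuple[float, float], s: float
) -> tuple[QuadratGrid, np.ndarray]:
    """Assign points to quadrats.

    Returns the grid and an integer quadrat id per point (-1 for points in
    partial edge cells, which are excluded from analysis).
    """
    width, height = plot_dims
    if not 0 < s <= min(width, height):
        raise ValueError(f"quadrat side {s} must be in (0, {min(width, height)}]")
    nx, ny = int(np.floor(width / s)), int(np.floor(height / s))
    col = np.floor(np.asarray(x, dtype=float) / s).astype(np.int64)
    row = np.floor(np.asarray(y, dtype=float) / s).astype(np.int64)
    # clamp the maximal boundary (x == width etc.) into the last full cell
    col[np.asarray(x) == width] = nx - 1
    row[np.asarray(y) == height] = ny - 1
    inside = (col < nx) & (row < ny)
    qid = np.where(inside, row * nx + col, -1)
    grid = QuadratGrid(s=float(s), nx=nx, ny=ny, plot_dims=(width, height),
                       log={"n_excluded_edge": int((~inside).sum())})
    return grid, qid


def community_matrix(
    census: pd.DataFrame,
    grid: QuadratGrid,
    species: tuple[str, ...] | list[str],
    census_label: str = "",
) -> CommunityMatrix:
    """Count alive stems per (quadrat, species).

    Species present in the census but absent from ``species`` raise an error
    (pass a pool that covers both censuses and the phylogeny tips).
    """
    alive = census.loc[census["status"] == "alive"]
    _, qid = gridify(alive["x"].to_numpy(), alive["y"].to_numpy(), grid.plot_dims, grid.s)
    sp_index = {sp: i for i, sp in enumerate(species)}
    unknown = set(alive["species"]) - set(species)
    if unknown:
        raise ValueError(f"species not in declared pool/phylogeny: {sorted(unknown)[:5]}")
    keep = qid >= 0
    sp = alive["species"].map(sp_index).to_numpy(dtype=np.int64)[keep]
    counts = np.zeros((grid.n_quadrats, len(species)), dtype=np.int64)
    np.add.at(counts, (qid[keep], sp), 1)
    return CommunityMatrix(counts=counts, grid=grid, species=tuple(species),
                           census_label=census_label)
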