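"""Lattice neighbor weights, Moran's I, and the SAR error model.

The quadrat grid induces a contiguity structure: rook (the 4 cells sharing
an edge — centers exactly one cell side apart, the "1 grid-cell lag") or
queen (8 cells including diagonals).  Moran's I over these weights measures
spatial autocorrelation and is tested by random permutation.  The SAR error
model

    y = X beta + u,   u = lambda W u + eps,   eps ~ iid N(0, sigma^2)

is fitted by maximum likelihood: beta and sigma^2 are profiled out and the
concentrated log-likelihood over lambda — whose Jacobian term
ln|I - lambda W| is evaluated from the eigenvalues of W — is maximized by
bounded scalar search.  It corrects coefficient inference (here, the slope
of ses.RaoD on NRI) for spatially autocorrelated residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .community import QuadratGrid


class SpatialError(ValueError):
    pass


@dataclass
class SpatialWeights:
    """Contiguity weights over a subset of quadrats of one grid."""

    ids: np.ndarray            # quadrat ids included, ascending
    binary: sp.csr_matrix      # symmetric 0/1 adjacency
    scheme: str = "rook"
    row_standardized: bool = True
    _w: sp.csr_matrix | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def W(self) -> sp.csr_matrix:
        if self._w is None:
            deg = np.asarray(self.binary.sum(axis=1)).ravel()
            if self.row_standardized:
                inv = np.divide(1.0, deg, out=np.zeros_like(deg, dtype=float),
                                where=deg > 0)
                self._w = sp.diags(inv) @ self.binary
            else:
                self._w = self.binary.astype(float)
        return self._w

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.binary.sum(axis=1)).ravel()

    def nonisolated(self) -> np.ndarray:
        return self.degrees > 0

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the row-standardized W (real: W is similar to a
        symmetric matrix D^-1/2 B D^-1/2)."""
        deg = self.degrees
        if np.any(deg == 0):
            raise SpatialError("drop isolated quadrats before eigen-analysis")
        d = 1.0 / np.sqrt(deg)
        S = sp.diags(d) @ self.binary @ sp.diags(d)
        return scipy.linalg.eigvalsh(S.toarray())

    def subset(self, mask: np.ndarray) -> "SpatialWeights":
        idx = np.flatnonzero(mask)
        return SpatialWeights(ids=self.ids[idx],
                              binary=self.binary[np.ix_(idx, idx)].tocsr(),
                              scheme=self.scheme,
                              row_standardized=self.row_standardized)


def lattice_weights(
    grid: QuadratGrid,
    include: np.ndarray | None = None,
    scheme: str = "rook",
    row_standardize: bool = True,
) -> SpatialWeights:
    """Contiguity weights among (optionally a subset of) grid quadrats.

    ``include``: boolean mask over quadrat ids; excluded quadrats are
    removed together with their links.  Isolated quadrats are retained with
    empty neighbor sets (warned); drop them with :meth:`SpatialWeights.subset`
    before Moran/SAR analysis.
    """
    if scheme not in ("rook", "queen"):
        raise SpatialError(f"unknown scheme {scheme!r}")
    nx, ny = grid.nx, grid.ny
    ids = np.arange(grid.n_quadrats) if include is None else np.flatnonzero(include)
    if len(ids) < 2:
        raise SpatialError("need at least 2 included quadrats")
    pos = -np.ones(grid.n_quadrats, dtype=np.int64)
    pos[ids] = np.arange(len(ids))
    rows_, cols_ = divmod(ids, nx)
    steps = [(0, 1), (1, 0)]
    if scheme == "queen":
        steps += [(1, 1), (1, -1)]
    ii, jj = [], []
    for dr, dc in steps:
        r2, c2 = rows_ + dr, cols_ + dc
        ok = (r2 >= 0) & (r2 < ny) & (c2 >= 0) & (c2 < nx)
        nbr = np.where(ok, r2 * nx + np.clip(c2, 0, nx - 1), -1)
        ok &= (nbr >= 0) & (pos[np.maximum(nbr, 0)] >= 0)
        ii.append(np.arange(len(ids))[ok])
        jj.append(pos[nbr[ok]])
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    data = np.ones(2 * len(i))
    B = sp.csr_matrix(
        (data, (np.r_[i, j], np.r_[j, i])), shape=(len(ids), len(ids))
    )
    B.data[:] = 1.0  # collapse duplicates
    B.sum_duplicates()
    B.data[:] = 1.0
    w = SpatialWeights(ids=ids, binary=B, scheme=scheme,
                       row_standardized=row_standardize)
    if np.any(w.degrees == 0):
        warnings.warn(f"{int((w.degrees == 0).sum())} isolated quadrat(s); "
                      "excluded from Moran's I and SAR fits")
    return w


@dataclass(frozen=True)
class MoranResult:
    I: float
    p: float
    n_perm: int
    expected: float

    @property
    def significant(self) -> bool:
        return self.p <= 0.05


def morans_i(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> MoranResult:
    """Moran's I with a two-sided permutation test (add-one rule)."""
    rng = rng if rng is not None else np.random.default_rng()
    keep = weights.nonisolated()
    w = weights if keep.all() else weights.subset(keep)
    v = np.asarray(values, dtype=float)[keep] if not keep.all() else np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise SpatialError("values must be finite")
    if v.std() == 0:
        raise SpatialError("zero variance: Moran's I undefined")
    W = w.W
    S0 = W.sum()
    n = len(v)

    def stat(Z: np.ndarray) -> np.ndarray:
        Zc = Z - Z.mean(axis=0, keepdims=True)
        num = np.einsum("nm,nm->m", Zc, W @ Zc)
        return (n / S0) * num / (Zc**2).sum(axis=0)

    I_obs = float(stat(v[:, None])[0])
    if n_perm > 0:
        perms = np.empty((n, n_perm))
        for k in range(n_perm):
            perms[:, k] = rng.permutation(v)
        I_null = stat(perms)
        p_hi = (1 + np.sum(I_null >= I_obs)) / (n_perm + 1)
        p_lo = (1 + np.sum(I_null <= I_obs)) / (n_perm + 1)
        p = min(1.0, 2 * min(p_hi, p_lo))
    else:
        p = np.nan
    return MoranResult(I=I_obs, p=float(p), n_perm=n_perm,
                       expected=-1.0 / (n - 1))


@dataclass
class SARFit:
    """ML fit of the SAR error model y = X beta + u, u = lambda W u + eps."""

    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    lam: float
    sigma2: float
    loglik: float
    resid: np.ndarray   # whitened innovations eps_hat = (I - lam W)(y - X beta)
    n: int
    names: list[str]

    def summary(self) -> str:
        rows = [f"SAR error model (n={self.n}, lambda={self.lam:.4f}, "
                f"logLik={self.loglik:.2f})"]
        for nm, b, se, z, p in zip(self.names, self.params, self.bse,
                                   self.zvalues, self.pvalues):
            rows.append(f"  {nm:>12s}  {b: .5f}  se={se:.5f}  z={z: .3f}  p={p:.4g}")
        return "\n".join(rows)


def sar_error_fit(
    y: np.ndarray,
    X: np.ndarray,
    weights: SpatialWeights,
    names: list[str] | None = None,
    eigvals: np.ndarray | None = None,
) -> SARFit:
    """Maximum-likelihood SAR error fit.

    ``X`` must include the intercept column.  ``eigvals`` may pass
    precomputed eigenvalues of W (reused across fits on the same lattice).
    """
    keep = weights.nonisolated()
    if not keep.all():
        weights = weights.subset(keep)
        y = np.asarray(y, dtype=float)[keep]
        X = np.asarray(X, dtype=float)[keep]
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise SpatialError("collinear design matrix")
    W = weights.W
    omega = eigvals if eigvals is not None else weights.eigenvalues()
    lo = 1.0 / omega.min() + 1e-6 if omega.min() < 0 else -0.999999
    hi = 1.0 / omega.max() - 1e-6

    Wy = W @ y
    WX = W @ X

    def profile(lam: float):
        Ay = y - lam * Wy
        AX = X - lam * WX
        beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
        e = Ay - AX @ beta
        sigma2 = float(e @ e) / n
        ll = (-0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
              + np.sum(np.log1p(-lam * omega)))
        return ll, beta, sigma2, e, AX

    res = minimize_scalar(lambda lam: -profile(lam)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-8})
    if not res.success:  # pragma: no cover
        raise SpatialError(f"lambda search failed: {res.message}")
    lam = float(res.x)
    ll, beta, sigma2, e, AX = profile(lam)
    cov = sigma2 * np.linalg.inv(AX.T @ AX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * norm.sf(np.abs(z))
    return SARFit(params=beta, bse=se, zvalues=z, pvalues=pvals, lam=lam,
                  sigma2=sigma2, loglik=float(ll), resid=e, n=n,
                  names=names or [f"x{i}" for i in range(p)])
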