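"""PCNM spatial eigenfunctions and adjusted-R^2 variation partitioning.

PCNM (principal coordinates of neighbour matrices) axes are spatial
predictors spanning all scales a quadrat grid accommodates: the pairwise
distance matrix among quadrat centroids is truncated at the
diagonal-neighbor distance t = s*sqrt(2) (larger distances replaced by 4t),
double-centered, and eigendecomposed; the positive-eigenvalue eigenvectors
are the axes.  After removing a broad cubic trend in the coordinates, axes
are chosen by forward selection with permutation tests, and the variance of
the response (here detrended ses.RaoD) is partitioned into the fraction
explained only by NRI [a], shared [b], only by space [c] and residual [d],
all on the adjusted-R^2 scale (so fractions can be slightly negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform


class VarpartError(ValueError):
    pass


@dataclass(frozen=True)
class PCNMBasis:
    vectors: np.ndarray      # (n, k) orthonormal
    eigenvalues: np.ndarray  # (k,) positive, descending
    truncation: float

    @property
    def n_axes(self) -> int:
        return self.vectors.shape[1]


def pcnm_basis(
    centroids: np.ndarray, s: float, literal_4d: bool = False
) -> PCNMBasis:
    """PCNM axes for quadrat centroids on a grid of cell side ``s``.

    ``literal_4d`` replaces each above-threshold distance by 4x itself
    instead of the conventional constant 4t (sensitivity option).
    """
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 3:
        raise VarpartError("need at least 3 quadrats for PCNM")
    d = squareform(pdist(pts))
    t = s * np.sqrt(2.0) * (1 + 1e-9)
    far = d > t
    d = d.copy()
    d[far] = 4 * d[far] if literal_4d else 4 * t
    # Gower double-centering of -D^2/2, then eigendecomposition
    a = -0.5 * d**2
    a -= a.mean(axis=0, keepdims=True)
    a -= a.mean(axis=1, keepdims=True)
    evals, evecs = np.linalg.eigh(a)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-8 * evals.max(), 1e-10)
    return PCNMBasis(vectors=evecs[:, pos], eigenvalues=evals[pos],
                     truncation=t / (1 + 1e-9))


def _design(X: np.ndarray | None, n: int) -> np.ndarray:
    one = np.ones((n, 1))
    if X is None or X.size == 0:
        return one
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    return np.hstack([one, X])


def _r2(y: np.ndarray, X: np.ndarray | None) -> tuple[float, int]:
    """(R^2, number of non-intercept predictors) of an OLS fit."""
    n = len(y)
    M = _design(X, n)
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise VarpartError("response has zero variance")
    return 1.0 - float(resid @ resid) / tss, M.shape[1] - 1


def adjusted_r2(y: np.ndarray, X: np.ndarray | None) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1) for the OLS fit of y on X."""
    n = len(y)
    r2, p = _r2(y, X)
    if n - p - 1 <= 0:
        raise VarpartError(f"too few observations (n={n}) for {p} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def detrend_poly3(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Residuals after removing a full third-degree polynomial trend in the
    centroid coordinates (9 monomials x^p y^q, 1 <= p+q <= 3, + intercept),
    fitted on an orthogonalized basis for conditioning."""
    y = np.asarray(values, dtype=float)
    pts = np.asarray(centroids, dtype=float)
    n = len(y)
    if n <= 10:
        raise VarpartError("need more than 10 observations for a cubic trend")
    xs = (pts[:, 0] - pts[:, 0].mean()) / (pts[:, 0].std() or 1.0)
    ys = (pts[:, 1] - pts[:, 1].mean()) / (pts[:, 1].std() or 1.0)
    cols = [np.ones(n)]
    for total in (1, 2, 3):
        for px in range(total + 1):
            cols.append(xs ** px * ys ** (total - px))
    M = np.column_stack(cols)
    q, r = np.linalg.qr(M)
    if np.min(np.abs(np.diag(r))) < 1e-10 * np.max(np.abs(np.diag(r))):
        raise VarpartError("collinear centroid polynomial basis")
    return y - q @ (q.T @ y)


def forward_select(
    y: np.ndarray,
    basis: PCNMBasis,
    alpha: float = 0.05,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Forward selection of PCNM axes by permutation-tested R^2 increase.

    At each step the axis giving the largest R^2 increase is the candidate;
    its gain is compared with the best achievable gain on data where the
    current model's residuals are randomly permuted (Freedman-Lane), which
    keeps the first-step test exact despite best-of-m selection.  Selection
    stops at the first non-significant step.  May return an empty list.
    """
    rng = rng if rng is not None else np.random.default_rng()
    y = np.asarray(y, dtype=float)
    V = basis.vectors
    n, m = V.shape
    selected: list[int] = []
    remaining = list(range(m))
    yc = y - y.mean()
    while remaining:
        # orthogonalize remaining axes against intercept + selected axes
        Msel = np.hstack([np.ones((n, 1)), V[:, selected]]) if selected else np.ones((n, 1))
        Q, _ = np.linalg.qr(Msel)
        resid_y = yc - Q @ (Q.T @ yc)
        rss_cur = float(resid_y @ resid_y)
        if rss_cur <= 1e-14:
            break
        Vr = V[:, remaining] - Q @ (Q.T @ V[:, remaining])
        norms = (Vr**2).sum(axis=0)
        usable = norms > 1e-12
        if not usable.any():
            break
        gains = np.zeros(len(remaining))
        gains[usable] = (Vr[:, usable].T @ resid_y) ** 2 / norms[usable]
        best_pos = int(np.argmax(gains))
        if alpha <= 0:
            break
        # permutation null of the best gain (reselected per permutation)
        fitted = yc - resid_y
        E = np.empty((n, n_perm))
        for k in range(n_perm):
            E[:, k] = rng.permutation(resid_y)
        Yp = fitted[:, None] + E
        Rp = Yp - Q @ (Q.T @ Yp)             # residuals of permuted data
        G = (Vr[:, usable].T @ Rp) ** 2 / norms[usable][:, None]
        rssp = np.einsum("nm,nm->m", Rp, Rp)
        best_frac_null = G.max(axis=0) / rssp
        best_frac_obs = gains[best_pos] / rss_cur
        p = (1 + np.sum(best_frac_null >= best_frac_obs)) / (n_perm + 1)
        if p > alpha:
            break
        selected.append(remaining.pop(best_pos))
    return selected


@dataclass(frozen=True)
class VarPartResult:
    a: float            # pure NRI
    b: float            # shared
    c: float            # pure spatial
    d: float            # residual
    ab: float           # total NRI = R2a of the NRI-only model
    selected_axes: tuple[int, ...]
    n: int
    r2a_nri: float
    r2a_pcnm: float
    r2a_both: float


def variation_partition(
    y: np.ndarray,
    x_nri: np.ndarray,
    pcnm_axes: np.ndarray | None,
    selected_axes: tuple[int, ...] = (),
) -> VarPartResult:
    """Partition variance of ``y`` between NRI and the selected PCNM axes.

    a = R2a(both) - R2a(PCNM), c = R2a(both) - R2a(NRI),
    b = R2a(NRI) - a, d = 1 - (a + b + c).  Fractions may be slightly
    negative (an adjusted-R^2 property).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    S = None
    if pcnm_axes is not None and np.size(pcnm_axes):
        S = np.atleast_2d(np.asarray(pcnm_axes, dtype=float))
        if S.shape[0] != n:
            S = S.T
    r2a_nri = adjusted_r2(y, x_nri)
    if S is None:
        r2a_pcnm = 0.0
        r2a_both = r2a_nri
    else:
        r2a_pcnm = adjusted_r2(y, S)
        r2a_both = adjusted_r2(y, np.column_stack([np.asarray(x_nri, float).reshape(n, -1), S]))
    a = r2a_both - r2a_pcnm
    c = r2a_both - r2a_nri
    b = r2a_nri - a
    d = 1.0 - (a + b + c)
    return VarPartResult(a=a, b=b, c=c, d=d, ab=r2a_nri,
                         selected_axes=tuple(selected_axes), n=n,
                         r2a_nri=r2a_nri, r2a_pcnm=r2a_pcnm, r2a_both=r2a_both)
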