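"""Blomberg's K: phylogenetic signal of a continuous trait and its test.

K compares the trait's fit to the tree's Brownian-motion covariance
structure against the fit expected if the trait evolved by Brownian motion:
K ~ 0 means no signal, K = 1 is the Brownian expectation, K > 1 means close
relatives resemble each other even more than Brownian motion predicts.
Significance is assessed by shuffling trait values across the tips and
asking how often a shuffled K reaches the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class SignalError(ValueError):
    pass


@dataclass(frozen=True)
class SignalResult:
    trait: str
    K: float
    p: float
    n_shuffles: int
    n_species: int


def bm_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance among tips: C_ij = depth of MRCA(i, j),
    C_ii = root-to-tip distance.  Tips ordered by label."""
    tips = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    labels = [nd.taxon.label for nd in tips]
    index = {id(nd): i for i, nd in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth.get(id(node.parent_node), 0.0)
        depth[id(node)] = parent_depth + (node.edge.length or 0.0)
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tipsets[id(node)] = [i]
            C[i, i] = depth[id(node)]
            continue
        child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    C[i, child_sets[b]] = d
                    C[np.array(child_sets[b]), i] = d
        tipsets[id(node)] = [i for s in child_sets for i in s]
    return C, labels


def _prune_to(tree: dendropy.Tree, labels: set[str]) -> dendropy.Tree:
    keep = [t for t in tree.taxon_namespace if t.label in labels]
    return tree.extract_tree_with_taxa(keep)


def _k_from_c(Cinv: np.ndarray, C_trace: float, x: np.ndarray) -> np.ndarray:
    """K for one trait vector or a (n, m) matrix of permuted vectors."""
    X = np.atleast_2d(x.T).T  # (n, m)
    n = X.shape[0]
    ones = np.ones(n)
    ci1 = Cinv @ ones
    denom = ones @ ci1
    ahat = (ci1 @ X) / denom  # (m,)
    R = X - ahat[None, :]
    mse0 = (R**2).sum(axis=0) / (n - 1)
    mse = np.einsum("nm,nm->m", R, Cinv @ R) / (n - 1)
    if np.any(mse <= 0) or np.any(mse0 <= 0):
        raise SignalError("trait is constant across tips: K undefined")
    expected = (C_trace - n / denom) / (n - 1)
    k = (mse0 / mse) / expected
    return k if np.ndim(x) > 1 else float(k[0])


def blomberg_k(tree: dendropy.Tree, trait: dict[str, float]) -> float:
    """Blomberg's K for one trait; species missing a value are pruned."""
    shared = {t.label for t in tree.taxon_namespace} & set(trait)
    if len(shared) < 3:
        raise SignalError("need >= 3 species shared between tree and trait table")
    sub = _prune_to(tree, shared)
    C, labels = bm_covariance(sub)
    x = np.array([trait[lb] for lb in labels], dtype=float)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as e:
        raise SignalError(f"singular phylogenetic covariance: {e}") from None
    return _k_from_c(Cinv, float(np.trace(C)), x)


def k_significance(
    tree: dendropy.Tree,
    trait: dict[str, float],
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    trait_name: str = "trait",
) -> SignalResult:
    """One-tailed tip-shuffle test of K.

    p = (1 + #{K_null >= K_obs}) / (1 + n_shuffles): the probability that a
    random assignment of the same trait values to the tips yields as much
    signal as observed.
    """
    if n_shuffles < 1:
        raise SignalError("n_shuffles must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    shared = {t.label for t in tree.taxon_namespace} & set(trait)
    if len(shared) < 3:
        raise SignalError("need >= 3 species shared between tree and trait table")
    sub = _prune_to(tree, shared)
    C, labels = bm_covariance(sub)
    x = np.array([trait[lb] for lb in labels], dtype=float)
    Cinv = np.linalg.inv(C)
    tr = float(np.trace(C))
    k_obs = _k_from_c(Cinv, tr, x)
    perms = np.column_stack([rng.permutation(x) for _ in range(n_shuffles)])
    k_null = _k_from_c(Cinv, tr, perms)
    p = (1 + int(np.sum(k_null >= k_obs))) / (1 + n_shuffles)
    return SignalResult(trait=trait_name, K=float(k_obs), p=float(p),
                        n_shuffles=n_shuffles, n_species=len(labels))
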