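"""Phylogeny handling: patristic distances and node-age branch-length smoothing.

Trees are :class:`dendropy.Tree` objects with tip labels equal to the species
codes used in the census tables.  :func:`patristic_matrix` returns the
pairwise tip-to-tip path-length matrix d_ij used throughout (Rao turnover,
MPD/NRI).  :func:`bladj_smooth` implements even-interpolation age smoothing:
nodes with known ages (e.g. fossil or molecular calibration points) are fixed
and every undated node is spaced evenly between its nearest dated ancestor
and nearest dated descendant, yielding an ultrametric tree in time units.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd


class PhyloError(ValueError):
    pass


@dataclass(frozen=True)
class PatristicMatrix:
    """Symmetric tip-to-tip path-length matrix with its species index."""

    matrix: np.ndarray
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.species)
        if self.matrix.shape != (n, n):
            raise PhyloError("matrix shape does not match species index")

    @property
    def index(self) -> dict[str, int]:
        return {sp: i for i, sp in enumerate(self.species)}

    def distance(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.matrix[idx[a], idx[b]])

    def reorder(self, species: list[str]) -> "PatristicMatrix":
        """Return a submatrix aligned to ``species`` (must be a subset)."""
        idx = self.index
        try:
            sel = np.array([idx[s] for s in species])
        except KeyError as e:
            raise PhyloError(f"species {e.args[0]!r} not in phylogeny") from None
        return PatristicMatrix(self.matrix[np.ix_(sel, sel)], tuple(species))


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree, preserving internal node labels."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)


def patristic_matrix(tree: dendropy.Tree) -> PatristicMatrix:
    """Pairwise patristic distances between all tips, sorted by tip label.

    d_ij is the sum of branch lengths along the path joining tips i and j.
    """
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise PhyloError("tree has edges without branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = tuple(t.label for t in taxa)
    if len(set(labels)) != len(labels):
        raise PhyloError("duplicate tip labels")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return PatristicMatrix(d, labels)


def read_age_constraints(path: str | Path) -> dict[str, float]:
    """Two-column CSV (node name, age in Myr) -> constraint dict."""
    df = pd.read_csv(path, header=None if _headerless(path) else 0)
    df.columns = ["node", "age"][: len(df.columns)]
    return dict(zip(df["node"].astype(str), df["age"].astype(float)))


def _headerless(path: str | Path) -> bool:
    with open(path) as fh:
        first = fh.readline().split(",")
    try:
        float(first[1])
        return True
    except (ValueError, IndexError):
        return False


def bladj_smooth(tree: dendropy.Tree, ages: dict[str, float]) -> dendropy.Tree:
    """Fix dated nodes at their ages and interpolate the rest evenly.

    ``ages`` maps internal node labels to ages (time before present); the
    root must be constrained (by its label, or the key ``"root"``).  Tips are
    fixed at age 0.  Every undated internal node is placed by even
    interpolation between its nearest dated ancestor and its nearest dated
    descendant along the path (nearest by edge count; ties broken by the
    oldest such descendant).  Branch lengths are rewritten as parent age
    minus child age; the result is ultrametric.

    Raises
    ------
    PhyloError
        If the root is unconstrained or any assignment makes a child at
        least as old as its parent.
    """
    tree = tree.clone(depth=1)
    node_age: dict[int, float | None] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node_age[id(node)] = 0.0
        else:
            label = node.taxon.label if node.taxon else node.label
            if label is not None and label in ages:
                node_age[id(node)] = float(ages[label])
            elif node is tree.seed_node and "root" in ages:
                node_age[id(node)] = float(ages["root"])
            else:
                node_age[id(node)] = None
    if node_age[id(tree.seed_node)] is None:
        raise PhyloError("root age must be constrained")

    def nearest_constrained_descendant(node) -> tuple[float, int]:
        # BFS down; among the shallowest constrained nodes, take the oldest
        best: tuple[int, float] | None = None
        queue = deque((child, 1) for child in node.child_nodes())
        while queue:
            cur, depth = queue.popleft()
            if best is not None and depth > best[0]:
                break
            a = node_age[id(cur)]
            if a is not None:
                if best is None or (depth == best[0] and a > best[1]):
                    best = (depth, a)
                continue
            queue.extend((c, depth + 1) for c in cur.child_nodes())
        assert best is not None  # every path ends in a tip (age 0)
        return best[1], best[0]

    for node in tree.preorder_node_iter():
        if node_age[id(node)] is not None:
            continue
        anc, g_up = node.parent_node, 1
        while node_age[id(anc)] is None:
            anc, g_up = anc.parent_node, g_up + 1
        a_age = node_age[id(anc)]
        d_age, g_down = nearest_constrained_descendant(node)
        node_age[id(node)] = d_age + (a_age - d_age) * g_down / (g_up + g_down)

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        gap = node_age[id(node.parent_node)] - node_age[id(node)]
        if gap <= 0:
            raise PhyloError(
                f"age constraint conflict: node age {node_age[id(node)]:g} >= "
                f"parent age {node_age[id(node.parent_node)]:g}"
            )
        node.edge.length = gap
    return tree
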