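"""Distance-based phylogeny over the species panel.

Distances are p-distances derived from pairwise percent identity
(``d = 1 - identity/100``); an optional Poisson correction
(``d = -ln(1 - p)``) is available but off by default since the panels of
interest are near-identical, where the correction is negligible.  Trees are
built by Saitou-Nei neighbor joining, which reconstructs additive distances
exactly, and written as Newick.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


@dataclass
class TreeNode:
    """Node of an (unrooted, stored rooted-at-top) phylogenetic tree."""

    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out


@dataclass
class PhyloTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()


def distance_from_identity(
    identity_pct: dict[tuple[str, str], float],
    labels: list[str],
    poisson_correct: bool = False,
) -> DistanceMatrix:
    """Build a distance matrix from pairwise percent identities.

    ``identity_pct`` maps unordered label pairs to identity percentages;
    every off-diagonal pair must be present (either orientation).
    """
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = (labels[i], labels[j])
            if key not in identity_pct:
                key = (labels[j], labels[i])
            if key not in identity_pct:
                raise ValueError(
                    f"missing pairwise identity for ({labels[i]}, {labels[j]})"
                )
            p = 1.0 - identity_pct[key] / 100.0
            if poisson_correct:
                if p >= 1.0:
                    raise ValueError("cannot Poisson-correct p-distance >= 1")
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(labels), d)


def _sort_key(node: TreeNode) -> str:
    # canonical key of a working node = smallest leaf label under it
    return min(node.leaf_names())


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Exact on additive matrices.  Ties in the Q criterion are broken toward
    the lexicographically smallest pair of canonical node labels, so the
    result is deterministic.  Negative branch lengths are clamped to zero
    with a logged warning.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    nodes: list[TreeNode] = [TreeNode(lbl) for lbl in dm.labels]
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.d[i, j])
    active = list(range(n))
    next_id = n

    def d(i: int, j: int) -> float:
        return dist[(min(i, j), max(i, j))] if i != j else 0.0

    def clamp(x: float, a: TreeNode, b: TreeNode) -> float:
        if x < 0:
            logger.warning(
                "negative NJ branch length %.3g clamped to 0 (join of %s, %s)",
                x, _sort_key(a), _sort_key(b),
            )
            return 0.0
        return x

    node_of: dict[int, TreeNode] = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = tuple(sorted((_sort_key(node_of[i]), _sort_key(node_of[j]))))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and best is not None and key < best[1]
                ):
                    best_q = q
                    best = ((i, j), key)
        (i, j), _ = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d(i, j) - li
        li = clamp(li, node_of[i], node_of[j])
        lj = clamp(lj, node_of[j], node_of[i])
        parent = TreeNode(children=[(node_of[i], li), (node_of[j], lj)])
        u = next_id
        next_id += 1
        node_of[u] = parent
        for k in active:
            if k in (i, j):
                continue
            dist[(min(u, k), max(u, k))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = TreeNode(
        children=[
            (node_of[a], clamp(la, node_of[a], node_of[b])),
            (node_of[b], clamp(lb, node_of[b], node_of[a])),
            (node_of[c], clamp(lc, node_of[c], node_of[a])),
        ]
    )
    return PhyloTree(root)


_NEEDS_QUOTING = re.compile(r"[\s()\[\]{}:;,']")


def _newick_label(name: str) -> str:
    if _NEEDS_QUOTING.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: PhyloTree, decimals: int = 10) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return _newick_label(node.name)
        inner = ",".join(
            f"{fmt(child)}:{format(round(length, decimals), f'.{decimals}f').rstrip('0').rstrip('.')}"
            for child, length in node.children
        )
        return f"({inner})"

    return fmt(tree.root) + ";"


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n", encoding="utf-8")
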