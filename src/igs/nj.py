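"""Neighbor-joining (Saitou & Nei) on p-distance matrices.

Produces an unrooted tree represented by a trifurcating root node.
Negative branch-length estimates are clamped to zero with the deficit
transferred to the sister branch, and agglomeration ties are broken on
the lexicographically smallest pair of subtree labels (the label of a
subtree is its smallest leaf label), making the construction fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix

__all__ = ["TreeNode", "build_nj", "tree_clusters"]


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def n_edges(self) -> int:
        total = 0
        for c, _ in self.children:
            total += 1 + c.n_edges()
        return total

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"

    def edges(self, _parent=None):
        """Yield (parent, child, length) over the whole subtree."""
        for c, bl in self.children:
            yield (self, c, bl)
            yield from c.edges(self)


def _clamp(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def build_nj(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a complete distance matrix (n >= 3)."""
    if not dm.is_complete():
        raise ValueError("distance matrix has undefined entries")
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=lab) for lab in dm.ids]
    keys = [str(lab) for lab in dm.ids]  # tie-break label per subtree
    D = dm.values.astype(float).copy()

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin))
        best = None
        for i, j in cand:
            if i >= j:
                continue
            key = tuple(sorted((keys[i], keys[j])))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        _, i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        li, lj = _clamp(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.empty((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final three subtrees joined at the unrooted trifurcation
    (d01, d02, d12) = (D[0, 1], D[0, 2], D[1, 2])
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    l0, l1, l2 = max(l0, 0.0), max(l1, 0.0), max(l2, 0.0)
    return TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])


def tree_clusters(tree: TreeNode, n_clusters: int) -> list[set[str]]:
    """Leaf partition obtained by cutting the longest internal edges.

    The n_clusters-1 longest internal edges are removed (leaf edges are
    used only if internal edges run out); the leaf sets of the resulting
    components are returned sorted by their smallest member.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    edges = list(tree.edges())
    if n_clusters - 1 > len(edges):
        raise ValueError("more clusters requested than edges available")
    internal = [(p, c, bl) for p, c, bl in edges if not c.is_leaf()]
    external = [(p, c, bl) for p, c, bl in edges if c.is_leaf()]
    order = sorted(internal, key=lambda e: (-e[2], min(e[1].leaves()))) + \
        sorted(external, key=lambda e: (-e[2], min(e[1].leaves())))
    cut = {id(c) for _, c, _ in order[: n_clusters - 1]}

    clusters: list[set[str]] = []

    def collect(node: TreeNode, bag: set[str]):
        if node.is_leaf():
            bag.add(node.name)
        for child, _ in node.children:
            if id(child) in cut:
                newbag: set[str] = set()
                clusters.append(newbag)
                collect(child, newbag)
            else:
                collect(child, bag)

    root_bag: set[str] = set()
    clusters.append(root_bag)
    collect(tree, root_bag)
    return sorted((c for c in clusters if c), key=min)
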