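"""Neighbor-joining dendrograms (Saitou-Nei) with Newick serialization.

The agglomeration joins, at each step, the pair (i, j) minimizing

    Q_ij = (n - 2) d_ij - r_i - r_j,      r_i = sum_k d_ik

with ties broken toward the smallest (i, j) pair in the current node
order. Branch lengths use the standard three-point formulas; a negative
estimate is clamped to zero with the deficit moved to its sister branch,
preserving the pair's total. The result is an unrooted tree; for
serialization it is rooted at the last internal join.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relatedness import KinshipMatrix


class TreeError(ValueError):
    """Invalid distance matrix for tree building."""


@dataclass
class TreeNode:
    """A node of the dendrogram: a labelled leaf or an internal node
    whose ``children`` carry (child, branch length) pairs."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self, decimals: int = 6) -> str:
        return self._newick(decimals) + ";"

    def _newick(self, decimals: int) -> str:
        if self.is_leaf:
            return self.label
        inner = ",".join(
            f"{child._newick(decimals)}:{bl:.{decimals}f}"
            for child, bl in self.children
        )
        return f"({inner})"

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions of the leaf set (as clade leaf sets)."""
        all_leaves = frozenset(self.leaves())
        out: set[frozenset] = set()

        def rec(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            clade = frozenset().union(*(rec(c) for c, _ in node.children))
            if 1 < len(clade) < len(all_leaves) - 1:
                out.add(min(clade, all_leaves - clade, key=sorted))
            return clade

        for child, _ in self.children:
            rec(child)
        return out


def _clamp(li: float, lj: float) -> tuple[float, float]:
    """Clamp negative branch estimates to 0, deficit onto the sister."""
    if li < 0:
        lj, li = lj + li, 0.0
    if lj < 0:
        li, lj = li + lj, 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(distance: KinshipMatrix | np.ndarray, ids: list[str] | None = None) -> TreeNode:
    """Build the neighbor-joining tree of a symmetric distance matrix."""
    if isinstance(distance, KinshipMatrix):
        ids = list(distance.ids)
        d = np.array(distance.values, dtype=float)
    else:
        d = np.array(distance, dtype=float)
        if ids is None:
            ids = [f"t{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 2:
        raise TreeError("NJ needs at least 2 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-9, rtol=0):
        raise TreeError("distance matrix must be square and symmetric")

    nodes: list[TreeNode] = [TreeNode(label=t) for t in ids]
    while len(nodes) > 2:
        m = d.shape[0]
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q[np.tril_indices(m)] = np.inf  # keep i < j; argmin is lexicographic
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)

        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])

        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        new_d = np.empty((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = du[keep]
        new_d[-1, -1] = 0.0
        d = new_d
        nodes = [nodes[x] for x in keep] + [parent]

    a, b = nodes
    dab = float(d[0, 1])
    if a.is_leaf and b.is_leaf:
        return TreeNode(children=[(a, dab / 2.0), (b, dab / 2.0)])
    # root at the internal node, attaching the other with the full edge
    root, other = (a, b) if not a.is_leaf else (b, a)
    root.children.append((other, max(dab, 0.0)))
    return root
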