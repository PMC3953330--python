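"""Neighbor-joining trees over samples from rank-correlation distances.

The distance between two samples is 1 minus Spearman's rank correlation
(rho) of their FPKM profiles over the loci passing an expression filter
(FPKM > 1.0 in at least one sample by default), giving distances in
[0, 2]. Trees are built with the classical Saitou-Nei neighbor-joining
algorithm with deterministic lexicographic tie-breaking and negative
branch lengths clamped to zero (the deficit moved to the sister branch).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .feature_io import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "expression_distance",
    "neighbor_joining",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any() or (v > 2 + 1e-9).any():
            raise ValueError("distances must lie in [0, 2]")
        object.__setattr__(self, "values", v)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def expression_distance(
    expr: ExpressionMatrix,
    feature_ids: Optional[Sequence[str]] = None,
    min_fpkm: float = 1.0,
) -> DistanceMatrix:
    """1 - Spearman rho between all sample pairs.

    Loci are retained when their FPKM exceeds *min_fpkm* in at least one
    sample (a single global filter, not per-pair); ranks use the average
    rank for ties. A sample with zero variance over the retained loci has
    no defined rank correlation and raises an error naming it.
    """
    values = expr.values
    if feature_ids is not None:
        values = values.loc[list(feature_ids)]
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for a distance matrix")
    keep = (values > min_fpkm).any(axis=1)
    values = values.loc[keep]
    if values.shape[0] < 2:
        raise ValueError(
            f"fewer than 2 loci pass the FPKM > {min_fpkm} filter"
        )
    mat = values.values
    for j, sid in enumerate(values.columns):
        if np.allclose(mat[:, j], mat[0, j]):
            raise ValueError(
                f"sample {sid} has zero variance over retained loci; "
                "Spearman rho undefined"
            )
    ranks = np.apply_along_axis(rankdata, 0, mat)
    rho = np.corrcoef(ranks, rowvar=False)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(ids=tuple(values.columns), values=d)


class PhyloTree:
    """An unrooted tree over sample ids with branch lengths >= 0."""

    def __init__(
        self,
        adjacency: Dict[int, List[Tuple[int, float]]],
        leaf_names: Dict[int, str],
    ):
        self.adjacency = adjacency
        self.leaf_names = leaf_names

    @property
    def leaves(self) -> list:
        return sorted(self.leaf_names.values())

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the leaf-to-leaf path."""
        name_to_node = {v: k for k, v in self.leaf_names.items()}
        start, goal = name_to_node[a], name_to_node[b]
        stack = [(start, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == goal:
                return dist
            for nbr, ln in self.adjacency[node]:
                if nbr != parent:
                    stack.append((nbr, node, dist + ln))
        raise KeyError(f"no path between {a} and {b}")

    def _min_leaf(self, node: int, parent: int) -> str:
        if node in self.leaf_names:
            return self.leaf_names[node]
        return min(
            self._min_leaf(nbr, node)
            for nbr, _ in self.adjacency[node]
            if nbr != parent
        )

    def to_newick(self, digits: int = 10) -> str:
        """Canonical Newick: rooted for printing at the internal node
        adjacent to the lexicographically smallest leaf; children sorted
        by their smallest descendant leaf."""
        name_to_node = {v: k for k, v in self.leaf_names.items()}
        first_leaf = name_to_node[min(self.leaf_names.values())]
        root = self.adjacency[first_leaf][0][0] if self.adjacency[first_leaf] else first_leaf

        def render(node: int, parent: int) -> str:
            if node in self.leaf_names:
                return self.leaf_names[node]
            parts = []
            for nbr, ln in self.adjacency[node]:
                if nbr == parent:
                    continue
                parts.append(
                    (self._min_leaf(nbr, node), f"{render(nbr, node)}:{ln:.{digits}g}")
                )
            parts.sort()
            return "(" + ",".join(p[1] for p in parts) + ")"

        return render(root, -1) + ";"


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical Saitou-Nei neighbor joining.

    Iteratively joins the pair minimising the Q criterion
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``; branch lengths come from the
    standard closed form, with negative lengths clamped to zero and the
    deficit shifted to the sister branch so the pair distance is
    preserved. Ties in Q break lexicographically on the smallest leaf
    label under each node, making the output deterministic under sample
    permutation.
    """
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    D: Dict[Tuple[int, int], float] = {}
    adjacency: Dict[int, List[Tuple[int, float]]] = {}
    leaf_names: Dict[int, str] = {}
    # sort initial nodes so node order never affects the result
    order = sorted(range(n0), key=lambda i: dm.ids[i])
    keys: Dict[int, str] = {}
    for new_idx, orig in enumerate(order):
        leaf_names[new_idx] = dm.ids[orig]
        keys[new_idx] = dm.ids[orig]
        adjacency[new_idx] = []
    for i in range(n0):
        for j in range(i + 1, n0):
            D[(i, j)] = float(dm.values[order[i], order[j]])
    active = list(range(n0))
    next_id = n0

    def d(i: int, j: int) -> float:
        if i == j:
            return 0.0
        return D[(min(i, j), max(i, j))]

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d(i, k) for k in active) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (n - 2) * d(i, j) - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (n - 2))
        lj = d(i, j) - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = next_id
        next_id += 1
        adjacency[u] = [(i, li), (j, lj)]
        adjacency[i].append((u, li))
        adjacency[j].append((u, lj))
        keys[u] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            D[(min(u, k), max(u, k))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = [k for k in active if k not in (i, j)] + [u]
    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    center = next_id
    adjacency[center] = [(a, la), (b, lb), (c, lc)]
    for node, ln in ((a, la), (b, lb), (c, lc)):
        adjacency[node].append((center, ln))
    return PhyloTree(adjacency=adjacency, leaf_names=leaf_names)
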