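"""Agglomerative Ward clustering of SASA observation vectors.

Observations (whole-protein SASA summary vectors or equal-length
SCR-SASA fingerprints) are compared by Euclidean distance and merged
bottom-up under the Ward criterion: at every step the pair of clusters
whose fusion least increases the total within-cluster variance is
joined.  Distances to a freshly merged cluster follow the
Lance–Williams recurrence on squared distances,

    d²(k, i∪j) = [(nᵢ+nₖ)d²ᵢₖ + (nⱼ+nₖ)d²ⱼₖ − nₖ d²ᵢⱼ] / (nᵢ+nⱼ+nₖ),

with merge heights reported as the (root) Ward distance itself, so two
singletons at Euclidean distance d merge at height d.  Ward linkage is
reducible, hence heights are non-decreasing and the dendrogram has no
inversions; ties are broken towards the smallest (i, j) index pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistanceMatrix",
    "LinkageTree",
    "euclidean_distances",
    "ward_linkage",
    "to_newick",
    "cophenetic_heights",
    "similarity_percent",
    "cut_tree",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = self.d
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class LinkageTree:
    """Merge list of an agglomerative clustering.

    ``merges[k] = (left, right, height, size)`` joins nodes *left* and
    *right* into node ``n_leaves + k``; leaves are nodes 0..n-1 in label
    order.  Heights are non-decreasing.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("need exactly n-1 merges for n leaves")
        prev = -np.inf
        for left, right, height, size in self.merges:
            if height < prev - 1e-9:
                raise ValueError("merge heights decrease (inversion)")
            prev = max(prev, height)


def euclidean_distances(
    vectors: dict[str, np.ndarray] | list[tuple[str, np.ndarray]]
) -> DistanceMatrix:
    """Pairwise Euclidean distance matrix over labelled vectors."""
    items = list(vectors.items()) if isinstance(vectors, dict) else list(vectors)
    if len(items) < 2:
        raise ValueError("need at least two vectors")
    labels = tuple(lab for lab, _ in items)
    arrs = [np.asarray(v, dtype=float) for _, v in items]
    lengths = {a.shape for a in arrs}
    if len(lengths) != 1:
        detail = ", ".join(f"{lab}: {a.shape[0]}" for lab, a in zip(labels, arrs))
        raise ValueError(f"vector length mismatch ({detail})")
    x = np.vstack(arrs)
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, d=d)


def ward_linkage(dm: DistanceMatrix) -> LinkageTree:
    """Agglomerative Ward clustering via the Lance–Williams recurrence."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two leaves")
    d2 = dm.d.astype(float) ** 2
    # active cluster bookkeeping: node id and size per active slot
    node_of = list(range(n))
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_node = n
    d2 = d2.copy()

    for _ in range(n - 1):
        # pick the minimal-distance active pair; ties -> smallest (i, j)
        best = None
        for ai in range(len(active)):
            i = active[ai]
            for aj in range(ai + 1, len(active)):
                j = active[aj]
                val = d2[i, j]
                if best is None or val < best[0] - 1e-15:
                    best = (val, i, j)
        assert best is not None
        val, i, j = best
        ni, nj = sizes[i], sizes[j]
        height = float(np.sqrt(max(val, 0.0)))
        merges.append((node_of[i], node_of[j], height, ni + nj))
        # Lance-Williams update into slot i
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            new = ((ni + nk) * d2[i, k] + (nj + nk) * d2[j, k]
                   - nk * d2[i, j]) / (ni + nj + nk)
            d2[i, k] = d2[k, i] = new
        sizes[i] = ni + nj
        node_of[i] = next_node
        next_node += 1
        active.remove(j)

    return LinkageTree(labels=dm.labels, merges=tuple(merges))


def _children(t: LinkageTree) -> dict[int, tuple[int, int, float]]:
    out = {}
    for k, (left, right, height, _) in enumerate(t.merges):
        out[t.n_leaves + k] = (left, right, height)
    return out


def _node_height(t: LinkageTree, node: int) -> float:
    if node < t.n_leaves:
        return 0.0
    return t.merges[node - t.n_leaves][2]


def to_newick(t: LinkageTree, precision: int = 6) -> str:
    """Serialise the dendrogram to Newick with ultrametric branch lengths.

    Node elevations are half the merge height (midpoint convention), so a
    two-leaf tree of height 4 renders as ``(a:2.0,b:2.0);``.
    """
    children = _children(t)

    def render(node: int) -> str:
        elev = _node_height(t, node) / 2.0
        if node < t.n_leaves:
            return t.labels[node], elev
        left, right, _ = children[node]
        ls, le = render(left)
        rs, re = render(right)
        lb = round(elev - le, precision)
        rb = round(elev - re, precision)
        return f"({ls}:{lb},{rs}:{rb})", elev

    body, _ = render(t.n_leaves + len(t.merges) - 1) if t.merges else (t.labels[0], 0)
    return body + ";"


def cophenetic_heights(t: LinkageTree) -> dict[tuple[str, str], float]:
    """Dendrogram height at which each leaf pair first joins."""
    members: dict[int, list[int]] = {i: [i] for i in range(t.n_leaves)}
    heights: dict[tuple[str, str], float] = {}
    for k, (left, right, height, _) in enumerate(t.merges):
        for a in members[left]:
            for b in members[right]:
                i, j = sorted((a, b))
                heights[(t.labels[i], t.labels[j])] = height
        members[t.n_leaves + k] = members.pop(left) + members.pop(right)
    return heights


def similarity_percent(
    t: LinkageTree,
    transform=None,
) -> dict[tuple[str, str], float]:
    """Pairwise similarity percentages from cophenetic heights.

    The default transform is ``100 * (1 - h / h_root)``: pairs merging at
    the root score 0 %, identical observations (height 0) score 100 %.
    A custom ``transform(height, root_height) -> percent`` may be given.
    """
    root = t.root_height
    if transform is None:
        def transform(h: float, root: float) -> float:
            return 100.0 if root == 0 else 100.0 * (1.0 - h / root)
    return {
        pair: transform(h, root)
        for pair, h in cophenetic_heights(t).items()
    }


def cut_tree(t: LinkageTree, k: int) -> dict[str, int]:
    """Flat clustering with *k* clusters: undo the last k-1 merges."""
    if not 1 <= k <= t.n_leaves:
        raise ValueError(f"k must be in [1, {t.n_leaves}]")
    parent = {}
    for m, (left, right, _, _) in enumerate(t.merges[: t.n_leaves - k]):
        parent[left] = parent[right] = t.n_leaves + m

    def find(node: int) -> int:
        while node in parent:
            node = parent[node]
        return node

    roots: dict[int, int] = {}
    out = {}
    for i, lab in enumerate(t.labels):
        r = find(i)
        roots.setdefault(r, len(roots))
        out[lab] = roots[r]
    return out
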