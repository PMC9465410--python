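"""Agglomerative hierarchical clustering of similarity matrices.

Similarities are first mapped to distances (1 - s for the bounded Tanimoto /
PathSim kinds; an order-preserving affine shift s - min(s) for the unbounded
separation kind), then merged bottom-up with average (default), complete or
single linkage. The merge sequence uses the Lance-Williams updates with a
deterministic tie-break — among equally close pairs the lexicographically
smallest (i, j) merges first — so runs are exactly reproducible.

The dendrogram follows the usual encoding: leaves are 0..N-1, the cluster
created by merge t gets id N+t. `cut` flattens to k clusters and `to_newick`
exports the ultrametric tree (a node's children hang at half the merge
height) for standard tree tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix

__all__ = ["Dendrogram", "to_distance", "linkage", "cut", "to_newick"]

LINKAGE_METHODS = ("average", "complete", "single")


@dataclass
class Dendrogram:
    """Merge sequence (cluster_i, cluster_j, height) over labeled leaves."""

    merges: list[tuple[int, int, float]]
    labels: list[str]

    def __post_init__(self):
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])


def to_distance(m: SimilarityMatrix) -> np.ndarray:
    """Similarity -> distance: 1 - s for bounded kinds, affine shift for separation.

    Both transforms are monotone decreasing in similarity, so the merge order
    is driven by the same geometry the similarity expressed. The diagonal is
    forced to zero.
    """
    s = m.values
    if m.kind in ("tanimoto", "pathsim"):
        d = 1.0 - s
    elif m.kind == "separation":
        # smaller S_AB = more similar, so S_AB is already a dissimilarity;
        # shift so the smallest entry maps to distance 0
        d = s - s.min()
    else:  # pragma: no cover - SimilarityMatrix already validates kinds
        raise ValueError(f"unknown kind {m.kind!r}")
    d = d.copy()
    np.fill_diagonal(d, 0.0)
    return d


def linkage(d: np.ndarray, labels: list[str], method: str = "average") -> Dendrogram:
    """Naive O(N^3) agglomerative merge sequence with exact tie-breaking."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}")
    if len(labels) != n:
        raise ValueError("labels length mismatch")

    # active cluster id -> index into the working distance matrix
    dist = d.astype(float).copy()
    cluster_ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float]] = []

    for t in range(n - 1):
        m = len(cluster_ids)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (dist[a, b], cluster_ids[a], cluster_ids[b])
                if best is None or key < best:
                    best = key
                    pair = (a, b)
        a, b = pair
        height = best[0]
        ca, cb = cluster_ids[a], cluster_ids[b]
        new_id = n + t
        merges.append((ca, cb, float(height)))

        # Lance-Williams update of distances to the merged cluster
        na, nb = sizes[ca], sizes[cb]
        rest = [k for k in range(m) if k not in (a, b)]
        if method == "average":
            new_row = (na * dist[a, rest] + nb * dist[b, rest]) / (na + nb)
        elif method == "complete":
            new_row = np.maximum(dist[a, rest], dist[b, rest])
        else:
            new_row = np.minimum(dist[a, rest], dist[b, rest])

        keep = np.array(rest, dtype=int)
        dist = dist[np.ix_(keep, keep)]
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row
        dist[:-1, -1] = new_row
        cluster_ids = [cluster_ids[k] for k in rest] + [new_id]
        sizes[new_id] = na + nb

    return Dendrogram(merges, list(labels))


def cut(dend: Dendrogram, k: int) -> dict[str, int]:
    """Flat cluster labels from stopping the merge sequence at k clusters.

    Cluster ids are renumbered 0..k-1 in order of first appearance along the
    leaf order, so the labeling is stable under reruns.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (i, j, _h) in enumerate(dend.merges[: n - k]):
        parent[find(i)] = parent[find(j)] = n + t

    renumber: dict[int, int] = {}
    out: dict[str, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in renumber:
            renumber[root] = len(renumber)
        out[dend.labels[leaf]] = renumber[root]
    return out


def to_newick(dend: Dendrogram) -> str:
    """Newick export; children hang at half the merge height (ultrametric)."""
    n = dend.n_leaves
    height = {i: 0.0 for i in range(n)}
    rep: dict[int, str] = {}

    def node_str(cid: int, parent_h: float) -> str:
        bl = parent_h / 2.0 - height[cid] / 2.0
        return f"{rep[cid]}:{bl}"

    for i in range(n):
        rep[i] = dend.labels[i]
    for t, (i, j, h) in enumerate(dend.merges):
        cid = n + t
        rep[cid] = f"({node_str(i, h)},{node_str(j, h)})"
        height[cid] = h
    root = 2 * n - 2
    return rep[root] + ";"
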