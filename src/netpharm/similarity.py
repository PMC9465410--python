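"""Three drug-similarity fingerprints over a common compound panel.

1. *Chemical structure*: Tanimoto coefficient |a AND b| / |a OR b| on binary
   substructure fingerprints.
2. *Target-module proximity*: the network-medicine separation measure

       S_AB = <d_AB> - (<d_AA> + <d_BB>) / 2

   on the interactome, comparing the mean shortest distance between two
   drugs' target modules to the mean within-module distances. Smaller S_AB
   means topologically closer target modules, hence more similar drugs.
   Distances are unweighted hop counts with the closest-member convention:
   <d_AA> averages, over members of A, the distance to the nearest *other*
   member (0 for singletons); <d_AB> averages, over all nodes of A and B, the
   distance to the nearest member of the opposite set (shared nodes count 0).
3. *Cellular function*: PathSim on the heterogeneous
   compound-target-function network under the symmetric metapath
   compound -> target -> function -> target -> compound. With C the
   compound x target incidence and F the target x function incidence, the
   metapath commuting matrix is M = (CF)(CF)^T and
   s(x, y) = 2 M_xy / (M_xx + M_yy).

Each measure fills an N x N labeled similarity matrix ready for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph_io import BipartiteIncidence, FingerprintSet, GeneSet

__all__ = [
    "SimilarityMatrix",
    "SeparationResult",
    "tanimoto",
    "pairwise_tanimoto",
    "separation",
    "pairwise_target_similarity",
    "pathsim_matrix",
]

KINDS = ("tanimoto", "separation", "pathsim")


@dataclass
class SimilarityMatrix:
    """Symmetric labeled N x N similarity values of one kind."""

    labels: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")
        if self.kind in ("tanimoto", "pathsim"):
            if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
                raise ValueError(f"{self.kind} values must lie in [0,1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str) -> "SimilarityMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(list(df.index), df.values, kind)


@dataclass
class SeparationResult:
    """S_AB and its three distance components."""

    s_ab: float
    d_ab: float
    d_aa: float
    d_bb: float

    def __post_init__(self):
        expected = self.d_ab - (self.d_aa + self.d_bb) / 2.0
        if abs(self.s_ab - expected) > 1e-12:
            raise ValueError("s_ab inconsistent with its components")


# ---------------------------------------------------------------------------
# Tanimoto


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient of two equal-length bit vectors.

    Two all-zero vectors are identical objects, hence similarity 1; an
    all-zero vector against a nonzero one shares nothing, hence 0.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def pairwise_tanimoto(fps: FingerprintSet) -> SimilarityMatrix:
    """Tanimoto similarity matrix over all compounds of a fingerprint set."""
    labels = fps.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 fingerprints")
    x = np.stack([fps[l].astype(bool) for l in labels]).astype(float)
    inter = x @ x.T
    ones = x.sum(axis=1)
    union = ones[:, None] + ones[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return SimilarityMatrix(labels, s, "tanimoto")


# ---------------------------------------------------------------------------
# interactome separation S_AB


def _present(g: nx.Graph, s: GeneSet) -> list[str]:
    members = sorted(m for m in s.members if m in g)
    if not members:
        raise ValueError(f"no member of {s.name!r} is present in the graph")
    return members


def _nearest_to_set(g: nx.Graph, sources: list[str]) -> dict[str, int]:
    """Hop distance from every reachable node to the nearest source node."""
    return nx.multi_source_dijkstra_path_length(g, sources, weight=lambda *_: 1)


def _mean_within(g: nx.Graph, members: list[str]) -> float:
    """Mean over members of the distance to the nearest other member; 0 for singletons."""
    if len(members) == 1:
        return 0.0
    member_set = set(members)
    dists = []
    for a in members:
        lengths = nx.single_source_shortest_path_length(g, a)
        best = min((d for n, d in lengths.items() if n in member_set and n != a), default=None)
        if best is None:
            raise ValueError(f"node {a!r} cannot reach any other module member")
        dists.append(best)
    return float(np.mean(dists))


def separation(g: nx.Graph, set_a: GeneSet, set_b: GeneSet) -> SeparationResult:
    """Network separation S_AB of two target modules on the interactome."""
    a = _present(g, set_a)
    b = _present(g, set_b)
    to_b = _nearest_to_set(g, b)
    to_a = _nearest_to_set(g, a)
    unreachable = [n for n in a if n not in to_b] + [n for n in b if n not in to_a]
    if unreachable:
        raise ValueError(f"nodes unreachable from the opposite module: {unreachable[:10]}")
    cross = [to_b[n] for n in a] + [to_a[n] for n in b]
    d_ab = float(np.mean(cross))
    d_aa = _mean_within(g, a)
    d_bb = _mean_within(g, b)
    return SeparationResult(d_ab - (d_aa + d_bb) / 2.0, d_ab, d_aa, d_bb)


def pairwise_target_similarity(g: nx.Graph, target_sets: list[GeneSet]) -> SimilarityMatrix:
    """S_AB matrix over a panel of drug target modules (diagonal = S_AA)."""
    if len(target_sets) < 2:
        raise ValueError("need at least 2 target sets")
    labels = [s.name for s in target_sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate target-set names")
    n = len(target_sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = separation(g, target_sets[i], target_sets[j]).s_ab
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(labels, values, "separation")


# ---------------------------------------------------------------------------
# PathSim on the compound-target-function metapath


def pathsim_matrix(ct: BipartiteIncidence, tf: BipartiteIncidence) -> SimilarityMatrix:
    """PathSim similarity of compounds along compound-target-function-target-compound.

    M = (C F)(C F)^T counts metapath instances between compound pairs;
    s(x,y) = 2 M_xy / (M_xx + M_yy), 0 when both self-counts vanish, and the
    diagonal is 1 whenever a compound has any path to itself.
    """
    if ct.col_labels != tf.row_labels:
        raise ValueError("compound-target columns do not align with target-function rows")
    if len(ct.row_labels) < 1:
        raise ValueError("need at least one compound")
    cf = ct.values.astype(float) @ tf.values.astype(float)
    m = cf @ cf.T
    diag = np.diag(m)
    denom = diag[:, None] + diag[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, 2.0 * m / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(s, np.where(diag > 0, 1.0, 0.0))
    return SimilarityMatrix(list(ct.row_labels), s, "pathsim")
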