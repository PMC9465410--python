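"""Random Walk with Restart (RWR) over a weighted interactome.

A walker starts on the seed nodes and at every step either restarts (jumps
back to a uniformly chosen seed) with probability r, or moves to a neighbour
with probability proportional to edge weight. The stationary distribution

    p = r * e + (1 - r) * W @ p

(e uniform over seeds, W the column-stochastic transition matrix A D^-1) is
the *influence score vector* of the seed set: a per-node probability mass
measuring network influence. Default restart probability is 0.75.

Propagation requires every node to have at least one neighbour, so callers
restrict to the largest connected component first (`largest_component`);
scores on other components would be identically zero and the downstream
distances infinite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .graph_io import GeneSet

logger = logging.getLogger("netpharm")

__all__ = ["InfluenceVector", "build_transition", "rwr", "RwrSolver", "largest_component"]


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the tolerance within max_iter."""


@dataclass
class InfluenceVector:
    """Stationary RWR probabilities for one seed set.

    Scores are aligned with `nodes` (the sorted node universe of the graph
    the walk ran on), sum to one, and are all non-negative.
    """

    nodes: list[str]
    scores: np.ndarray
    seeds_used: GeneSet
    restart: float
    iterations: int
    residual: float

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.nodes) != len(self.scores):
            raise ValueError("nodes/scores length mismatch")
        if (self.scores < -1e-12).any():
            raise ValueError("negative influence score")
        if abs(self.scores.sum() - 1.0) > 1e-9:
            raise ValueError("influence scores must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.scores))


def largest_component(g: nx.Graph) -> nx.Graph:
    """Subgraph on the largest connected component; logs what was dropped."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)[0]))
    if len(comps) > 1:
        dropped = sum(len(c) for c in comps[1:])
        logger.warning("restricting to largest component: dropped %d node(s)", dropped)
    return g.subgraph(comps[0]).copy()


def _node_order(g: nx.Graph) -> list[str]:
    return sorted(g.nodes)


def build_transition(g: nx.Graph) -> tuple[sp.csr_matrix, list[str]]:
    """Column-stochastic transition operator W = A D^-1 over sorted nodes.

    Column j holds the outgoing probabilities of node j: edge weight divided
    by weighted degree. Isolated nodes have no outgoing move and are an
    error — restrict to the largest component first.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = _node_order(g)
    isolated = [n for n in nodes if g.degree(n) == 0]
    if isolated:
        raise ValueError(f"isolated node(s) with no transitions: {isolated[:10]}")
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csr")
    wdeg = np.asarray(a.sum(axis=0)).ravel()
    w = a @ sp.diags(1.0 / wdeg)
    return sp.csr_matrix(w), nodes


def _seed_vector(nodes: list[str], seeds: GeneSet) -> tuple[np.ndarray, GeneSet]:
    node_idx = {n: i for i, n in enumerate(nodes)}
    mapped = sorted(m for m in seeds.members if m in node_idx)
    missing = len(seeds) - len(mapped)
    if not mapped:
        raise ValueError(f"no seed of {seeds.name!r} maps to the graph")
    if missing:
        logger.warning("%s: %d seed(s) absent from the graph dropped", seeds.name, missing)
    e = np.zeros(len(nodes))
    e[[node_idx[m] for m in mapped]] = 1.0 / len(mapped)
    used = GeneSet(seeds.name, frozenset(mapped), seeds.description)
    return e, used


def rwr(
    g: nx.Graph,
    seeds: GeneSet,
    restart: float = 0.75,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> InfluenceVector:
    """Iterate p <- r e + (1-r) W p to the stationary influence vector.

    Stops when the L1 change between iterates drops below `tol`; raises
    ConvergenceError (carrying the residual) if max_iter is hit first. Seeds
    absent from the graph are dropped with a warning and recorded in
    `seeds_used`.
    """
    if not 0.0 < restart < 1.0:
        raise ValueError(f"restart must be in (0,1), got {restart}")
    w, nodes = build_transition(g)
    e, used = _seed_vector(nodes, seeds)
    p = e.copy()
    for it in range(1, max_iter + 1):
        p_next = restart * e + (1.0 - restart) * (w @ p)
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < tol:
            return InfluenceVector(nodes, p, used, restart, it, delta)
    raise ConvergenceError(f"RWR did not converge in {max_iter} iterations (residual {delta:g})")


class RwrSolver:
    """Exact RWR fixed points by a pre-factorized linear solve.

    The stationary vector solves (I - (1-r) W) p = r e; one LU factorization
    of that matrix turns each seed set (or a whole batch of seed vectors)
    into a triangular solve. Identical fixed point as the power iteration —
    used where many influence vectors are needed on the same graph, e.g. the
    permutation null.
    """

    def __init__(self, g: nx.Graph, restart: float = 0.75):
        if not 0.0 < restart < 1.0:
            raise ValueError(f"restart must be in (0,1), got {restart}")
        w, nodes = build_transition(g)
        self.nodes = nodes
        self.restart = restart
        m = np.eye(len(nodes)) - (1.0 - restart) * w.toarray()
        self._lu = scipy.linalg.lu_factor(m)
        self._node_idx = {n: i for i, n in enumerate(nodes)}

    def influence(self, seeds: GeneSet) -> InfluenceVector:
        e, used = _seed_vector(self.nodes, seeds)
        p = scipy.linalg.lu_solve(self._lu, self.restart * e)
        p = np.maximum(p, 0.0)
        p /= p.sum()
        return InfluenceVector(self.nodes, p, used, self.restart, 0, 0.0)

    def influence_batch(self, seed_index_sets: list[np.ndarray]) -> np.ndarray:
        """Influence vectors for many index-based seed sets, one matrix solve.

        Returns an (n_nodes, n_sets) array of stationary probabilities.
        """
        n = len(self.nodes)
        e = np.zeros((n, len(seed_index_sets)))
        for j, idx in enumerate(seed_index_sets):
            e[idx, j] = 1.0 / len(idx)
        p = scipy.linalg.lu_solve(self._lu, self.restart * e)
        p = np.maximum(p, 0.0)
        return p / p.sum(axis=0, keepdims=True)
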