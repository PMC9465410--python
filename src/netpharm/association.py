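"""Drug-disease association: correlated network influence plus a permutation Z.

The association statistic asks whether a drug's targets and a disease's genes
influence the same parts of the interactome. Both sets are propagated by RWR;
the Pearson correlation Cor of the two influence vectors (over all nodes of
the component, seeds included) is then standardized against a permutation
null:

    Z = (Cor - E(Cor)) / sd(Cor)

where the null is built from random contrast disease sets — groups of
uniformly drawn nodes of the same size as the disease seed set (default
1,000 groups), each propagated and correlated with the (cached) drug vector.
Only the disease side is randomized. Z > 3 is the conventional significance
call.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_io import GeneSet
from .propagation import InfluenceVector, RwrSolver

__all__ = [
    "NullDistribution",
    "AssociationResult",
    "influence_correlation",
    "permutation_null",
    "associate",
]

Z_SIGNIFICANCE = 3.0


@dataclass
class NullDistribution:
    """Null Pearson correlations from random contrast disease sets."""

    correlations: np.ndarray
    n_perm: int
    rng_seed: int

    def __post_init__(self):
        self.correlations = np.asarray(self.correlations, dtype=float)
        if len(self.correlations) != self.n_perm:
            raise ValueError("null length != n_perm")

    @property
    def mean(self) -> float:
        return float(self.correlations.mean())

    @property
    def sd(self) -> float:
        return float(self.correlations.std(ddof=1))


@dataclass
class AssociationResult:
    cor: float
    z: float
    null: NullDistribution
    significant: bool
    z_threshold: float = Z_SIGNIFICANCE

    def summary(self) -> dict:
        return {
            "cor": self.cor,
            "z": self.z,
            "null_mean": self.null.mean,
            "null_sd": self.null.sd,
            "n_perm": self.null.n_perm,
            "z_threshold": self.z_threshold,
            "significant": self.significant,
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in an influence vector")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def influence_correlation(p_drug: InfluenceVector, p_disease: InfluenceVector) -> float:
    """Pearson correlation of two influence vectors over the same node universe."""
    if p_drug.nodes != p_disease.nodes:
        raise ValueError("influence vectors are over different node universes")
    return _pearson(p_drug.scores, p_disease.scores)


def _null_correlations(
    solver: RwrSolver, drug_scores: np.ndarray, disease_size: int, n_perm: int, rng
) -> np.ndarray:
    """Correlations of the drug vector with n_perm uniform-random contrast sets."""
    n = len(solver.nodes)
    idx_sets = [rng.choice(n, size=disease_size, replace=False) for _ in range(n_perm)]
    p = solver.influence_batch(idx_sets)  # (n_nodes, n_perm)
    xc = drug_scores - drug_scores.mean()
    sx = np.sqrt((xc * xc).sum())
    yc = p - p.mean(axis=0, keepdims=True)
    sy = np.sqrt((yc * yc).sum(axis=0))
    if sx == 0.0 or (sy == 0.0).any():
        raise ValueError("zero variance in an influence vector")
    return np.clip(xc @ yc / (sx * sy), -1.0, 1.0)


def permutation_null(
    g: nx.Graph,
    drug_targets: GeneSet,
    disease_size: int,
    n_perm: int = 1000,
    restart: float = 0.75,
    rng_seed: int = 0,
    solver: RwrSolver | None = None,
) -> NullDistribution:
    """Null distribution of Cor against random same-size disease sets.

    Each replicate draws `disease_size` nodes uniformly without replacement,
    propagates them, and correlates with the drug influence vector (computed
    once). Deterministic for a fixed rng_seed.
    """
    if disease_size < 1:
        raise ValueError("disease_size must be >= 1")
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if solver is None:
        solver = RwrSolver(g, restart)
    if disease_size > len(solver.nodes):
        raise ValueError("disease_size exceeds the number of graph nodes")
    rng = np.random.default_rng(rng_seed)
    drug_vec = solver.influence(drug_targets)
    cors = _null_correlations(solver, drug_vec.scores, disease_size, n_perm, rng)
    return NullDistribution(cors, n_perm, rng_seed)


def associate(
    g: nx.Graph,
    drug_targets: GeneSet,
    disease_genes: GeneSet,
    n_perm: int = 1000,
    restart: float = 0.75,
    rng_seed: int = 0,
    z_threshold: float = Z_SIGNIFICANCE,
    solver: RwrSolver | None = None,
) -> AssociationResult:
    """Full association: observed Cor, permutation null, Z-score, call at Z>3."""
    if solver is None:
        solver = RwrSolver(g, restart)
    drug_vec = solver.influence(drug_targets)
    disease_vec = solver.influence(disease_genes)
    cor = _pearson(drug_vec.scores, disease_vec.scores)
    null = permutation_null(
        g,
        drug_targets,
        disease_size=len(disease_vec.seeds_used),
        n_perm=n_perm,
        restart=restart,
        rng_seed=rng_seed,
        solver=solver,
    )
    if null.sd == 0.0:
        raise ValueError("degenerate null: zero standard deviation")
    z = (cor - null.mean) / null.sd
    return AssociationResult(cor, z, null, significant=z > z_threshold, z_threshold=z_threshold)
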