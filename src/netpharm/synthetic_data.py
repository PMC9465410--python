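"""Synthetic inputs with the statistical structure the pipeline assumes.

Real network-pharmacology studies run on a protein interactome of ~1.6e4
nodes, curated drug-target and disease gene sets, compound annotation
databases and extracted clinical-trial tables. None of those are
redistributable here, so every stage consumes instances from this module
instead:

* a scale-free (preferential-attachment) interactome, because the behaviour
  of propagation-based association statistics depends on hubs;
* drug-target / disease-gene seed sets with a *tunable planted proximity*,
  so association recovery can be measured against ground truth;
* bipartite compound-target and target-function annotations with planted
  compound groups, for similarity/clustering recovery;
* structure fingerprints as bit vectors mutated from group prototypes;
* ranked gene lists with a planted up-shifted set, for enrichment;
* per-study effect tables with controllable between-study variance tau^2,
  for the meta-analysis engine.

All generators are pure functions of their configuration, including the
integer seed: reruns are bit-identical and no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph_io import BipartiteIncidence, FingerprintSet, GeneSet, RankedList, StudyTable

__all__ = [
    "SimConfig",
    "gen_interactome",
    "gen_seed_sets",
    "gen_annotations",
    "gen_fingerprints",
    "gen_ranked_list",
    "gen_meta_studies",
]


class ConfigurationError(ValueError):
    """An invalid simulation configuration."""


@dataclass
class SimConfig:
    """Knobs for every generator; defaults define the study conditions.

    The interactome is a reduced-scale stand-in for a curated PPI background
    (hundreds of nodes instead of ~16k, same heavy-tailed degree shape).
    `proximity` is the fraction of drug targets drawn from the 1-hop closure
    of the disease module: 1.0 plants a drug whose targets sit on top of the
    disease neighbourhood, 0.0 a drug with uniformly remote targets.
    `true_effect` and `tau2` set the mean and between-study variance of the
    per-study true effects for the meta-analysis generator; the default
    emulates a ~30-trial continuous-outcome synthesis of blood-flow-velocity
    mean differences.
    """

    n_nodes: int = 500
    edges_per_node: int = 2
    seed: int = 0
    module_size: int = 25
    proximity: float = 0.9
    n_compounds: int = 12
    n_targets: int = 30
    n_functions: int = 12
    n_groups: int = 3
    fp_bits: int = 256
    fp_density: float = 0.2
    fp_flip_rate: float = 0.02
    tau2: float = 1.0
    n_studies: int = 30
    true_effect: float = 4.89
    study_kind: str = "continuous"

    def __post_init__(self):
        counts = {
            "n_nodes": self.n_nodes,
            "edges_per_node": self.edges_per_node,
            "module_size": self.module_size,
            "n_compounds": self.n_compounds,
            "n_targets": self.n_targets,
            "n_functions": self.n_functions,
            "n_groups": self.n_groups,
            "fp_bits": self.fp_bits,
            "n_studies": self.n_studies,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if not 0.0 <= self.proximity <= 1.0:
            raise ConfigurationError(f"proximity must be in [0,1], got {self.proximity}")
        if self.tau2 < 0:
            raise ConfigurationError(f"tau2 must be >= 0, got {self.tau2}")
        if not 0.0 <= self.fp_flip_rate < 0.5:
            raise ConfigurationError("fp_flip_rate must be in [0, 0.5)")
        if self.study_kind not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown study_kind {self.study_kind!r}")


def gen_interactome(cfg: SimConfig) -> nx.Graph:
    """Scale-free background network via Barabasi-Albert preferential attachment.

    Connected, undirected, simple (no self-loops or parallel edges), with unit
    edge weights and a heavy-tailed degree distribution dominated by hubs —
    the topology feature propagation statistics are sensitive to.
    """
    if cfg.n_nodes < cfg.edges_per_node + 1:
        raise ConfigurationError("n_nodes must be >= edges_per_node + 1")
    g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.edges_per_node, seed=cfg.seed)
    width = len(str(cfg.n_nodes - 1))
    mapping = {i: f"g{i:0{width}d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


def gen_seed_sets(g: nx.Graph, cfg: SimConfig) -> tuple[GeneSet, GeneSet]:
    """Plant a disease module and a drug-target set at tunable proximity.

    The disease module is a connected BFS ball of `module_size` nodes around a
    random root (disease genes cluster in interactomes). The drug-target set
    has the same size: round(proximity * module_size) members come from the
    ball's 1-hop closure, the rest are uniform over nodes outside that
    closure. Near-targets are sampled by first picking a ball member and then
    one of its closed neighbours (uniform over member/neighbour pairs), so
    the planted signal concentrates around the module mass rather than being
    diluted when a hub inflates the closure. Overlap with the disease module
    is permitted (proximity near 1) and simply recorded by the caller if
    needed.
    """
    nodes = sorted(g.nodes)
    if cfg.module_size >= len(nodes) / 2:
        raise ConfigurationError("module_size must be < n_nodes / 2")
    rng = np.random.default_rng(cfg.seed)
    root = nodes[rng.integers(len(nodes))]

    # BFS ball: take nodes in breadth-first order until the module is full
    ball: list[str] = []
    for node in nx.bfs_tree(g, root):
        ball.append(node)
        if len(ball) == cfg.module_size:
            break
    ball_set = set(ball)
    ball_sorted = sorted(ball_set)

    closure = set(ball_set)
    for node in ball_set:
        closure.update(g.neighbors(node))
    far_pool = sorted(set(nodes) - closure)

    n_near = round(cfg.proximity * cfg.module_size)
    n_far = cfg.module_size - n_near
    if n_far > len(far_pool):
        raise ConfigurationError("not enough nodes outside the disease neighbourhood")

    near: set[str] = set()
    tries = 0
    while len(near) < n_near and tries < 100 * n_near:
        member = ball_sorted[rng.integers(len(ball_sorted))]
        candidates = sorted({member, *g.neighbors(member)})
        near.add(candidates[rng.integers(len(candidates))])
        tries += 1
    if len(near) < n_near:  # pathological graph: top up deterministically
        for node in sorted(closure - near):
            near.add(node)
            if len(near) == n_near:
                break
    far = list(rng.choice(far_pool, size=n_far, replace=False))
    drug = GeneSet("drug_targets", frozenset(list(near) + far), "planted drug-target set")
    disease = GeneSet("disease_genes", frozenset(ball_set), "planted disease module")
    return drug, disease


def _group_labels(cfg: SimConfig) -> list[int]:
    """Compound group assignment: contiguous blocks, remainder to early groups."""
    base = cfg.n_compounds // cfg.n_groups
    sizes = [base + (1 if i < cfg.n_compounds % cfg.n_groups else 0) for i in range(cfg.n_groups)]
    labels: list[int] = []
    for grp, size in enumerate(sizes):
        labels.extend([grp] * size)
    return labels


def compound_labels(cfg: SimConfig) -> list[str]:
    return [f"cpd{i:02d}" for i in range(cfg.n_compounds)]


def gen_annotations(cfg: SimConfig) -> tuple[BipartiteIncidence, BipartiteIncidence]:
    """Planted-group compound-target and target-function incidences.

    Targets and functions are partitioned into one block per planted compound
    group. A compound links densely (p=0.9) to its own group's target block
    and sparsely (p=0.05) elsewhere; targets link to their block's functions
    the same way. Rows are guaranteed non-empty so downstream metapath counts
    are defined for every compound.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    groups = _group_labels(cfg)
    cpds = compound_labels(cfg)
    targets = [f"t{i:02d}" for i in range(cfg.n_targets)]
    functions = [f"f{i:02d}" for i in range(cfg.n_functions)]

    t_block = np.array([min(i * cfg.n_groups // cfg.n_targets, cfg.n_groups - 1) for i in range(cfg.n_targets)])
    f_block = np.array([min(i * cfg.n_groups // cfg.n_functions, cfg.n_groups - 1) for i in range(cfg.n_functions)])

    def planted(n_rows, row_groups, n_cols, col_blocks):
        m = np.zeros((n_rows, n_cols), dtype=np.int8)
        for i in range(n_rows):
            own = col_blocks == row_groups[i]
            m[i, own] = rng.random(own.sum()) < 0.9
            m[i, ~own] = rng.random((~own).sum()) < 0.05
            if m[i].sum() == 0:  # every row must touch something
                cols = np.flatnonzero(own)
                m[i, cols[rng.integers(len(cols))]] = 1
        return m

    ct = planted(cfg.n_compounds, np.array(groups), cfg.n_targets, t_block)
    tf = planted(cfg.n_targets, t_block, cfg.n_functions, f_block)
    return (
        BipartiteIncidence(cpds, targets, ct),
        BipartiteIncidence(targets, functions, tf),
    )


def gen_fingerprints(cfg: SimConfig, groups: list[int] | None = None) -> FingerprintSet:
    """Structure fingerprints: group prototypes mutated at a low flip rate.

    Each group draws an independent Bernoulli(fp_density) prototype; members
    flip each bit independently with probability fp_flip_rate. Within-group
    Tanimoto therefore concentrates near 1 for small flip rates while
    between-group Tanimoto sits at the density-determined baseline
    d/(2-d) in expectation for independent prototypes of density d.
    """
    if cfg.fp_bits < 8:
        raise ConfigurationError("fp_bits must be >= 8")
    if groups is None:
        groups = _group_labels(cfg)
    if len(groups) != cfg.n_compounds:
        raise ConfigurationError("group labels must cover every compound")
    rng = np.random.default_rng(cfg.seed + 2)
    protos = {
        grp: (rng.random(cfg.fp_bits) < cfg.fp_density).astype(np.uint8)
        for grp in sorted(set(groups))
    }
    bits = {}
    for label, grp in zip(compound_labels(cfg), groups):
        flips = rng.random(cfg.fp_bits) < cfg.fp_flip_rate
        bits[label] = np.where(flips, 1 - protos[grp], protos[grp]).astype(np.uint8)
    return FingerprintSet(bits)


def map_targets_to_nodes(g: nx.Graph, cfg: SimConfig) -> dict[str, str]:
    """Place annotation targets on interactome nodes, one BFS ball per group.

    Group roots are chosen greedily to be pairwise distant, then each group's
    target block is assigned to distinct nodes of a BFS ball around its root.
    Compounds of the same planted group therefore carry target modules that
    are topologically close, giving the separation fingerprint the same
    planted structure as the annotation and structure fingerprints.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    nodes = sorted(g.nodes)
    # same block partition as gen_annotations
    t_block = [min(i * cfg.n_groups // cfg.n_targets, cfg.n_groups - 1) for i in range(cfg.n_targets)]
    block = [t_block.count(grp) for grp in range(cfg.n_groups)]
    if max(block) > len(nodes) // cfg.n_groups:
        raise ConfigurationError("graph too small for the requested target blocks")

    roots = [nodes[rng.integers(len(nodes))]]
    for _ in range(1, cfg.n_groups):
        dists = np.full(len(nodes), np.inf)
        for r in roots:
            lengths = nx.single_source_shortest_path_length(g, r)
            for i, n in enumerate(nodes):
                dists[i] = min(dists[i], lengths.get(n, np.inf))
        roots.append(nodes[int(np.argmax(dists))])

    mapping: dict[str, str] = {}
    used: set[str] = set()
    t_idx = 0
    for grp, size in enumerate(block):
        ball = []
        for node in nx.bfs_tree(g, roots[grp]):
            if node not in used:
                ball.append(node)
            if len(ball) == size:
                break
        if len(ball) < size:
            raise ConfigurationError("graph too small for the requested target blocks")
        used.update(ball)
        for node in ball:
            mapping[f"t{t_idx:02d}"] = node
            t_idx += 1
    return mapping


def compound_target_sets(ct: "BipartiteIncidence", node_map: dict[str, str]) -> list[GeneSet]:
    """Per-compound target modules as interactome gene sets."""
    sets = []
    for i, cpd in enumerate(ct.row_labels):
        members = {node_map[t] for t, hit in zip(ct.col_labels, ct.values[i]) if hit}
        sets.append(GeneSet(cpd, frozenset(members), "compound target module"))
    return sets


def gen_ranked_list(
    n_genes: int, planted_set_size: int, shift: float, seed: int
) -> tuple[RankedList, GeneSet]:
    """Standard-normal gene scores with a planted set shifted by +shift.

    Returns the descending ranked list and the planted set, so enrichment
    recovery can be scored against ground truth. shift=0 leaves the planted
    genes exchangeable with the rest (uniform over ranks).
    """
    if planted_set_size >= n_genes:
        raise ConfigurationError("planted_set_size must be < n_genes")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes - 1))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    scores = rng.standard_normal(n_genes)
    planted_idx = rng.choice(n_genes, size=planted_set_size, replace=False)
    scores[planted_idx] += shift
    planted = GeneSet("planted", frozenset(genes[i] for i in planted_idx), f"shift={shift}")
    return RankedList(genes, scores), planted


def gen_meta_studies(cfg: SimConfig) -> StudyTable:
    """Per-study summaries with between-study heterogeneity tau^2.

    Study-level true effects are theta_i ~ Normal(true_effect, tau2).
    Continuous tables report arm means/SDs/sizes drawn so the study mean
    difference is an unbiased estimate of theta_i (observed SDs drawn from
    the chi-square sampling distribution). The binary variant links the risk
    ratio to theta_i on the log scale: p_e = p_c * exp(theta_i), baseline
    risk 0.3, and reports 2x2 event counts.
    """
    if cfg.n_studies < 2:
        raise ConfigurationError("n_studies must be >= 2")
    rng = np.random.default_rng(cfg.seed + 3)
    theta = rng.normal(cfg.true_effect, np.sqrt(cfg.tau2), size=cfg.n_studies)
    rows = []
    if cfg.study_kind == "continuous":
        for i, th in enumerate(theta):
            n_e = int(rng.integers(30, 101))
            n_c = int(rng.integers(30, 101))
            sd_true = rng.uniform(4.0, 8.0)
            mean_c = rng.normal(20.0, sd_true / np.sqrt(n_c))
            mean_e = rng.normal(20.0 + th, sd_true / np.sqrt(n_e))
            sd_e = sd_true * np.sqrt(rng.chisquare(n_e - 1) / (n_e - 1))
            sd_c = sd_true * np.sqrt(rng.chisquare(n_c - 1) / (n_c - 1))
            rows.append(
                dict(study=f"study{i:02d}", n_e=n_e, mean_e=mean_e, sd_e=sd_e,
                     n_c=n_c, mean_c=mean_c, sd_c=sd_c)
            )
        return StudyTable("continuous", pd.DataFrame(rows))
    p_c = 0.3
    for i, th in enumerate(theta):
        total_e = int(rng.integers(30, 101))
        total_c = int(rng.integers(30, 101))
        p_e = min(0.95, p_c * np.exp(th))
        rows.append(
            dict(
                study=f"study{i:02d}",
                events_e=int(rng.binomial(total_e, p_e)),
                total_e=total_e,
                events_c=int(rng.binomial(total_c, p_c)),
                total_c=total_c,
            )
        )
    return StudyTable("binary", pd.DataFrame(rows))
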