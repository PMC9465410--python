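"""Gene-set enrichment: DEG thresholding, ortholog collapse, preranked GSEA, ORA.

Differential-expression tables arrive precomputed (gene, log2FC, FDR); genes
pass the DEG filter under the strict thresholds FDR < 0.05 and |log2FC| > 1.5
(both configurable). Cross-species tables collapse to unique human orthologs:
sources mapping to exactly one target survive, unmapped and multi-mapped
genes are dropped and counted.

Preranked GSEA walks the ranked list accumulating a weighted
Kolmogorov-Smirnov running sum — hits add |score|^p normalized by the total
hit weight, misses subtract 1/(N - N_hit) — and takes the signed maximum
deviation as the enrichment score ES. Significance comes from random
same-size gene sets: NES = ES / mean(|null ES| of the matching sign), p is
the one-sided permutation fraction, and the q value is the permutation FDR
across the queried sets (equal to p when a single set is queried).

Over-representation (ORA) is the upper-tail hypergeometric test of a query
set against term sets within a background universe, with Benjamini-Hochberg
correction across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graph_io import GeneSet, RankedList

logger = logging.getLogger("netpharm")

__all__ = [
    "DegRecord",
    "GseaResult",
    "deg_filter",
    "read_deg_table",
    "map_orthologs",
    "enrichment_score",
    "gsea_preranked",
    "gsea_fdr",
    "ora_hypergeometric",
]


@dataclass(frozen=True)
class DegRecord:
    gene: str
    log2fc: float
    fdr: float

    def __post_init__(self):
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"{self.gene}: fdr must be in [0,1]")


@dataclass
class GseaResult:
    es: float
    nes: float
    p: float
    q: float
    n_perm: int
    rng_seed: int
    n_hits: int

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.es <= 1.0 + 1e-12:
            raise ValueError("ES out of [-1, 1]")
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError("p/q out of [0, 1]")


def read_deg_table(path) -> list[DegRecord]:
    """TSV with header columns gene, log2FC, FDR (case-insensitive)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    try:
        g, fc, fdr = cols["gene"], cols["log2fc"], cols["fdr"]
    except KeyError as exc:
        raise ValueError(f"{path}: need columns gene, log2FC, FDR") from exc
    return [DegRecord(str(r[g]), float(r[fc]), float(r[fdr])) for _, r in df.iterrows()]


def deg_filter(
    records: list[DegRecord], fdr_max: float = 0.05, lfc_min: float = 1.5
) -> frozenset[str]:
    """Differentially expressed genes: FDR < fdr_max and |log2FC| > lfc_min.

    Both inequalities are strict. An empty result is a valid (empty) set.
    """
    if not records:
        raise ValueError("no DEG records supplied")
    return frozenset(r.gene for r in records if r.fdr < fdr_max and abs(r.log2fc) > lfc_min)


def map_orthologs(genes: GeneSet, mapping: dict[str, list[str]]) -> GeneSet:
    """Collapse to unique orthologs: keep 1:1 mappings, drop the rest (logged)."""
    kept, unmapped, multi = set(), 0, 0
    for gene in genes.members:
        targets = mapping.get(gene)
        if not targets:
            unmapped += 1
        elif len(targets) > 1:
            multi += 1
        else:
            kept.add(targets[0])
    if unmapped or multi:
        logger.warning(
            "%s: dropped %d unmapped and %d multi-mapped gene(s)", genes.name, unmapped, multi
        )
    if not kept:
        raise ValueError(f"{genes.name!r}: no gene survived ortholog mapping")
    return GeneSet(genes.name, frozenset(kept), genes.description)


# ---------------------------------------------------------------------------
# preranked GSEA


def _es_from_hits(
    abs_scores: np.ndarray, hit_pos: np.ndarray, p: float
) -> np.ndarray:
    """Signed-max-deviation ES for one or many hit-position sets.

    hit_pos: (m,) or (k, m) array of 0-based positions into the descending
    list; positions within a row must be sortable (they are sorted here).
    Uses the closed form of the running sum at its only candidate extrema
    (immediately after each hit for the maximum, immediately before each hit
    for the minimum).
    """
    hp = np.atleast_2d(np.sort(hit_pos, axis=-1))
    k, m = hp.shape
    n = len(abs_scores)
    w = abs_scores[hp] ** p if p != 0 else np.ones_like(hp, dtype=float)
    total = w.sum(axis=1, keepdims=True)
    # degenerate: all hit weights zero -> fall back to unweighted steps
    zero = (total == 0).ravel()
    if zero.any():
        w[zero] = 1.0
        total = w.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w, axis=1) / total
    if n == m:  # no miss steps: the running sum climbs monotonically to 1
        return np.ones(k) if hit_pos.ndim > 1 else np.array([1.0])
    miss = 1.0 / (n - m)
    i = np.arange(1, m + 1)
    after = cumw - (hp + 1 - i) * miss
    before = np.concatenate([np.zeros((k, 1)), cumw[:, :-1]], axis=1) - (hp + 1 - i) * miss
    pos = np.maximum(after.max(axis=1), 0.0)
    neg = np.minimum(before.min(axis=1), 0.0)
    return np.where(pos >= -neg, pos, neg)


def enrichment_score(ranked: RankedList, gene_set: GeneSet, p: float = 1.0) -> float:
    """Weighted KS enrichment score of a gene set on a descending ranked list."""
    in_set = set(gene_set.members)
    hit_pos = np.array([i for i, g in enumerate(ranked.genes) if g in in_set])
    if len(hit_pos) == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no member in the ranked list")
    return float(_es_from_hits(np.abs(ranked.scores), hit_pos, p)[0])


def _null_es(
    ranked: RankedList, n_hits: int, p: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(ranked)
    keys = rng.random((n_perm, n))
    hit_pos = np.argpartition(keys, n_hits - 1, axis=1)[:, :n_hits] if n_hits < n else (
        np.tile(np.arange(n), (n_perm, 1))
    )
    return _es_from_hits(np.abs(ranked.scores), hit_pos, p)


def _nes_p(es: float, null: np.ndarray) -> tuple[float, float]:
    matched = null[null >= 0] if es >= 0 else null[null < 0]
    if len(matched) == 0 or np.abs(matched).mean() == 0:
        return np.sign(es) * np.inf, 1.0 / (len(null) + 1)
    nes = es / np.abs(matched).mean()
    more_extreme = int((np.abs(matched) >= abs(es)).sum())
    p = (more_extreme + 1) / (len(matched) + 1)
    return float(nes), float(p)


def gsea_preranked(
    ranked: RankedList,
    gene_set: GeneSet,
    p: float = 1.0,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> GseaResult:
    """Preranked GSEA of one gene set: ES, NES, permutation p, and q (= p)."""
    members_in = set(gene_set.members) & set(ranked.genes)
    if not members_in:
        raise ValueError(f"gene set {gene_set.name!r} has no member in the ranked list")
    if len(members_in) > len(ranked):
        raise ValueError("gene set larger than ranked list")
    es = enrichment_score(ranked, gene_set, p)
    rng = np.random.default_rng(rng_seed)
    null = _null_es(ranked, len(members_in), p, n_perm, rng)
    nes, pval = _nes_p(es, null)
    return GseaResult(es, nes, pval, pval, n_perm, rng_seed, len(members_in))


def gsea_fdr(
    ranked: RankedList,
    gene_sets: list[GeneSet],
    p: float = 1.0,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """GSEA over several sets with a permutation FDR q across the panel.

    q(S) = [fraction of sign-matched null NES at least as extreme as NES(S)]
    / [fraction of observed sign-matched NES at least as extreme], clipped to
    [0, 1] and made monotone in |NES|.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    null_nes_all: list[np.ndarray] = []
    for gs in gene_sets:
        members_in = set(gs.members) & set(ranked.genes)
        if not members_in:
            raise ValueError(f"gene set {gs.name!r} has no member in the ranked list")
        es = enrichment_score(ranked, gs, p)
        null = _null_es(ranked, len(members_in), p, n_perm, rng)
        nes, pval = _nes_p(es, null)
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes_all.append(null_nes[~np.isnan(null_nes)])
        rows.append(dict(term=gs.name, es=es, nes=nes, p=pval, n_hits=len(members_in)))
    df = pd.DataFrame(rows)
    pooled = np.concatenate(null_nes_all)
    qs = []
    for nes in df["nes"]:
        if nes >= 0:
            null_frac = (pooled[pooled >= 0] >= nes).mean() if (pooled >= 0).any() else 1.0
            obs_frac = (df["nes"][df["nes"] >= 0] >= nes).mean()
        else:
            null_frac = (pooled[pooled < 0] <= nes).mean() if (pooled < 0).any() else 1.0
            obs_frac = (df["nes"][df["nes"] < 0] <= nes).mean()
        qs.append(min(1.0, null_frac / max(obs_frac, 1e-12)))
    df["q"] = qs
    # enforce monotone q in |NES| within each sign
    for sign in (1, -1):
        mask = (df["nes"] >= 0) if sign == 1 else (df["nes"] < 0)
        idx = df.index[mask]
        order = df.loc[idx, "nes"].abs().sort_values(ascending=False).index
        df.loc[order, "q"] = np.minimum.accumulate(df.loc[order, "q"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# over-representation


def ora_hypergeometric(
    query: GeneSet, terms: list[GeneSet], background: GeneSet
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH correction.

    For each term T (intersected with the background universe of size M),
    p = P[overlap >= observed] under sampling |query| genes from the
    background. Returns a frame with term, term size, overlap, p, bh_q.
    """
    bg = set(background.members)
    q = set(query.members)
    if not q <= bg:
        raise ValueError("query contains genes outside the background")
    rows = []
    for t in terms:
        t_bg = set(t.members) & bg
        k = len(q & t_bg)
        p = float(stats.hypergeom.sf(k - 1, len(bg), len(t_bg), len(q)))
        rows.append(dict(term=t.name, term_size=len(t_bg), overlap=k, p=min(p, 1.0)))
    df = pd.DataFrame(rows)
    df["bh_q"] = stats.false_discovery_control(df["p"], method="bh")
    return df
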