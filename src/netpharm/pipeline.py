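"""End-to-end synthetic experiment: simulate -> associate -> similarity ->
cluster -> enrich -> meta.

The run mirrors the study design the package implements: a drug with targets
planted near the disease module (positive control) and a drug with remote
targets (negative control) are both scored against the disease by the
propagation Z statistic; a compound panel with three planted groups is
compared under the structure / target-module / cellular-function similarity
fingerprints and clustered; a planted ranked list is tested for enrichment;
and a synthetic multi-study table is pooled by the meta-analysis engine.

Stages communicate only via files under the configured output directory, so
any stage's inputs and outputs can be inspected or re-run; a manifest records
seeds, per-stage summaries and content hashes, and is identical across reruns
of the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import association, clustering, enrichment, graph_io, meta_analysis, similarity
from .graph_io import GeneSet
from .propagation import RwrSolver, largest_component
from .synthetic_data import (
    SimConfig,
    compound_labels,
    compound_target_sets,
    gen_annotations,
    gen_fingerprints,
    gen_interactome,
    gen_meta_studies,
    gen_ranked_list,
    gen_seed_sets,
    map_targets_to_nodes,
    _group_labels,
)

logger = logging.getLogger("netpharm")

ALL_STAGES = ("simulate", "associate", "similarity", "cluster", "enrich", "meta")


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and the cause."""


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    restart: float = 0.75
    n_perm: int = 1000
    z_threshold: float = 3.0
    i2_threshold: float = 50.0
    fdr_max: float = 0.05
    lfc_min: float = 1.5
    n_genes: int = 1000
    planted_set_size: int = 50
    shift: float = 3.0
    gsea_n_perm: int = 1000
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for name in ("z_threshold", "i2_threshold", "fdr_max", "lfc_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        sim = SimConfig(**raw.pop("sim", {}))
        stages = tuple(raw.pop("stages", ALL_STAGES))
        return cls(sim=sim, stages=stages, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _deg_table_from_ranked(ranked: graph_io.RankedList) -> pd.DataFrame:
    """Recast ranked-list scores as a DEG table (log2FC = score, BH FDR)."""
    p = 2.0 * stats.norm.sf(np.abs(ranked.scores))
    fdr = stats.false_discovery_control(p, method="bh")
    return pd.DataFrame({"gene": ranked.genes, "log2FC": ranked.scores, "FDR": fdr})


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order; return (and write) the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}, "files": {}}
    written: list[Path] = []

    def record(stage: str, summary: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {"status": "ok", **summary}
        written.extend(files)

    def run_stage(stage: str, fn) -> None:
        if stage not in cfg.stages:
            manifest["stages"][stage] = {"status": "skipped"}
            return
        try:
            fn()
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # ---------------- simulate ----------------
    def simulate():
        sim = cfg.sim
        g = gen_interactome(sim)
        graph_io.write_edge_list(g, out / "network.tsv")

        drug_pos, disease = gen_seed_sets(g, sim)
        neg_cfg = dataclasses.replace(sim, proximity=0.0)
        drug_neg, _ = gen_seed_sets(g, neg_cfg)
        sets = {
            "drug_positive": GeneSet("drug_positive", drug_pos.members, "planted proximal drug"),
            "drug_negative": GeneSet("drug_negative", drug_neg.members, "planted remote drug"),
            "disease": GeneSet("disease", disease.members, "planted disease module"),
        }
        graph_io.write_gmt(sets, out / "seed_sets.gmt")

        ct, tf = gen_annotations(sim)
        graph_io.write_matrix(
            pd.DataFrame(ct.values, index=ct.row_labels, columns=ct.col_labels),
            out / "compound_target.tsv",
        )
        graph_io.write_matrix(
            pd.DataFrame(tf.values, index=tf.row_labels, columns=tf.col_labels),
            out / "target_function.tsv",
        )
        node_map = map_targets_to_nodes(g, sim)
        graph_io.write_mapping({t: [n] for t, n in node_map.items()}, out / "target_nodes.tsv")

        fps = gen_fingerprints(sim)
        graph_io.write_fingerprints(fps, out / "fingerprints.tsv")
        groups = _group_labels(sim)
        pd.DataFrame({"compound": compound_labels(sim), "group": groups}).to_csv(
            out / "planted_groups.tsv", sep="\t", index=False
        )

        ranked, planted = gen_ranked_list(cfg.n_genes, cfg.planted_set_size, cfg.shift, sim.seed + 5)
        graph_io.write_ranked_list(ranked, out / "ranked.tsv")
        graph_io.write_gmt({"planted": planted}, out / "planted.gmt")
        _deg_table_from_ranked(ranked).to_csv(out / "degs.tsv", sep="\t", index=False)
        # ortholog map: identity for all genes (the stand-in species map)
        graph_io.write_mapping({g_: [g_] for g_ in ranked.genes}, out / "orthologs.tsv")

        studies = gen_meta_studies(sim)
        graph_io.write_study_table(studies, out / "studies.csv")
        files = sorted(out.glob("*.tsv")) + [out / "seed_sets.gmt", out / "planted.gmt", out / "studies.csv"]
        record(
            "simulate",
            {
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
                "disease_size": len(disease),
                "drug_size": len(drug_pos),
                "n_compounds": sim.n_compounds,
                "n_studies": len(studies),
            },
            files,
        )

    # ---------------- associate ----------------
    def assoc():
        g = largest_component(graph_io.read_edge_list(out / "network.tsv"))
        sets = graph_io.read_gmt(out / "seed_sets.gmt")
        solver = RwrSolver(g, cfg.restart)
        results = {}
        for name in ("drug_positive", "drug_negative"):
            res = association.associate(
                g,
                sets[name],
                sets["disease"],
                n_perm=cfg.n_perm,
                restart=cfg.restart,
                rng_seed=cfg.seed + 10,
                z_threshold=cfg.z_threshold,
                solver=solver,
            )
            results[name] = res.summary()
        (out / "association.json").write_text(json.dumps(results, indent=2))
        record(
            "associate",
            {name: {"z": r["z"], "significant": r["significant"]} for name, r in results.items()},
            [out / "association.json"],
        )

    # ---------------- similarity ----------------
    def sims():
        fps = graph_io.read_fingerprints(out / "fingerprints.tsv")
        m_tan = similarity.pairwise_tanimoto(fps)
        graph_io.write_matrix(m_tan.to_frame(), out / "sim_tanimoto.tsv")

        ct_df = graph_io.read_matrix(out / "compound_target.tsv")
        tf_df = graph_io.read_matrix(out / "target_function.tsv")
        ct = graph_io.BipartiteIncidence(list(ct_df.index), list(ct_df.columns), ct_df.values)
        tf = graph_io.BipartiteIncidence(list(tf_df.index), list(tf_df.columns), tf_df.values)
        m_ps = similarity.pathsim_matrix(ct, tf)
        graph_io.write_matrix(m_ps.to_frame(), out / "sim_pathsim.tsv")

        g = largest_component(graph_io.read_edge_list(out / "network.tsv"))
        node_map = {s: t[0] for s, t in graph_io.read_mapping(out / "target_nodes.tsv").items()}
        target_sets = compound_target_sets(ct, node_map)
        m_sep = similarity.pairwise_target_similarity(g, target_sets)
        graph_io.write_matrix(m_sep.to_frame(), out / "sim_separation.tsv")
        record(
            "similarity",
            {
                "n_compounds": len(m_tan.labels),
                "tanimoto_mean_offdiag": float(
                    m_tan.values[~np.eye(len(m_tan.labels), dtype=bool)].mean()
                ),
            },
            sorted(out.glob("sim_*.tsv")),
        )

    # ---------------- cluster ----------------
    def cluster():
        try:
            from sklearn.metrics import adjusted_rand_score
        except ImportError:  # pragma: no cover
            adjusted_rand_score = None
        planted = pd.read_csv(out / "planted_groups.tsv", sep="\t")
        truth = dict(zip(planted["compound"], planted["group"]))
        k = cfg.sim.n_groups
        summary = {}
        files = []
        for kind in ("tanimoto", "pathsim", "separation"):
            df = graph_io.read_matrix(out / f"sim_{kind}.tsv", symmetric=True)
            m = similarity.SimilarityMatrix.from_frame(df, kind)
            dend = clustering.linkage(clustering.to_distance(m), m.labels)
            labels = clustering.cut(dend, k)
            pd.DataFrame(
                {"compound": list(labels), "cluster": [labels[c] for c in labels]}
            ).to_csv(out / f"clusters_{kind}.tsv", sep="\t", index=False)
            (out / f"tree_{kind}.nwk").write_text(clustering.to_newick(dend) + "\n")
            entry = {"k": k}
            if adjusted_rand_score is not None:
                entry["ari_vs_planted"] = float(
                    adjusted_rand_score(
                        [truth[c] for c in m.labels], [labels[c] for c in m.labels]
                    )
                )
            summary[kind] = entry
            files += [out / f"clusters_{kind}.tsv", out / f"tree_{kind}.nwk"]
        record("cluster", summary, files)

    # ---------------- enrich ----------------
    def enrich():
        ranked = graph_io.read_ranked_list(out / "ranked.tsv")
        planted = graph_io.read_gmt(out / "planted.gmt")["planted"]
        gsea = enrichment.gsea_preranked(
            ranked, planted, n_perm=cfg.gsea_n_perm, rng_seed=cfg.seed + 20
        )
        degs = enrichment.read_deg_table(out / "degs.tsv")
        deg_genes = enrichment.deg_filter(degs, cfg.fdr_max, cfg.lfc_min)
        mapping = graph_io.read_mapping(out / "orthologs.tsv")
        summary = {
            "gsea": {"es": gsea.es, "nes": gsea.nes, "p": gsea.p, "q": gsea.q},
            "n_degs": len(deg_genes),
        }
        if deg_genes:
            deg_set = enrichment.map_orthologs(
                GeneSet("degs", frozenset(deg_genes)), mapping
            )
            background = GeneSet("background", frozenset(ranked.genes))
            ora = enrichment.ora_hypergeometric(deg_set, [planted], background)
            ora.to_csv(out / "ora.tsv", sep="\t", index=False)
            summary["ora_planted_p"] = float(ora["p"].iloc[0])
        (out / "enrichment.json").write_text(json.dumps(summary, indent=2))
        record("enrich", summary, [out / "enrichment.json"])

    # ---------------- meta ----------------
    def meta():
        table = graph_io.read_study_table(out / "studies.csv")
        result = meta_analysis.run_meta(table, model="auto", i2_threshold=cfg.i2_threshold)
        (out / "meta.json").write_text(json.dumps(result.report(), indent=2))
        meta_analysis.forest_table(result).to_csv(out / "forest.tsv", sep="\t", index=False)
        record("meta", result.report(), [out / "meta.json", out / "forest.tsv"])

    for stage, fn in zip(
        ALL_STAGES, (simulate, assoc, sims, cluster, enrich, meta)
    ):
        run_stage(stage, fn)

    manifest["files"] = {p.name: _sha256(p) for p in sorted(set(written))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
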