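"""Generators: determinism, planted structure, and calibration properties."""

import dataclasses

import networkx as nx
import numpy as np
import pytest

from netpharm import meta_analysis as ma
from netpharm import similarity
from netpharm.synthetic_data import (
    ConfigurationError,
    SimConfig,
    compound_target_sets,
    gen_annotations,
    gen_fingerprints,
    gen_interactome,
    gen_meta_studies,
    gen_ranked_list,
    gen_seed_sets,
    map_targets_to_nodes,
)


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_nodes=0)
        with pytest.raises(ConfigurationError):
            SimConfig(proximity=1.5)
        with pytest.raises(ConfigurationError):
            SimConfig(tau2=-1.0)


class TestInteractome:
    def test_small_graph_connected_with_requested_size(self):
        g = gen_interactome(SimConfig(n_nodes=10, edges_per_node=2, seed=1))
        assert g.number_of_nodes() == 10
        assert nx.is_connected(g)
        assert nx.number_of_selfloops(g) == 0

    def test_deterministic_per_seed(self):
        cfg = SimConfig(n_nodes=50, edges_per_node=2, seed=9)
        g1, g2 = gen_interactome(cfg), gen_interactome(cfg)
        assert set(g1.edges) == set(g2.edges)
        g3 = gen_interactome(dataclasses.replace(cfg, seed=10))
        assert set(g1.edges) != set(g3.edges)

    def test_heavy_tailed_degrees(self):
        g = gen_interactome(SimConfig(n_nodes=500, edges_per_node=3, seed=0))
        degrees = np.array([d for _, d in g.degree])
        assert degrees.max() > 3 * np.median(degrees)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_interactome(SimConfig(n_nodes=3, edges_per_node=3))


class TestSeedSets:
    def test_proximity_one_within_one_hop_of_ball(self):
        cfg = SimConfig(n_nodes=200, edges_per_node=2, seed=4, module_size=12, proximity=1.0)
        g = gen_interactome(cfg)
        drug, disease = gen_seed_sets(g, cfg)
        closure = set(disease.members)
        for m in disease.members:
            closure.update(g.neighbors(m))
        assert drug.members <= closure

    def test_proximity_zero_outside_the_ball(self):
        cfg = SimConfig(n_nodes=200, edges_per_node=2, seed=4, module_size=12, proximity=0.0)
        g = gen_interactome(cfg)
        drug, disease = gen_seed_sets(g, cfg)
        assert not (drug.members & disease.members)

    def test_disease_module_is_connected(self):
        cfg = SimConfig(n_nodes=200, edges_per_node=2, seed=13, module_size=15)
        g = gen_interactome(cfg)
        _, disease = gen_seed_sets(g, cfg)
        assert nx.is_connected(g.subgraph(disease.members))

    def test_high_proximity_means_smaller_distance(self):
        cfg = SimConfig(n_nodes=300, edges_per_node=2, seed=6, module_size=15)
        g = gen_interactome(cfg)

        def mean_dist(prox):
            drug, disease = gen_seed_sets(g, dataclasses.replace(cfg, proximity=prox))
            dist = nx.multi_source_dijkstra_path_length(
                g, sorted(disease.members), weight=lambda *_: 1
            )
            return np.mean([dist[m] for m in drug.members])

        assert mean_dist(0.8) < mean_dist(0.2)

    def test_proximity_monotone_over_seeds(self):
        """Mean drug->disease distance is non-increasing in proximity (5 seeds)."""
        grid = (0.0, 0.25, 0.5, 0.75, 1.0)
        means = np.zeros(len(grid))
        for seed in range(5):
            cfg = SimConfig(n_nodes=300, edges_per_node=2, seed=seed, module_size=15)
            g = gen_interactome(cfg)
            for i, prox in enumerate(grid):
                drug, disease = gen_seed_sets(g, dataclasses.replace(cfg, proximity=prox))
                dist = nx.multi_source_dijkstra_path_length(
                    g, sorted(disease.members), weight=lambda *_: 1
                )
                means[i] += np.mean([dist[m] for m in drug.members]) / 5
        assert np.all(np.diff(means) <= 0)

    def test_oversized_module_rejected(self):
        cfg = SimConfig(n_nodes=20, edges_per_node=2, module_size=10)
        g = gen_interactome(cfg)
        with pytest.raises(ConfigurationError):
            gen_seed_sets(g, cfg)


class TestAnnotations:
    def test_deterministic_and_rows_nonempty(self):
        cfg = SimConfig(n_compounds=9, n_targets=12, n_functions=6, seed=2)
        ct1, tf1 = gen_annotations(cfg)
        ct2, _ = gen_annotations(cfg)
        np.testing.assert_array_equal(ct1.values, ct2.values)
        assert (ct1.values.sum(axis=1) >= 1).all()
        assert (tf1.values.sum(axis=1) >= 1).all()

    def test_single_function_shared_by_all_targets(self):
        cfg = SimConfig(n_compounds=4, n_targets=6, n_functions=1, n_groups=1, seed=0)
        _, tf = gen_annotations(cfg)
        assert (tf.values == 1).all()

    def test_planted_groups_separate_under_pathsim(self):
        cfg = SimConfig(n_compounds=6, n_targets=12, n_functions=6, n_groups=2, seed=3)
        ct, tf = gen_annotations(cfg)
        m = similarity.pathsim_matrix(ct, tf).values
        within = np.mean([m[i, j] for i in range(3) for j in range(i + 1, 3)] +
                         [m[i, j] for i in range(3, 6) for j in range(i + 1, 6)])
        between = np.mean([m[i, j] for i in range(3) for j in range(3, 6)])
        assert within > between


class TestFingerprints:
    def test_zero_flip_rate_gives_within_group_identity(self):
        cfg = SimConfig(n_compounds=6, n_groups=2, fp_bits=64, fp_flip_rate=0.0, seed=1)
        fps = gen_fingerprints(cfg)
        labels = fps.labels
        assert similarity.tanimoto(fps[labels[0]], fps[labels[1]]) == 1.0
        assert similarity.tanimoto(fps[labels[3]], fps[labels[4]]) == 1.0

    def test_between_group_near_density_baseline(self):
        # independent Bernoulli(d) prototypes: E[tanimoto] ~ d/(2-d)
        cfg = SimConfig(
            n_compounds=40, n_groups=40, fp_bits=4096, fp_flip_rate=0.0, fp_density=0.2, seed=7
        )
        fps = gen_fingerprints(cfg, groups=list(range(40)))
        m = similarity.pairwise_tanimoto(fps).values
        off = m[~np.eye(40, dtype=bool)]
        baseline = 0.2 / (2 - 0.2)
        assert abs(off.mean() - baseline) < 0.02

    def test_deterministic_per_seed(self):
        cfg = SimConfig(n_compounds=4, fp_bits=32, seed=5)
        f1, f2 = gen_fingerprints(cfg), gen_fingerprints(cfg)
        for label in f1.labels:
            np.testing.assert_array_equal(f1[label], f2[label])


class TestRankedList:
    def test_shifted_set_ranks_high(self):
        ranked, planted = gen_ranked_list(1000, 50, shift=3.0, seed=3)
        ranks = [ranked.rank_of(g) for g in planted.members]
        assert np.median(ranks) < 250  # top quartile

    def test_no_shift_is_exchangeable(self):
        ranked, planted = gen_ranked_list(2000, 100, shift=0.0, seed=3)
        ranks = [ranked.rank_of(g) for g in planted.members]
        # uniform over ranks: mean rank ~ n/2 within 4 sd
        se = 2000 / np.sqrt(12 * 100)
        assert abs(np.mean(ranks) - 1000) < 4 * se

    def test_deterministic_and_size_checked(self):
        r1, p1 = gen_ranked_list(100, 10, 1.0, seed=2)
        r2, p2 = gen_ranked_list(100, 10, 1.0, seed=2)
        assert r1.genes == r2.genes and p1.members == p2.members
        with pytest.raises(ConfigurationError):
            gen_ranked_list(10, 10, 1.0, seed=0)


class TestMetaStudies:
    def test_homogeneous_tables_have_low_i2(self):
        table = gen_meta_studies(SimConfig(tau2=0.0, n_studies=30, seed=5))
        res = ma.run_meta(table, model="fixed")
        assert res.i2 < 50.0

    def test_heterogeneous_tables_trigger_random_effects(self):
        table = gen_meta_studies(SimConfig(tau2=9.0, n_studies=30, seed=5))
        res = ma.run_meta(table, model="auto")
        assert res.model == "random"

    def test_q_calibrated_against_chi_square_at_tau2_zero(self):
        """With no heterogeneity, E[Q] ~ df (chi-square moment), 500 replicates."""
        n_studies = 10
        qs = [
            ma.run_meta(
                gen_meta_studies(SimConfig(tau2=0.0, n_studies=n_studies, seed=seed)),
                model="fixed",
            ).Q
            for seed in range(500)
        ]
        df = n_studies - 1
        assert abs(np.mean(qs) - df) / df < 0.15

    def test_binary_tables_valid_and_deterministic(self):
        cfg = SimConfig(study_kind="binary", n_studies=10, seed=6, true_effect=0.3, tau2=0.1)
        t1, t2 = gen_meta_studies(cfg), gen_meta_studies(cfg)
        assert t1.kind == "binary"
        assert t1.records.equals(t2.records)
        assert (t1.records["events_e"] <= t1.records["total_e"]).all()


class TestTargetNodePlacement:
    def test_blocks_disjoint_and_cover_targets(self):
        cfg = SimConfig(n_nodes=300, edges_per_node=2, n_targets=30, n_groups=3, seed=1)
        g = gen_interactome(cfg)
        node_map = map_targets_to_nodes(g, cfg)
        assert len(node_map) == 30
        assert len(set(node_map.values())) == 30

    def test_compound_modules_follow_planted_groups(self):
        cfg = SimConfig(n_nodes=300, edges_per_node=2, seed=1)
        g = gen_interactome(cfg)
        ct, _ = gen_annotations(cfg)
        node_map = map_targets_to_nodes(g, cfg)
        sets = compound_target_sets(ct, node_map)
        m = similarity.pairwise_target_similarity(g, sets).values
        n = cfg.n_compounds // cfg.n_groups
        within = np.mean([m[i, j] for i in range(n) for j in range(i + 1, n)])
        between = np.mean([m[i, j] for i in range(n) for j in range(n, 2 * n)])
        assert within < between  # smaller separation = more similar
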