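"""Similarity fingerprints vs brute-force oracles (path enumeration, all-pairs BFS)."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm import similarity
from netpharm.graph_io import BipartiteIncidence, FingerprintSet, GeneSet
from netpharm.synthetic_data import SimConfig, gen_annotations, gen_fingerprints, gen_interactome


def gs(name, *members):
    return GeneSet(name, frozenset(members))


# ---------------------------------------------------------------------------
# oracles


def pathsim_bruteforce(ct: BipartiteIncidence, tf: BipartiteIncidence) -> np.ndarray:
    """Explicit enumeration of compound->target->function->target->compound paths."""
    nc, nt = ct.values.shape
    nf = tf.values.shape[1]
    counts = np.zeros((nc, nc))
    for x in range(nc):
        for y in range(nc):
            total = 0
            for t1 in range(nt):
                for f in range(nf):
                    for t2 in range(nt):
                        total += (
                            ct.values[x, t1] * tf.values[t1, f] * tf.values[t2, f] * ct.values[y, t2]
                        )
            counts[x, y] = total
    s = np.zeros((nc, nc))
    for x in range(nc):
        for y in range(nc):
            denom = counts[x, x] + counts[y, y]
            s[x, y] = 2 * counts[x, y] / denom if denom > 0 else 0.0
    np.fill_diagonal(s, [1.0 if counts[i, i] > 0 else 0.0 for i in range(nc)])
    return s


def separation_bruteforce(g, a_members, b_members):
    """S_AB from a literal all-pairs BFS distance table."""
    dist = dict(nx.all_pairs_shortest_path_length(g))

    def d_within(members):
        if len(members) == 1:
            return 0.0
        return np.mean(
            [min(dist[m][o] for o in members if o != m) for m in members]
        )

    cross = [min(dist[m][o] for o in b_members) for m in a_members] + [
        min(dist[m][o] for o in a_members) for m in b_members
    ]
    d_ab = float(np.mean(cross))
    return d_ab - (d_within(a_members) + d_within(b_members)) / 2.0


# ---------------------------------------------------------------------------
# tanimoto


class TestTanimoto:
    @pytest.mark.parametrize(
        "on_a,on_b,expected",
        [
            ({1, 2, 3}, {1, 2, 3}, 1.0),
            ({1, 2}, {5, 6}, 0.0),
            ({1, 2, 3}, {2, 3, 4}, 0.5),
        ],
    )
    def test_hand_cases(self, on_a, on_b, expected):
        a = np.zeros(8, dtype=np.uint8)
        b = np.zeros(8, dtype=np.uint8)
        a[list(on_a)] = 1
        b[list(on_b)] = 1
        assert similarity.tanimoto(a, b) == expected

    def test_all_zero_conventions(self):
        z = np.zeros(8, dtype=np.uint8)
        nz = np.array([1, 0, 0, 0, 0, 0, 0, 0], dtype=np.uint8)
        assert similarity.tanimoto(z, z) == 1.0
        assert similarity.tanimoto(z, nz) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity.tanimoto(np.zeros(8), np.zeros(9))

    def test_pairwise_matches_per_pair_calls(self):
        fps = gen_fingerprints(SimConfig(n_compounds=6, n_groups=2, fp_bits=64, seed=4))
        m = similarity.pairwise_tanimoto(fps)
        for i, j in itertools.combinations(range(len(m.labels)), 2):
            expected = similarity.tanimoto(fps[m.labels[i]], fps[m.labels[j]])
            assert m.values[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(np.diag(m.values), 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    def test_one_minus_tanimoto_triangle_inequality(self, xa, xb, xc):
        bits = lambda x: np.array([(x >> i) & 1 for i in range(16)], dtype=np.uint8)
        a, b, c = bits(xa), bits(xb), bits(xc)
        dab = 1 - similarity.tanimoto(a, b)
        dbc = 1 - similarity.tanimoto(b, c)
        dac = 1 - similarity.tanimoto(a, c)
        assert dac <= dab + dbc + 1e-12


# ---------------------------------------------------------------------------
# separation


class TestSeparation:
    def test_three_node_path_by_hand(self, path_graph):
        res = similarity.separation(path_graph, gs("A", "a"), gs("B", "c"))
        assert (res.d_aa, res.d_bb, res.d_ab, res.s_ab) == (0.0, 0.0, 2.0, 2.0)

    def test_identical_sets_give_nonpositive_separation(self, small_interactome):
        members = sorted(small_interactome.nodes)[:6]
        res = similarity.separation(small_interactome, gs("A", *members), gs("B", *members))
        assert res.d_ab == 0.0
        assert res.s_ab == pytest.approx(-res.d_aa)
        assert res.s_ab <= 0.0

    def test_symmetry(self, small_interactome):
        nodes = sorted(small_interactome.nodes)
        a, b = gs("A", *nodes[:5]), gs("B", *nodes[20:28])
        r1 = similarity.separation(small_interactome, a, b)
        r2 = similarity.separation(small_interactome, b, a)
        assert r1.s_ab == pytest.approx(r2.s_ab, abs=1e-12)

    def test_matches_bruteforce_bfs(self):
        g = gen_interactome(SimConfig(n_nodes=80, edges_per_node=2, seed=9))
        nodes = sorted(g.nodes)
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = [nodes[i] for i in rng.choice(80, 6, replace=False)]
            b = [nodes[i] for i in rng.choice(80, 4, replace=False)]
            res = similarity.separation(g, gs("A", *a), gs("B", *b))
            assert res.s_ab == pytest.approx(separation_bruteforce(g, a, b), abs=1e-12)

    def test_pairwise_matrix_symmetric_and_planted_order(self):
        cfg = SimConfig(n_nodes=200, edges_per_node=2, seed=2, module_size=10)
        g = gen_interactome(cfg)
        import networkx as nx

        nodes = sorted(g.nodes)
        near_a = nodes[:6]
        near_b = [n for m in near_a for n in g.neighbors(m)][:6]
        far = nodes[-6:]
        sets = [gs("a", *near_a), gs("b", *near_b), gs("far", *far)]
        m = similarity.pairwise_target_similarity(g, sets)
        assert np.allclose(m.values, m.values.T)
        ia, ib, ifar = (m.labels.index(k) for k in ("a", "b", "far"))
        assert m.values[ia, ib] < m.values[ia, ifar]  # near pair has smaller S_AB


# ---------------------------------------------------------------------------
# PathSim


class TestPathSim:
    def test_minimal_two_compound_example(self):
        # C = I2, one shared function: every compound has 1 self path and 1 cross path
        ct = BipartiteIncidence(["x", "y"], ["t1", "t2"], np.eye(2, dtype=int))
        tf = BipartiteIncidence(["t1", "t2"], ["f"], np.ones((2, 1), dtype=int))
        m = similarity.pathsim_matrix(ct, tf)
        np.testing.assert_allclose(m.values, np.ones((2, 2)))

    def test_identical_target_rows_are_maximally_similar(self):
        ct = BipartiteIncidence(["x", "y"], ["t1", "t2"], np.array([[1, 1], [1, 1]]))
        tf = BipartiteIncidence(["t1", "t2"], ["f1", "f2"], np.array([[1, 0], [0, 1]]))
        m = similarity.pathsim_matrix(ct, tf)
        assert m.values[0, 1] == 1.0

    def test_label_misalignment_rejected(self):
        ct = BipartiteIncidence(["x"], ["t1"], np.array([[1]]))
        tf = BipartiteIncidence(["tX"], ["f"], np.array([[1]]))
        with pytest.raises(ValueError):
            similarity.pathsim_matrix(ct, tf)

    def test_matches_bruteforce_enumeration(self):
        for seed in range(3):
            cfg = SimConfig(n_compounds=6, n_targets=8, n_functions=5, n_groups=2, seed=seed)
            ct, tf = gen_annotations(cfg)
            m = similarity.pathsim_matrix(ct, tf)
            np.testing.assert_allclose(m.values, pathsim_bruteforce(ct, tf), atol=1e-12)

    def test_planted_groups_have_higher_within_similarity(self):
        cfg = SimConfig(n_compounds=6, n_targets=12, n_functions=6, n_groups=2, seed=1)
        ct, tf = gen_annotations(cfg)
        m = similarity.pathsim_matrix(ct, tf)
        within = [m.values[i, j] for i in range(3) for j in range(3) if i < j]
        within += [m.values[i, j] for i in range(3, 6) for j in range(3, 6) if i < j]
        between = [m.values[i, j] for i in range(3) for j in range(3, 6)]
        assert np.mean(within) > np.mean(between)


def test_similarity_matrix_validation():
    with pytest.raises(ValueError):
        similarity.SimilarityMatrix(["a", "b"], np.array([[1.0, 0.2], [0.3, 1.0]]), "tanimoto")
    with pytest.raises(ValueError):
        similarity.SimilarityMatrix(["a", "b"], np.array([[1.0, 2.0], [2.0, 1.0]]), "pathsim")
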