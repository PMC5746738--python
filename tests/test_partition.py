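"""Distance matrix, B-matrix, eigenvector split and the module tree."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from mma.partition import (
    annotate_tree,
    build_b_matrix,
    b_matrix_chunk,
    leading_eigenvector_split,
    modularity_q,
    recursive_partition,
    shortest_path_distances,
)
from tests.conftest import make_model


def path_graph(weights):
    g = nx.Graph()
    for i, w in enumerate(weights):
        g.add_edge(chr(ord("A") + i), chr(ord("A") + i + 1), weight=w)
    return g


def brute_force_max_q(B):
    """Independent oracle: exhaustive max of Q over all 2^(n-1) bipartitions."""
    n = B.shape[0]
    best_q, best_s = -np.inf, None
    for bits in range(2 ** (n - 1)):
        s = np.array([1] + [1 if (bits >> k) & 1 else -1 for k in range(n - 1)])
        q = float(s @ B @ s)
        if q > best_q:
            best_q, best_s = q, s
    return best_q, best_s


def assert_tree_invariants(tree):
    """Disjoint union, height recurrence, strict size decrease, positive Q."""
    for m in tree:
        if m.children:
            child_sets = [tree[c].reaction_ids for c in m.children]
            union = frozenset().union(*child_sets)
            assert union == m.reaction_ids
            assert sum(len(s) for s in child_sets) == len(union)  # disjoint
            assert len(m.children) >= 2
            for c in m.children:
                assert tree[c].size < m.size
                assert tree[c].parent == m.module_id
            if m.height is not None:
                assert m.height == 1 + max(tree[c].height for c in m.children)
            assert m.q_split is not None and m.q_split > 1e-12
        else:
            if m.height is not None:
                assert m.height == 0


class TestDistances:
    def test_two_hops_unit_weights(self):
        D, nodes = shortest_path_distances(path_graph([1, 1]))
        i, j = nodes.index("A"), nodes.index("C")
        assert D[i, j] == pytest.approx(2.0)

    def test_additive_weights(self):
        D, nodes = shortest_path_distances(path_graph([0.2, 0.25]))
        assert D[nodes.index("A"), nodes.index("C")] == pytest.approx(0.45)

    def test_triangle_direct_edges_dominate(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("A", "B", 1), ("B", "C", 1), ("A", "C", 1)])
        D, _ = shortest_path_distances(g)
        off = D[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_disconnected_rejected(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1)
        g.add_node("Z")
        with pytest.raises(ValueError, match="disconnected"):
            shortest_path_distances(g)

    def test_metric_properties(self):
        D, _ = shortest_path_distances(path_graph([0.3, 1.2, 0.7]))
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
        n = D.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestBMatrix:
    def test_hand_derived_path_values(self):
        # unit path A-B-C: pooled vector for (A,B) is {2, 1, 1}; the
        # midrank of 1 is 1.5 so B = 1 - 2(0.5)/2 = 0.5; for (A,C) the
        # distance 2 ranks last of three, B = -1
        D, nodes = shortest_path_distances(path_graph([1, 1]))
        B = build_b_matrix(D)
        a, b, c = (nodes.index(x) for x in "ABC")
        assert B[a, b] == pytest.approx(0.5)
        assert B[b, c] == pytest.approx(0.5)
        assert B[a, c] == pytest.approx(-1.0)

    def test_full_ties_map_to_zero(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("A", "B", 1), ("B", "C", 1), ("A", "C", 1)])
        D, _ = shortest_path_distances(g)
        B = build_b_matrix(D)
        assert np.allclose(B[~np.eye(3, dtype=bool)], 0.0)

    def test_strictly_smallest_distance_maps_to_one(self):
        D = np.array(
            [[0.0, 0.1, 5.0, 6.0],
             [0.1, 0.0, 5.0, 6.0],
             [5.0, 5.0, 0.0, 1.0],
             [6.0, 6.0, 1.0, 0.0]]
        )
        B = build_b_matrix(D)
        assert B[0, 1] == pytest.approx(1.0)

    def test_two_node_component_degenerate(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        B = build_b_matrix(D)
        assert B[0, 1] == pytest.approx(1.0)

    def test_bounds_symmetry_zero_diagonal(self, rng):
        g = nx.gnm_random_graph(12, 30, seed=3)
        for u, v in g.edges():
            g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
        D, _ = shortest_path_distances(g)
        B = build_b_matrix(D)
        assert np.allclose(B, B.T) and np.allclose(np.diag(B), 0)
        assert (B >= -1 - 1e-12).all() and (B <= 1 + 1e-12).all()

    def test_chunked_equals_serial(self):
        D, _ = shortest_path_distances(path_graph([0.2, 0.25, 1.0, 0.4]))
        serial = build_b_matrix(D)
        for chunk_size in (1, 3):
            assert np.array_equal(serial, build_b_matrix(D, chunk_size=chunk_size))
        pairs = [(0, 3), (1, 2)]
        for i, j, b in b_matrix_chunk(D, pairs):
            assert b == serial[i, j]

    def test_value_convention_alternative(self):
        # linear in the distance value: midpoint distance maps to 0
        D = np.array(
            [[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]]
        )
        B = build_b_matrix(D, convention="value")
        # pair (0,1): pooled values {2, 3, 1}; 1 -> +1 (minimum)
        assert B[0, 1] == pytest.approx(1.0)
        # pair (1,2): pooled {1, 2, 3}; 3 is the maximum -> -1
        assert B[1, 2] == pytest.approx(-1.0)


class TestModularityQ:
    def test_all_plus_sums_matrix(self):
        B = np.array([[0, 0.5, -0.2], [0.5, 0, 0.1], [-0.2, 0.1, 0]])
        assert modularity_q(B, [1, 1, 1]) == pytest.approx(B.sum())

    def test_two_node_antisymmetric_signs(self):
        B = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert modularity_q(B, [1, -1]) == pytest.approx(-2.0)

    def test_zero_matrix_zero_q(self):
        B = np.zeros((4, 4))
        for s in itertools.product([-1, 1], repeat=4):
            assert modularity_q(B, s) == 0.0


class TestLeadingEigenvectorSplit:
    def test_two_node_positive_coupling_no_split(self):
        B = np.array([[0.0, 1.0], [1.0, 0.0]])
        s, q, found = leading_eigenvector_split(B)
        assert not found and (s == s[0]).all()

    def test_planted_two_block_matches_brute_force(self):
        B = np.full((4, 4), -0.9)
        B[:2, :2] = 0.9
        B[2:, 2:] = 0.9
        np.fill_diagonal(B, 0.0)
        s, q, found = leading_eigenvector_split(B)
        assert found and q > 0
        assert set(map(tuple, [s[:2], s[2:]])) == {(1, 1), (-1, -1)}
        best_q, best_s = brute_force_max_q(B)
        assert q == pytest.approx(best_q)

    def test_zero_matrix_terminates(self):
        s, q, found = leading_eigenvector_split(np.zeros((3, 3)))
        assert not found and q == pytest.approx(0.0)

    def test_never_beats_brute_force_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            g = nx.gnm_random_graph(n, int(rng.integers(n - 1, n * (n - 1) // 2 + 1)),
                                    seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            for u, v in g.edges():
                g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
            D, _ = shortest_path_distances(g)
            B = build_b_matrix(D)
            s, q, found = leading_eigenvector_split(B)
            best_q, _ = brute_force_max_q(B)
            assert q <= best_q + 1e-9

    def test_deterministic_sign_orientation(self):
        B = np.full((4, 4), -0.5)
        B[:2, :2] = 0.5
        B[2:, 2:] = 0.5
        np.fill_diagonal(B, 0.0)
        s1, _, _ = leading_eigenvector_split(B)
        s2, _, _ = leading_eigenvector_split(B.copy())
        assert (s1 == s2).all()
        assert s1[0] == 1  # first nonzero entry oriented positive


class TestRecursivePartition:
    def test_bridge_between_triangles_severed_first(self):
        g = nx.Graph()
        for tri in (["a1", "a2", "a3"], ["b1", "b2", "b3"]):
            g.add_weighted_edges_from(
                [(tri[0], tri[1], 1), (tri[1], tri[2], 1), (tri[0], tri[2], 1)]
            )
        g.add_edge("a1", "b1", weight=5)
        tree = recursive_partition(g)
        assert len(tree.roots) == 1
        root = tree[tree.roots[0]]
        assert len(root.children) == 2
        leaves = sorted(sorted(tree[c].reaction_ids) for c in root.children)
        assert leaves == [["a1", "a2", "a3"], ["b1", "b2", "b3"]]
        for c in root.children:
            assert tree[c].is_terminal

    def test_two_node_component_is_terminal(self):
        g = nx.Graph()
        g.add_edge("x", "y", weight=1.0)
        tree = recursive_partition(g)
        assert len(tree) == 1 and tree[tree.roots[0]].is_terminal

    def test_one_root_per_component(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1)
        g.add_edge("c", "d", weight=1)
        g.add_node("e")
        tree = recursive_partition(g)
        assert len(tree.roots) == 3
        assert tree.reaction_universe() == {"a", "b", "c", "d", "e"}

    def test_determinism(self, planted_run):
        *_, result = planted_run
        again = recursive_partition(result.graph)
        assert len(again) == len(result.tree)
        assert [sorted(m.reaction_ids) for m in again] == [
            sorted(m.reaction_ids) for m in result.tree
        ]

    @given(st.integers(min_value=0, max_value=30))
    def test_invariants_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 16))
        g = nx.gnp_random_graph(n, 0.4, seed=seed)
        for u, v in g.edges():
            g[u][v]["weight"] = float(rng.uniform(0.05, 2.0))
        tree = recursive_partition(g)
        assert_tree_invariants(tree)
        leaf_union = frozenset().union(*(m.reaction_ids for m in tree.leaves()))
        assert leaf_union == frozenset(g.nodes())


class TestAnnotateTree:
    def test_heights_and_density(self, toy):
        from mma.graph_build import build_reaction_graph, reaction_scores

        model, ssm = toy
        rg = build_reaction_graph(model, reaction_scores(model, ssm))
        tree = annotate_tree(recursive_partition(rg), model, ssm)
        for leaf in tree.leaves():
            assert leaf.height == 0
        root = tree[tree.roots[0]]
        assert root.height == max(m.height for m in tree)
        assert root.ssm_count == 4 and root.ssm_density == pytest.approx(4 / 5)

    def test_density_can_exceed_one(self):
        # five reactions collectively touching six SSM nodes: density 1.2
        mets = [f"s{i}[c]" for i in range(6)] + ["x[c]"]
        reactions = [
            ("R0", False, {"s0[c]": 1, "s1[c]": 1}, {"s2[c]": 1}),
            ("R1", False, {"s2[c]": 1}, {"s3[c]": 1}),
            ("R2", False, {"s3[c]": 1}, {"s4[c]": 1}),
            ("R3", False, {"s4[c]": 1}, {"s5[c]": 1}),
            ("R4", False, {"s5[c]": 1}, {"x[c]": 1}),
        ]
        model = make_model(reactions, mets)
        ssm = {f"s{i}[c]" for i in range(6)}
        from mma.graph_build import build_reaction_graph, reaction_scores

        rg = build_reaction_graph(model, reaction_scores(model, ssm))
        tree = annotate_tree(recursive_partition(rg), model, ssm)
        root = tree[tree.roots[0]]
        assert root.ssm_density == pytest.approx(1.2)
        assert root.baseline is True

    def test_no_ssms_zero_density_not_baseline(self, toy):
        from mma.graph_build import build_reaction_graph, reaction_scores

        model, _ = toy
        rg = build_reaction_graph(model, reaction_scores(model, set()))
        tree = annotate_tree(recursive_partition(rg), model, set())
        for m in tree:
            assert m.ssm_density == 0.0 and m.baseline is False


class TestSerialization:
    def test_json_round_trip(self, planted_run, tmp_path):
        *_, result = planted_run
        path = tmp_path / "tree.json"
        result.tree.to_json(path)
        from mma.partition import ModuleTree

        back = ModuleTree.from_json(path)
        assert len(back) == len(result.tree)
        for m in result.tree:
            b = back[m.module_id]
            assert b.reaction_ids == m.reaction_ids
            assert b.height == m.height
            assert b.baseline == m.baseline
            assert b.ssm_density == pytest.approx(m.ssm_density)

    def test_tsv_has_row_per_module(self, planted_run, tmp_path):
        *_, result = planted_run
        path = tmp_path / "tree.tsv"
        result.tree.to_tsv(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(result.tree) + 1
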