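"""Community detection, clique validation and maximal-clique enumeration."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

import plasmidnet as pn
from plasmidnet.detect import Community


def _clique_graph(*cliques, extra_edges=(), threshold=0.0) -> nx.Graph:
    g = nx.Graph(threshold=threshold)
    for members in cliques:
        for a, b in combinations(members, 2):
            g.add_edge(a, b, weight=1.0)
    for a, b in extra_edges:
        g.add_edge(a, b, weight=0.1)
    return g


class TestVertexSignificance:
    def test_candidate_without_cluster_edges_scores_one(self):
        g = _clique_graph(["a", "b", "c"])
        g.add_edge("x", "y", weight=1.0)
        assert pn.vertex_significance("x", {"a", "b", "c"}, g) == 1.0

    def test_full_attachment_to_half_the_endpoints(self):
        # candidate v has k_v = 3, all into a cluster holding half of all
        # edge endpoints: P[Bin(3, 1/2) >= 3] = 0.125
        g = nx.Graph()
        for n in ("a", "b", "c"):
            g.add_edge("v", n)
        # balance endpoints: cluster degree must equal half of 2E
        g.add_edge("a", "x")
        g.add_edge("b", "y")
        cluster = {"a", "b", "c"}
        k_c = sum(g.degree(n) for n in cluster)
        assert k_c == g.number_of_edges()  # half of 2E
        assert pn.vertex_significance("v", cluster, g) == pytest.approx(0.125)

    def test_member_candidates_are_rejected(self):
        g = _clique_graph(["a", "b", "c"])
        with pytest.raises(ValueError):
            pn.vertex_significance("a", {"a", "b"}, g)

    def test_null_scores_stochastically_dominate_uniform(self):
        # On degree-preserving rewirings the observed internal degree is a
        # draw from (approximately) the null, so P[score <= x] <= x + noise.
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(40, 0.15, seed=7)
        cluster = set(range(6))
        candidate = 39
        scores = []
        for i in range(400):
            h = g.copy()
            nx.double_edge_swap(h, nswap=2 * h.number_of_edges(),
                                max_tries=10_000, seed=int(rng.integers(2**31)))
            if h.degree(candidate) == 0:
                continue
            scores.append(pn.vertex_significance(candidate, cluster, h))
        scores = np.sort(scores)
        ecdf = np.arange(1, len(scores) + 1) / len(scores)
        d_plus = float(np.max(ecdf - scores))
        # one-sided DKW bound at alpha = 0.01
        assert d_plus <= np.sqrt(np.log(1 / 0.01) / (2 * len(scores)))


class TestDetectCommunities:
    def test_two_bridged_cliques_are_split_apart(self):
        g = _clique_graph(
            [f"a{i}" for i in range(5)],
            [f"b{i}" for i in range(5)],
            extra_edges=[("a0", "b0")],
        )
        communities = pn.detect_communities(g, pn.DetectionConfig(n_runs=10))
        members = sorted(sorted(c.members) for c in communities)
        assert members == [
            [f"a{i}" for i in range(5)],
            [f"b{i}" for i in range(5)],
        ]

    def test_single_clique_is_one_community(self):
        g = _clique_graph([f"v{i}" for i in range(6)])
        communities = pn.detect_communities(g, pn.DetectionConfig(n_runs=5))
        assert len(communities) == 1
        assert communities[0].members == frozenset(f"v{i}" for i in range(6))

    def test_noise_graph_produces_almost_no_communities(self):
        g = nx.gnp_random_graph(50, 0.05, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g})
        communities = pn.detect_communities(g, pn.DetectionConfig(n_runs=10))
        assert sum(1 for c in communities if len(c.members) >= 3) <= 1

    def test_identical_seed_gives_identical_output(self, small_matrix):
        network = pn.build_network(small_matrix, 0.05)
        config = pn.DetectionConfig(n_runs=5, seed=93)
        first = pn.detect_communities(network, config)
        second = pn.detect_communities(network, config)
        assert [(c.members, c.p_value, c.support) for c in first] == [
            (c.members, c.p_value, c.support) for c in second
        ]


class TestValidateCliques:
    def test_missing_pair_rejects_community(self):
        original = nx.Graph(threshold=0.0)
        original.add_edges_from([("a", "b"), ("b", "c")])
        result = pn.validate_cliques(
            [Community(frozenset("abc"), 0.01, 1.0)], original
        )
        assert result.n_cliques == 0
        assert result.rejected == [(frozenset("abc"), 1)]

    def test_completeness_is_judged_on_original_not_thresholded(self):
        # complete in the original network even though a thresholded network
        # would have dropped the weak edge
        original = _clique_graph(["a", "b", "c"])
        result = pn.validate_cliques(
            [Community(frozenset("abc"), 0.01, 1.0)], original
        )
        assert result.n_cliques == 1
        thresholded = nx.Graph(threshold=0.3)
        with pytest.raises(ValueError, match="threshold"):
            pn.validate_cliques([], thresholded)

    def test_overlapping_cliques_share_a_plasmid(self):
        original = _clique_graph(["a", "b", "c"], ["c", "d", "e"])
        result = pn.validate_cliques(
            [
                Community(frozenset("abc"), 0.01, 1.0),
                Community(frozenset("cde"), 0.02, 1.0),
            ],
            original,
        )
        assert result.n_cliques == 2
        assert len(result.assignment["c"]) == 2
        assert result.multi_assigned() == {"c"}
        # assignment is the exact inverse of cliques
        for cid, members in result.cliques.items():
            for p in members:
                assert cid in result.assignment[p]

    def test_small_communities_are_discarded(self):
        original = _clique_graph(["a", "b"])
        result = pn.validate_cliques(
            [Community(frozenset("ab"), 0.01, 1.0)], original
        )
        assert result.n_cliques == 0 and not result.rejected

    def test_unknown_vertex_is_a_hard_error(self):
        original = _clique_graph(["a", "b", "c"])
        with pytest.raises(ValueError, match="unknown"):
            pn.validate_cliques(
                [Community(frozenset({"a", "b", "zz"}), 0.01, 1.0)], original
            )


def _brute_force_max_cliques(g: nx.Graph, min_size: int) -> set[frozenset]:
    """Exhaustive subset enumeration: every clique, kept if maximal."""
    nodes = list(g.nodes())
    cliques = set()
    for mask in range(1, 1 << len(nodes)):
        members = [nodes[i] for i in range(len(nodes)) if mask >> i & 1]
        if len(members) < min_size:
            continue
        if not all(g.has_edge(a, b) for a, b in combinations(members, 2)):
            continue
        if any(
            all(g.has_edge(u, v) for v in members)
            for u in nodes if u not in members
        ):
            continue  # extendable, hence not maximal
        cliques.add(frozenset(members))
    return cliques


class TestMaxCliques:
    def test_triangle_and_square(self):
        assert pn.max_cliques(nx.complete_graph(3)) == [frozenset({0, 1, 2})]
        assert pn.max_cliques(nx.cycle_graph(4)) == []

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)),
                                    seed=int(rng.integers(2**31)))
            assert set(pn.max_cliques(g, min_size=3)) == \
                _brute_force_max_cliques(g, 3)

    def test_output_order_is_size_then_lexicographic(self):
        g = _clique_graph(["x", "y", "z"], ["a", "b", "c", "d"])
        out = pn.max_cliques(g)
        assert out == [frozenset("abcd"), frozenset("xyz")]


class TestInternalSimilarity:
    def test_mean_of_pairwise_ji(self):
        mat = pn.SimilarityMatrix(ids=["a", "b", "c"], min_shared=1)
        mat.entries = {(0, 1): (0.4, 5), (0, 2): (0.5, 5), (1, 2): (0.6, 5)}
        assert pn.internal_similarity({"a", "b", "c"}, mat) == pytest.approx(0.5)

    def test_duplicate_plasmid_clique_scores_one(self):
        mat = pn.SimilarityMatrix(ids=["a", "b"], min_shared=1)
        mat.entries = {(0, 1): (1.0, 100)}
        assert pn.internal_similarity({"a", "b"}, mat) == 1.0

    def test_undefined_below_two_members(self):
        mat = pn.SimilarityMatrix(ids=["a"], min_shared=1)
        with pytest.raises(ValueError):
            pn.internal_similarity({"a"}, mat)
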