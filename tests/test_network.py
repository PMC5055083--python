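"""Tests for the term perturbation network, cluster graphs, orthogonality
metrics and precision-recall evaluation."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metscreen as ms
from metscreen.enrich import GeneSetCollection


def collection(sets):
    return GeneSetCollection(sets={k: set(v) for k, v in sets.items()})


def term_graph(edges):
    return pd.DataFrame(edges, columns=["child", "parent"])


class TestPerturbationNetwork:
    def test_identical_gene_sets_with_link_share_an_edge(self):
        ann = collection({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        g = ms.build_perturbation_network(
            ["A", "B"], ann, term_graph([("A", "B")]), 0.5, 2
        )
        assert g.has_edge("A", "B")
        assert g.edges["A", "B"]["overlap"] == pytest.approx(1.0)

    def test_forty_percent_overlap_fails_the_half_threshold(self):
        ann = collection({"A": {"g1", "g2", "g3", "g4", "g5"},
                          "B": {"g1", "g2", "x3", "x4", "x5"}})
        g = ms.build_perturbation_network(
            ["A", "B"], ann, term_graph([("A", "B")]), 0.5, 2
        )
        assert g.number_of_edges() == 0

    def test_toy_dag_matches_brute_force_application_of_both_rules(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        terms = {f"T{j}": set(rng.choice(genes, size=rng.integers(4, 10),
                                         replace=False)) for j in range(6)}
        ann = collection(terms)
        edges = term_graph(
            [("T1", "T0"), ("T2", "T0"), ("T3", "T1"), ("T4", "T2"), ("T5", "T4")]
        )
        g = ms.build_perturbation_network(list(terms), ann, edges, 0.5, 2)
        parent_child = nx.Graph(list(edges.itertuples(index=False, name=None)))
        for a, b in combinations(terms, 2):
            frac = len(terms[a] & terms[b]) / min(len(terms[a]), len(terms[b]))
            try:
                path = nx.shortest_path_length(parent_child, a, b)
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                path = math.inf
            assert g.has_edge(a, b) == (frac > 0.5 and path <= 2)

    def test_term_missing_from_graph_keeps_node_without_edges(self):
        ann = collection({"A": {"g1"}, "B": {"g1"}})
        g = ms.build_perturbation_network(["A", "B"], ann,
                                          term_graph([("A", "ROOT")]), 0.5, 2)
        assert set(g.nodes) == {"A", "B"}
        assert g.number_of_edges() == 0

    def test_communities_assigned(self):
        ann = collection({
            "A": {"g1", "g2"}, "B": {"g1", "g2"},
            "C": {"h1", "h2"}, "D": {"h1", "h2"},
        })
        edges = term_graph([("A", "B"), ("C", "D"), ("B", "C")])
        g = ms.build_perturbation_network(list(ann.sets), ann, edges, 0.5, 2)
        comm = nx.get_node_attributes(g, "community")
        assert comm["A"] == comm["B"]
        assert comm["C"] == comm["D"]


class TestClusterGraph:
    def test_single_cluster_of_four_has_six_edges(self):
        labels = pd.Series({f"g{i}": 1 for i in range(4)})
        assert ms.cluster_graph(labels).number_of_edges() == 6

    def test_sizes_three_two_two(self):
        labels = pd.Series({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 3, "g": 3})
        assert ms.cluster_graph(labels).number_of_edges() == 3 + 1 + 1

    def test_unassigned_strains_excluded(self):
        labels = pd.Series({"a": 1, "b": 1, "c": 0})
        g = ms.cluster_graph(labels)
        assert "c" not in g.nodes

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=5), min_size=2, max_size=40))
    def test_edge_count_identity_for_random_labelings(self, labs):
        labels = pd.Series(labs, index=[f"g{i}" for i in range(len(labs))])
        g = ms.cluster_graph(labels)
        expected = sum(
            math.comb(int(c), 2)
            for lab, c in labels.value_counts().items()
            if lab > 0
        )
        assert g.number_of_edges() == expected


class TestNetworkOverlap:
    def test_identity_case(self):
        labels = pd.Series({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2})
        g = ms.cluster_graph(labels)
        out = ms.network_overlap(g, g)
        assert out["edge_overlap"] == 1.0
        assert out["edge_ratio"] == 1.0
        assert out["shared_nodes"] == 5

    def test_disjoint_edge_sets_give_zero_overlap(self):
        g1 = nx.Graph([("a", "b"), ("c", "d")])
        g2 = nx.Graph([("a", "c"), ("b", "d")])
        assert ms.network_overlap(g1, g2)["edge_overlap"] == 0.0

    def test_matches_set_intersection_oracle_on_random_graphs(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(15)]
        def random_graph(seed):
            r = np.random.default_rng(seed)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for a, b in combinations(nodes, 2):
                if r.random() < 0.2:
                    g.add_edge(a, b)
            return g
        g1, g2 = random_graph(2), random_graph(3)
        out = ms.network_overlap(g1, g2)
        e1 = {frozenset(e) for e in g1.edges}
        e2 = {frozenset(e) for e in g2.edges}
        assert out["edge_overlap"] == pytest.approx(len(e1 & e2) / len(e1))

    def test_no_shared_nodes_is_error(self):
        with pytest.raises(ValueError):
            ms.network_overlap(nx.Graph([("a", "b")]), nx.Graph([("x", "y")]))


class TestPrecisionRecall:
    def gold(self, tps, tns):
        return pd.DataFrame(
            [(a, b, 1) for a, b in tps] + [(a, b, 0) for a, b in tns],
            columns=["gene_a", "gene_b", "label"],
        )

    def ranking(self, pairs_scores):
        return pd.DataFrame(
            [(a, b, s) for (a, b), s in pairs_scores.items()],
            columns=["gene_a", "gene_b", "consensus"],
        )

    def test_perfect_ranking_holds_precision_one_until_tp_exhausted(self):
        tps = [("a", "b"), ("c", "d"), ("e", "f")]
        tns = [("a", "c"), ("b", "d"), ("e", "a")]
        scores = {p: 1.0 - 0.01 * i for i, p in enumerate(tps)}
        scores |= {p: 0.5 - 0.01 * i for i, p in enumerate(tns)}
        curve = ms.precision_recall(self.ranking(scores), self.gold(tps, tns))
        pure = curve[curve["fp"] == 0]
        assert (pure["precision"] == 1.0).all()
        assert pure["tp"].max() == 3  # all TPs recovered before any FP

    def test_hand_enumerated_eight_pair_table(self):
        # scores descending: TP TN TP TP TN TN TP TN
        pairs = [("a","b"),("a","c"),("a","d"),("b","c"),("b","d"),
                 ("c","d"),("c","e"),("d","e")]
        labels = [1, 0, 1, 1, 0, 0, 1, 0]
        scores = {p: 0.9 - 0.1 * i for i, p in enumerate(pairs)}
        gold = pd.DataFrame(
            [(a, b, l) for (a, b), l in zip(pairs, labels)],
            columns=["gene_a", "gene_b", "label"],
        )
        curve = ms.precision_recall(self.ranking(scores), gold)
        expected = [
            (1, 0, 1.0), (1, 1, 1 / 2), (2, 1, 2 / 3), (3, 1, 3 / 4),
            (3, 2, 3 / 5), (3, 3, 1 / 2), (4, 3, 4 / 7), (4, 4, 1 / 2),
        ]
        got = list(zip(curve["tp"], curve["fp"], curve["precision"]))
        assert got == [
            (tp, fp, pytest.approx(prec)) for tp, fp, prec in expected
        ]

    def test_ties_processed_as_a_block(self):
        tps = [("a", "b")]
        tns = [("a", "c"), ("b", "c")]
        scores = {("a", "b"): 0.5, ("a", "c"): 0.5, ("b", "c"): 0.5}
        curve = ms.precision_recall(self.ranking(scores), self.gold(tps, tns))
        assert len(curve) == 1
        assert curve.loc[0, "precision"] == pytest.approx(1 / 3)

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(4)
        pairs = [(f"a{i}", f"b{i}") for i in range(30)]
        labels = rng.integers(0, 2, size=30)
        labels[0] = 1; labels[1] = 0
        scores = dict(zip(pairs, rng.random(30)))
        gold = pd.DataFrame(
            [(a, b, l) for (a, b), l in zip(pairs, labels)],
            columns=["gene_a", "gene_b", "label"],
        )
        c1 = ms.precision_recall(self.ranking(scores), gold)
        c2 = ms.precision_recall(
            self.ranking({p: np.exp(3 * s) for p, s in scores.items()}), gold
        )
        assert np.allclose(c1["precision"], c2["precision"])
        assert np.array_equal(c1["tp"], c2["tp"])

    def test_unranked_gold_pairs_enter_with_score_zero(self):
        tps = [("a", "b"), ("c", "d")]
        tns = [("a", "c"), ("b", "d")]
        scores = {("a", "b"): 0.9}  # other gold pairs unranked
        curve = ms.precision_recall(self.ranking(scores), self.gold(tps, tns))
        assert curve.iloc[0]["precision"] == 1.0
        assert curve.iloc[-1]["tp"] == 2

    def test_precision_at_recall(self):
        curve = pd.DataFrame(
            {"threshold": [0.9, 0.5], "tp": [2, 4], "fp": [0, 4],
             "precision": [1.0, 0.5]}
        )
        assert ms.precision_at_recall(curve, 3) == 0.5
        assert ms.precision_at_recall(curve, 100) == 0.5

    def test_gold_without_positives_is_error(self):
        gold = self.gold([], [("a", "b"), ("c", "d")])
        with pytest.raises(ValueError):
            ms.precision_recall(self.ranking({("a", "b"): 1.0}), gold)
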