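"""Phenotype-network construction and evaluation.

Builds the term "perturbation network" (enriched terms connected by gene
overlap and parent-child proximity), turns a cluster assignment into a fully
connected within-cluster graph, measures edge overlap against reference
interaction networks (orthogonality), and evaluates consensus-ranked gene
pairs against gold-standard pair sets by precision-recall.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_perturbation_network",
    "cluster_graph",
    "network_overlap",
    "precision_recall",
    "precision_at_recall",
]

log = logging.getLogger(__name__)


def build_perturbation_network(
    enriched,
    annotation,
    term_graph: pd.DataFrame,
    overlap_threshold: float = 0.5,
    max_path: int = 2,
) -> nx.Graph:
    """Connect enriched terms that share genes and sit close in the ontology.

    An edge (A, B) is drawn iff the gene overlap exceeds
    ``overlap_threshold`` as a fraction of the smaller term's gene set AND
    the undirected shortest path between A and B in the parent-child graph is
    at most ``max_path``.  Terms absent from the parent-child graph stay as
    nodes but can gain no edges (logged).  Communities are found by
    edge-betweenness (Girvan-Newman) at the modularity-maximal cut and stored
    as the node attribute ``community``.
    """
    enriched = list(enriched)
    missing = [t for t in enriched if t not in annotation.sets]
    if missing:
        raise ValueError(f"terms not in annotation: {missing}")
    parent_child = nx.Graph()
    parent_child.add_edges_from(
        term_graph[["child", "parent"]].itertuples(index=False, name=None)
    )
    g = nx.Graph()
    g.add_nodes_from(enriched)
    for i, a in enumerate(enriched):
        for b in enriched[i + 1 :]:
            ga, gb = annotation.sets[a], annotation.sets[b]
            smaller = min(len(ga), len(gb))
            if smaller == 0:
                continue
            frac = len(ga & gb) / smaller
            if frac <= overlap_threshold:
                continue
            if a not in parent_child or b not in parent_child:
                log.info("term %s or %s missing from term graph; no edge", a, b)
                continue
            try:
                path = nx.shortest_path_length(parent_child, a, b)
            except nx.NetworkXNoPath:
                continue
            if path <= max_path:
                g.add_edge(a, b, overlap=frac)

    for node, community in _edge_betweenness_communities(g).items():
        g.nodes[node]["community"] = community
    return g


def _edge_betweenness_communities(g: nx.Graph) -> dict:
    """Girvan-Newman partition at the modularity maximum."""
    communities = {n: 0 for n in g.nodes}
    if g.number_of_edges() == 0:
        return {n: i for i, n in enumerate(g.nodes)}
    # candidates: the connected components (which girvan_newman never
    # yields) and every successive edge-betweenness split
    components = [set(c) for c in nx.connected_components(g)]
    best_q, best = nx.community.modularity(g, components), components
    for partition in nx.community.girvan_newman(g):
        q = nx.community.modularity(g, partition)
        if q > best_q:
            best_q, best = q, partition
    for i, comm in enumerate(best):
        for n in comm:
            communities[n] = i
    return communities


def cluster_graph(labels: pd.Series) -> nx.Graph:
    """Fully connected graph per cluster; unassigned (label 0) excluded.

    The edge count is the combinatorial identity sum_k C(n_k, 2).
    """
    labels = labels[labels > 0]
    g = nx.Graph()
    g.add_nodes_from(labels.index)
    for _, members in labels.groupby(labels).groups.items():
        members = list(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                g.add_edge(a, b)
    return g


def network_overlap(metabolic: nx.Graph, reference: nx.Graph) -> dict:
    """Edge overlap and ratio on the shared node set.

    Both graphs are restricted to their shared nodes; ``edge_overlap`` is the
    fraction of metabolic edges present in the reference, ``edge_ratio`` the
    reference/metabolic edge-count ratio.
    """
    shared = set(metabolic.nodes) & set(reference.nodes)
    if not shared:
        raise ValueError("graphs share no nodes")
    met = metabolic.subgraph(shared)
    ref = reference.subgraph(shared)
    met_edges = {frozenset(e) for e in met.edges}
    ref_edges = {frozenset(e) for e in ref.edges}
    n_met = len(met_edges)
    return {
        "edge_overlap": len(met_edges & ref_edges) / n_met if n_met else np.nan,
        "edge_ratio": len(ref_edges) / n_met if n_met else np.nan,
        "shared_nodes": len(shared),
    }


def _pair_key(a, b):
    return (a, b) if a <= b else (b, a)


def precision_recall(ranking: pd.DataFrame, gold: pd.DataFrame) -> pd.DataFrame:
    """Precision-recall sweep of a consensus-ranked pair list.

    ``ranking`` has columns gene_a, gene_b and a score column (the last
    column); ``gold`` has gene_a, gene_b, label (1 = TP, 0 = TN).  Gold pairs
    absent from the ranking enter with score 0.  The sweep descends through
    distinct scores with ties processed as a block; recall is reported as the
    TP count.  Returns a frame with columns threshold, tp, fp, precision.
    """
    if gold["label"].nunique() < 2 or gold["label"].sum() == 0:
        raise ValueError("gold standard must contain both positives and negatives")
    score_col = ranking.columns[-1]
    scores = {
        _pair_key(a, b): s
        for a, b, s in ranking[["gene_a", "gene_b", score_col]].itertuples(index=False)
    }
    labeled = pd.DataFrame(
        {
            "score": [
                scores.get(_pair_key(a, b), 0.0)
                for a, b in gold[["gene_a", "gene_b"]].itertuples(index=False)
            ],
            "label": gold["label"].to_numpy(),
        }
    ).sort_values("score", ascending=False, kind="mergesort")

    rows = []
    tp = fp = 0
    for threshold, block in labeled.groupby("score", sort=False):
        tp += int(block["label"].sum())
        fp += int((1 - block["label"]).sum())
        rows.append(
            {
                "threshold": threshold,
                "tp": tp,
                "fp": fp,
                "precision": tp / (tp + fp),
            }
        )
    return pd.DataFrame(rows)


def precision_at_recall(curve: pd.DataFrame, tp_target: int) -> float:
    """Precision at the first sweep point reaching ``tp_target`` true
    positives (the last point if never reached)."""
    reached = curve[curve["tp"] >= tp_target]
    row = reached.iloc[0] if len(reached) else curve.iloc[-1]
    return float(row["precision"])
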