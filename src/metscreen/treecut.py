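"""Adaptive branch pruning ("dynamic tree cut") of a dendrogram.

Clusters are extracted from a hierarchical-clustering tree by shape-aware
branch decomposition instead of a single fixed cut height.  The hybrid scheme
implemented here:

1. The tree is split unconditionally above a cut height (by default 99% of
   the merge-height range), yielding top-level branches.
2. Each branch is decomposed recursively.  A merge node is split into its two
   children when both children are *distinct* branches: at least
   ``min_cluster_size`` leaves, a core scatter (mean internal merge height)
   below a threshold, and a gap between the node's merge height and the
   child's core scatter above a minimum.  The two thresholds are controlled
   by ``deep_split`` (0..4): higher values tolerate more scatter and require
   smaller gaps, producing a finer split.  The threshold ladder
   (0.64/0.73/0.82/0.91/0.95 of the height range) follows the convention of
   the R dynamicTreeCut package.
3. Leaves that end up outside any accepted branch (small, non-distinct side
   branches) are assigned to the nearest cluster by average distance if close
   enough (a PAM-like stage), otherwise labeled 0 (unassigned).
"""

from __future__ import annotations

import numpy as np

__all__ = ["cut_tree_hybrid"]

#: maximum core scatter, as a fraction of the usable height range, per
#: deep_split level 0..4
_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


def _subtree_stats(Z: np.ndarray):
    """Per-node leaf lists, counts and core scatter (mean merge height)."""
    n = Z.shape[0] + 1
    leaves: list[list[int]] = [[i] for i in range(n)] + [None] * (n - 1)
    hsum = np.zeros(2 * n - 1)
    for k in range(n - 1):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        leaves[n + k] = leaves[a] + leaves[b]
        hsum[n + k] = hsum[a] + hsum[b] + Z[k, 2]
    counts = np.array([len(lv) for lv in leaves])
    scatter = np.where(counts > 1, hsum / np.maximum(counts - 1, 1), 0.0)
    return leaves, counts, scatter


def cut_tree_hybrid(
    Z: np.ndarray,
    dist: np.ndarray,
    min_cluster_size: int = 2,
    deep_split: int = 4,
    respect_small_clusters: bool = True,
    cut_height: float | None = None,
    pam_stage: bool = True,
) -> np.ndarray:
    """Extract cluster labels from a linkage matrix.

    Parameters
    ----------
    Z
        scipy linkage matrix.
    dist
        Square distance matrix used to build ``Z`` (for the PAM-like
        assignment of leftover leaves).
    min_cluster_size, deep_split, respect_small_clusters
        The three exposed tuning parameters; ``deep_split`` in 0..4.
    cut_height
        Static split height; default min + 0.99 * (max - min) merge height.
    pam_stage
        Assign unlabeled leaves to the nearest cluster when their average
        distance to it is below the cut height.

    Returns
    -------
    labels : ndarray of int, 0 = unassigned, clusters numbered by
        decreasing size.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0] + 1
    dist = np.asarray(dist, dtype=float)
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    heights = Z[:, 2]
    hmin, hmax = float(heights.min()), float(heights.max())
    span = hmax - hmin
    if span <= 0:  # degenerate: everything merges at one height
        return (
            np.ones(n, dtype=int)
            if n >= min_cluster_size
            else np.zeros(n, dtype=int)
        )
    if cut_height is None:
        cut_height = hmin + 0.99 * span
    usable = cut_height - hmin
    max_scatter = hmin + _MAX_CORE_SCATTER[deep_split] * usable
    min_gap = (1.0 - _MAX_CORE_SCATTER[deep_split]) * 0.75 * usable

    leaves, counts, scatter = _subtree_stats(Z)
    node_height = np.concatenate([np.zeros(n), heights])

    def separated(child: int, parent_height: float) -> bool:
        # the merge joining a child branch to its sibling sits clearly above
        # the child's own core scatter (a height gap in the dendrogram) and
        # the child is not internally diffuse
        return (
            scatter[child] <= max_scatter
            and (parent_height - scatter[child]) >= min_gap
        )

    def distinct(child: int, parent_height: float) -> bool:
        return counts[child] >= min_cluster_size and separated(child, parent_height)

    clusters: list[list[int]] = []
    unassigned: list[int] = []

    def branch(root: int) -> None:
        """Decompose a branch rooted below the cut height (iterative)."""
        todo = [root]
        while todo:
            node = todo.pop()
            if counts[node] < min_cluster_size:
                unassigned.extend(leaves[node])
                continue
            if node < n:  # single leaf, only a cluster if min size is 1
                clusters.append(leaves[node])
                continue
            a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
            h = node_height[node]
            da, db = distinct(a, h), distinct(b, h)
            if da and db:
                todo.append(a)
                todo.append(b)
            elif da and counts[b] < min_cluster_size and respect_small_clusters:
                unassigned.extend(leaves[b])
                todo.append(a)
            elif db and counts[a] < min_cluster_size and respect_small_clusters:
                unassigned.extend(leaves[a])
                todo.append(b)
            elif (
                separated(a, h)
                and separated(b, h)
                and counts[a] < min_cluster_size
                and counts[b] < min_cluster_size
            ):
                # an artificial union of two well-separated branches that are
                # each below the minimum size is not a cluster
                unassigned.extend(leaves[node])
            else:
                clusters.append(leaves[node])

    # stage 1: forced split above the cut height
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node >= n and node_height[node] >= cut_height:
            stack.append(int(Z[node - n, 0]))
            stack.append(int(Z[node - n, 1]))
        else:
            branch(node)

    labels = np.zeros(n, dtype=int)
    clusters.sort(key=len, reverse=True)
    for k, members in enumerate(clusters, start=1):
        labels[members] = k

    if pam_stage and clusters and unassigned:
        members_by_cluster = [np.array(m) for m in clusters]
        for leaf in unassigned:
            avg = np.array([dist[leaf, m].mean() for m in members_by_cluster])
            best = int(np.argmin(avg))
            if avg[best] <= cut_height:
                labels[leaf] = best + 1
    return labels
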