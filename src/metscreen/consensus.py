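"""Perturbation-based consensus clustering of metabolic signatures.

Strains are clustered by pairwise Mahalanobis distance (whitened by the
robust covariance of the screen) with Ward agglomeration.  To obtain a
stability-aware similarity, the data are perturbed: in each iteration a
random 0-20% of profiles is removed, the survivors are re-clustered, and the
dendrogram is cut at 8 depths (evenly spaced fractions of the merge-height
range).
The consensus index c_ij is the fraction of cut x iteration combinations in
which i and j landed in the same cluster, normalized by the number of
iterations in which both survived — so removal never deflates similarity.
1 - consensus is then the distance for a final Ward clustering whose
dendrogram is cut by adaptive branch pruning (:mod:`metscreen.treecut`).

::

    model = ConsensusClusterModel(matrix, covariance=estimate.covariance)
    res = model.fit(n_iterations=500, seed=0)
    labels = res.final_clusters(min_cluster_size=2, deep_split=4)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import pdist, squareform

from .treecut import cut_tree_hybrid

__all__ = [
    "pairwise_mahalanobis",
    "ConsensusClusterModel",
    "ConsensusResults",
    "co_cluster_with_reference",
]


def pairwise_mahalanobis(matrix: pd.DataFrame, covariance) -> np.ndarray:
    """Condensed pairwise Mahalanobis distance matrix.

    d_ij = sqrt((x_i - x_j)^T Sigma^-1 (x_i - x_j)); computed by whitening
    with the Cholesky factor of Sigma and taking Euclidean distances.
    """
    X = np.asarray(matrix, dtype=float)
    cov = np.asarray(covariance, dtype=float)
    try:
        L = cholesky(cov, lower=True)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance must be positive definite") from err
    white = solve_triangular(L, X.T, lower=True).T
    return pdist(white)


def _cut_depth_heights(merge_heights: np.ndarray, n_depths: int) -> np.ndarray:
    """Cut heights at evenly spaced depths of the dendrogram.

    Depths are fractions (10%..80%) of the merge-height *range*, not
    quantiles of the merge-height distribution: metabolic signatures group by
    shared location rather than reduced internal spread, so the informative
    splits are the top-level ones and quantile-based cuts would fragment
    genuine groups.
    """
    lo, hi = merge_heights.min(), merge_heights.max()
    q = np.linspace(0.1, 0.8, n_depths)
    return lo + q * (hi - lo)


class ConsensusClusterModel:
    """Consensus clustering over a precomputed or derivable distance matrix.

    Provide either ``matrix`` plus ``covariance`` (pairwise Mahalanobis is
    computed) or a condensed ``distances`` vector with ``ids``.
    """

    def __init__(
        self,
        matrix: pd.DataFrame | None = None,
        covariance=None,
        distances: np.ndarray | None = None,
        ids=None,
    ):
        if distances is not None:
            self.distances = np.asarray(distances, dtype=float)
            m = self.distances.shape[0]
            n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
            self.ids = pd.Index(ids) if ids is not None else pd.RangeIndex(n)
        elif matrix is not None:
            if covariance is None:
                covariance = np.cov(np.asarray(matrix, dtype=float), rowvar=False)
            self.distances = pairwise_mahalanobis(matrix, covariance)
            self.ids = pd.Index(matrix.index)
        else:
            raise ValueError("provide matrix or distances")
        self.n = len(self.ids)
        if self.n < 3:
            raise ValueError("need at least 3 profiles")

    def fit(
        self,
        n_iterations: int = 500,
        removal_range: tuple = (0.0, 0.2),
        n_depths: int = 8,
        seed: int = 0,
    ) -> "ConsensusResults":
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        lo, hi = removal_range
        if not (0.0 <= lo <= hi < 0.5):
            raise ValueError("removal_range must lie within [0, 0.5)")
        rng = np.random.default_rng(seed)
        n = self.n
        square = squareform(self.distances)
        co_count = np.zeros((n, n))
        co_retained = np.zeros((n, n), dtype=np.int64)
        redrawn = 0

        it = 0
        while it < n_iterations:
            frac = rng.uniform(lo, hi)
            n_keep = int(round(n * (1.0 - frac)))
            if n_keep < 3:
                redrawn += 1  # logged; iteration redrawn
                continue
            keep = np.sort(rng.choice(n, size=n_keep, replace=False))
            sub = square[np.ix_(keep, keep)]
            Z = linkage(squareform(sub, checks=False), method="ward")
            heights = Z[:, 2]
            ix = np.ix_(keep, keep)
            co_retained[ix] += 1
            for t in _cut_depth_heights(heights, n_depths):
                labels = fcluster(Z, t=t, criterion="distance")
                co_count[ix] += labels[:, None] == labels[None, :]
            it += 1

        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = co_count / (co_retained * n_depths)
        consensus[co_retained == 0] = np.nan  # never co-retained: unknown
        np.fill_diagonal(consensus, 1.0)
        return ConsensusResults(
            consensus=pd.DataFrame(consensus, index=self.ids, columns=self.ids),
            co_retained=pd.DataFrame(co_retained, index=self.ids, columns=self.ids),
            params={
                "n_iterations": n_iterations,
                "removal_range": tuple(removal_range),
                "n_depths": n_depths,
                "seed": seed,
                "redrawn_iterations": redrawn,
            },
        )


@dataclass
class ConsensusResults:
    """Consensus-index matrix plus the final cluster extraction."""

    consensus: pd.DataFrame
    co_retained: pd.DataFrame
    params: dict
    labels: pd.Series | None = field(default=None)

    def distance_matrix(self) -> np.ndarray:
        """1 - consensus; pairs never co-retained are treated as maximally
        distant (their consensus is unknown, reported as NaN)."""
        d = 1.0 - self.consensus.to_numpy(copy=True)
        d[np.isnan(d)] = 1.0
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 1.0)

    def final_clusters(
        self,
        min_cluster_size: int = 2,
        deep_split: int = 4,
        respect_small_clusters: bool = True,
        pam_stage: bool = True,
    ) -> pd.Series:
        """Ward clustering of 1 - consensus, cut by adaptive branch pruning;
        label 0 marks unassigned strains."""
        d = self.distance_matrix()
        Z = linkage(squareform(d, checks=False), method="ward")
        labels = cut_tree_hybrid(
            Z,
            d,
            min_cluster_size=min_cluster_size,
            deep_split=deep_split,
            respect_small_clusters=respect_small_clusters,
            pam_stage=pam_stage,
        )
        self.labels = pd.Series(labels, index=self.consensus.index, name="cluster")
        return self.labels

    def plot_heatmap(self, ax=None):
        from .plots import plot_consensus_heatmap

        return plot_consensus_heatmap(self, ax=ax)

    def pair_ranking(self) -> pd.DataFrame:
        """All strain pairs ranked by consensus index, descending (ties
        contiguous); pairs never co-retained are omitted."""
        c = self.consensus.to_numpy()
        ids = self.consensus.index
        iu = np.triu_indices(len(ids), k=1)
        frame = pd.DataFrame(
            {
                "gene_a": ids[iu[0]],
                "gene_b": ids[iu[1]],
                "consensus": c[iu],
            }
        ).dropna(subset=["consensus"])
        return frame.sort_values("consensus", ascending=False, kind="mergesort").reset_index(
            drop=True
        )


def co_cluster_with_reference(
    z_matrix: pd.DataFrame,
    external: pd.DataFrame,
    correlation: pd.DataFrame,
    labels: pd.Series | None = None,
):
    """Jointly cluster screen profiles with external standardized profiles.

    ``z_matrix`` are the screen's standardized profiles (per-metabolite
    Z-scores), ``external`` one standardized profile per row (same columns),
    e.g. a drug-treated wild type.  Both live on the same scale, so the
    robust correlation matrix plays the covariance role in the joint pairwise
    Mahalanobis distance.  Returns ``(Z_linkage, assignments)`` where
    ``assignments`` reports, per external profile, its nearest strain, the
    distance, and that strain's final-cluster label (if ``labels`` given).
    """
    if list(external.columns) != list(z_matrix.columns):
        external = external.reindex(columns=z_matrix.columns)
        if external.isna().any().any():
            raise ValueError("external profiles do not match screen metabolites")
    joint = pd.concat([z_matrix, external], axis=0)
    dist = pairwise_mahalanobis(joint, correlation)
    Z = linkage(dist, method="ward")
    square = squareform(dist)
    n = len(z_matrix)
    rows = []
    for k, name in enumerate(external.index):
        d_to_strains = square[n + k, :n]
        nearest = int(np.argmin(d_to_strains))
        strain = z_matrix.index[nearest]
        rows.append(
            {
                "profile": name,
                "nearest_strain": strain,
                "distance": float(d_to_strains[nearest]),
                "cluster": int(labels.loc[strain]) if labels is not None else None,
            }
        )
    return Z, pd.DataFrame(rows).set_index("profile")
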