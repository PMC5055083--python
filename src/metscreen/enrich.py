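"""Functional enrichment of significance profiles and clusters.

Two engines: a gene-set enrichment test that aggregates the per-gene
multivariate χ² statistic (squared Mahalanobis distance) over a set and
compares it to a gene-sampling null, and the classical upper-tail
hypergeometric overlap test.  Cluster annotation runs the hypergeometric test
per cluster, optionally in leave-one-out mode where the studied ORF is
removed from both its cluster and the background before testing, and the
cluster's enriched terms are propagated to the ORF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import read_gmt, write_gmt

__all__ = [
    "GeneSetCollection",
    "gsea_chi2",
    "hypergeom_enrich",
    "annotate_clusters",
    "term_response_rate",
]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe of scoreable genes."""

    sets: dict  # term_id -> set of genes
    names: dict = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self):
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()

    @classmethod
    def from_gmt(cls, path, universe=None):
        sets = read_gmt(path)
        return cls(sets=sets, universe=set(universe) if universe else set())

    def to_gmt(self, path):
        write_gmt(self.sets, path, self.names)

    def restrict(self, universe, min_size: int = 1, max_size: int | None = None):
        """Intersect every term with ``universe`` and drop empty/out-of-range
        terms; the restriction is logged."""
        universe = set(universe)
        out = {}
        for term, genes in self.sets.items():
            g = genes & universe
            if len(g) < min_size or (max_size is not None and len(g) > max_size):
                continue
            out[term] = g
        log.info("restricted %d terms to %d (universe %d)", len(self.sets), len(out), len(universe))
        return GeneSetCollection(sets=out, names=self.names, universe=universe)

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, term):
        return self.sets[term]

    def items(self):
        return self.sets.items()


def _bh(frame: pd.DataFrame) -> pd.DataFrame:
    if len(frame):
        frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
    else:
        frame["q"] = pd.Series(dtype=float)
    return frame


def gsea_chi2(
    gene_stats: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
    max_size: int = 500,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Gene-set enrichment on per-gene χ² (D²) statistics.

    The set statistic is the mean (or median) gene-level statistic; the null
    is built from ``n_perm`` random same-size gene samples drawn from the
    universe, so p = (1 + #{null >= observed}) / (1 + n_perm).  Enrichment is
    non-directional: the statistic measures magnitude of metabolic impact.
    Terms smaller than ``min_size`` after restriction are skipped (logged).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    gene_stats = gene_stats.dropna()
    universe = set(gene_stats.index)
    values = gene_stats.to_numpy(dtype=float)
    index_of = {g: i for i, g in enumerate(gene_stats.index)}
    agg = np.mean if aggregate == "mean" else np.median
    rng = np.random.default_rng(seed)

    restricted = sets.restrict(universe, min_size=1)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for term, genes in restricted.items():
        size = len(genes)
        if size < min_size or size > max_size:
            log.info("term %s skipped (size %d)", term, size)
            continue
        idx = np.fromiter((index_of[g] for g in genes), dtype=int)
        observed = agg(values[idx])
        if size not in null_cache:
            draws = rng.integers(0, len(values), size=(n_perm, size))
            null_cache[size] = agg(values[draws], axis=1)
        null = null_cache[size]
        p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
        rows.append(
            {
                "term": term,
                "name": sets.names.get(term, term),
                "size": size,
                "statistic": float(observed),
                "p": float(p),
            }
        )
    return _bh(pd.DataFrame(rows))


def hypergeom_enrich(
    selected,
    annotation: GeneSetCollection,
    universe=None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap test per term.

    p = P(X >= overlap) with X ~ Hypergeom(|universe|, |term|, |selected|);
    BH-adjusted across terms.
    """
    selected = set(selected)
    if not selected:
        raise ValueError("selected gene set is empty")
    universe = set(universe) if universe is not None else set(annotation.universe)
    if not selected <= universe:
        raise ValueError("selected genes must be contained in the universe")
    restricted = annotation.restrict(universe, min_size=1)
    M, N = len(universe), len(selected)
    rows = []
    for term, genes in restricted.items():
        K = len(genes)
        overlap = genes & selected
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append(
            {
                "term": term,
                "name": annotation.names.get(term, term),
                "size": K,
                "overlap": k,
                "overlap_genes": ",".join(sorted(overlap)),
                "p": min(p, 1.0),
            }
        )
    return _bh(pd.DataFrame(rows))


def annotate_clusters(
    labels: pd.Series,
    annotation: GeneSetCollection,
    universe=None,
    mode: str = "cluster",
    alpha: float = 0.05,
):
    """Attach enriched terms to clusters or, in leave-one-out mode, to ORFs.

    ``mode="cluster"``: hypergeometric enrichment per cluster (label > 0).
    ``mode="per_orf_loo"``: for each ORF, its cluster minus the ORF is tested
    against the universe minus the ORF and terms with q < alpha are
    propagated to the ORF; singleton-cluster ORFs are reported
    unannotatable.  Returns ``(table, fraction_annotated)``.
    """
    labels = labels[labels > 0]
    if labels.empty:
        raise ValueError("no assigned cluster labels")
    universe = set(universe) if universe is not None else set(labels.index)

    if mode == "cluster":
        frames = []
        for cl, members in labels.groupby(labels).groups.items():
            res = hypergeom_enrich(set(members) & universe, annotation, universe)
            res.insert(0, "cluster", cl)
            frames.append(res)
        table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        hits = table[table["q"] < alpha] if len(table) else table
        annotated = set(labels.index[labels.isin(set(hits.get("cluster", [])))])
        return table, len(annotated) / len(labels)

    if mode != "per_orf_loo":
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    annotated = set()
    for orf, cl in labels.items():
        members = set(labels.index[labels == cl]) - {orf}
        if not members:
            rows.append({"orf": orf, "cluster": cl, "term": None, "p": np.nan, "q": np.nan})
            continue
        res = hypergeom_enrich(members & universe - {orf}, annotation, universe - {orf})
        hits = res[res["q"] < alpha]
        if hits.empty:
            rows.append({"orf": orf, "cluster": cl, "term": None, "p": np.nan, "q": np.nan})
        else:
            annotated.add(orf)
            for _, r in hits.iterrows():
                rows.append(
                    {"orf": orf, "cluster": cl, "term": r["term"], "p": r["p"], "q": r["q"]}
                )
    table = pd.DataFrame(rows)
    return table, len(annotated) / len(labels)


def term_response_rate(term_genes, significant: pd.Series) -> float:
    """Fraction of a term's genes whose profiles changed significantly."""
    term_genes = [g for g in term_genes if g in significant.index]
    if not term_genes:
        raise ValueError("term has no scoreable genes")
    return float(significant.loc[term_genes].sum() / len(term_genes))
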