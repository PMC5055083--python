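#!/usr/bin/env python
"""Reproduction run on the study's deposited processed dataset.

These checks operate on the deposited supplementary files of the original
screen (not bundled here; download them first — see the README section on
reproducing the results):

  * a concentration matrix (strains x amino acids, TSV/CSV; the deposited
    processed dataset) — the significance pipeline is re-run on it and the
    headline counts are reported (total significant strains, multivariate
    count, median hits per amino acid, single-change profiles, the most
    variable amino acid's relative SD), together with the across-seed spread
    of the MCD fit;
  * a cluster assignment (strain, cluster TSV) — the fully connected
    within-cluster graph is rebuilt and its exact node and edge counts
    reported;
  * optionally, consensus clustering is re-run on the concentration matrix
    with the screen's standard settings (500 iterations, 0-20% removal,
    8 depths, minClusterSize 2, deepSplit 4) and the resulting cluster count
    reported with across-seed spread.

Usage:
    python scripts/reproduce.py --concentrations mmc3.tsv \
        [--clusters mmc1.tsv] [--consensus] [--seeds 0 1 2] --out results/reproduce.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

import metscreen as ms


def load_matrix(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    return frame.select_dtypes("number")


def significance_counts(matrix: pd.DataFrame, seeds) -> dict:
    out = {}
    per_seed = []
    for seed in seeds:
        res = ms.ScreenProfileModel(matrix, support_fraction=0.75).fit(
            seed=seed, alpha=0.01
        )
        eff = res.summarize_effects()
        rsd = eff["rsd"]
        singles = int((eff["per_strain_changes"][res.significant_strains()] == 1).sum())
        per_seed.append(
            {
                "seed": seed,
                "n_significant": eff["n_significant"],
                "n_multivariate": eff["n_multivariate"],
                "median_per_metabolite": eff["median_per_metabolite"],
                "max_per_metabolite": int(eff["per_metabolite_counts"].max()),
                "single_change_profiles": singles,
                "max_rsd_pct": round(100 * float(rsd.max()), 1),
                "max_rsd_metabolite": str(rsd.idxmax()),
            }
        )
    out["per_seed"] = per_seed
    out["n_significant_spread"] = [
        min(s["n_significant"] for s in per_seed),
        max(s["n_significant"] for s in per_seed),
    ]
    return out


def cluster_graph_counts(labels: pd.Series) -> dict:
    graph = ms.cluster_graph(labels)
    return {"nodes": graph.number_of_nodes(), "edges": graph.number_of_edges()}


def consensus_cluster_count(matrix: pd.DataFrame, seeds) -> dict:
    counts = []
    for seed in seeds:
        profile = ms.ScreenProfileModel(matrix, support_fraction=0.75).fit(seed=seed)
        model = ms.ConsensusClusterModel(
            matrix, covariance=profile.estimate.covariance
        )
        res = model.fit(n_iterations=500, removal_range=(0.0, 0.2), seed=seed)
        labels = res.final_clusters(
            min_cluster_size=2, deep_split=4, respect_small_clusters=True
        )
        counts.append(int(labels.max()))
    return {"cluster_counts": counts, "spread": [min(counts), max(counts)]}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--concentrations", type=Path, required=True)
    parser.add_argument("--clusters", type=Path, default=None)
    parser.add_argument("--consensus", action="store_true")
    parser.add_argument("--seeds", type=int, nargs="+", default=[0, 1, 2])
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    matrix = load_matrix(args.concentrations)
    results = {"significance": significance_counts(matrix, args.seeds)}
    if args.clusters is not None:
        assignment = pd.read_csv(args.clusters, sep="\t", index_col=0).iloc[:, 0]
        results["cluster_graph"] = cluster_graph_counts(assignment)
    if args.consensus:
        results["consensus"] = consensus_cluster_count(matrix, args.seeds)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=2))
    print(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
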