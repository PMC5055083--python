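"""End-to-end orchestration: simulate/load -> quantify -> normalize -> test
-> cluster -> enrich -> evaluate, with a resolved-config and manifest trail.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import consensus, enrich, network, normalize, robust, simulate
from .quantify import calibrate_screen, curve_summary, qc_technical_rsd
from .quantify import quantify as quantify_responses

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and stage toggles of a screen analysis run.

    Defaults are the screen's standard operating values: significance level
    0.01 (BH-adjusted), slow-grower dilution cutoff 0.25, 500 consensus
    iterations with 0-20% removal and 8 cut depths, minimum cluster size 2
    with deep split 4, MCD support fraction 0.75, term-overlap threshold 0.5
    and a 9:1 TN:TP gold-standard ratio.
    """

    seed: int = 0
    # synthetic screen
    n_strains: int = 600
    n_metabolites: int = 19
    generator: dict = field(default_factory=dict)
    # quantification
    calibration_model: str | dict = "auto"
    # normalization
    pqn_cutoff: float = 0.25
    median_divisions: float = 2.79
    exclusions: dict = field(default_factory=dict)
    # robust statistics
    alpha: float = 0.01
    support_fraction: float = 0.75
    # consensus clustering
    consensus_iterations: int = 500
    removal_range: tuple = (0.0, 0.2)
    n_depths: int = 8
    min_cluster_size: int = 2
    deep_split: int = 4
    respect_small_clusters: bool = True
    # enrichment / evaluation
    n_terms: int = 30
    annotation_noise: float = 0.1
    n_perm: int = 1000
    enrich_alpha: float = 0.05
    overlap_threshold: float = 0.5
    max_path: int = 2
    tn_ratio: int = 9
    # stage toggles
    stages: tuple = (
        "simulate",
        "quantify",
        "normalize",
        "test",
        "cluster",
        "enrich",
        "evaluate",
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**payload)
        return cfg

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["removal_range"] = list(self.removal_range)
        payload["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(payload))


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def quantify_and_normalize(screen, calibration_model="auto"):
    """Quantify a (synthetic or loaded) screen and normalize the strain
    samples; returns ``(normalized, dilution_factors)``.

    Convenience wrapper over the quantify and normalize stages: bracketed
    calibration, inverse prediction, per-strain matrix extraction, batch
    scaling and PQN dilution correction.
    """
    curves = calibrate_screen(
        screen.responses, screen.layout, screen.standards, calibration_model
    )
    conc, _ = quantify_responses(
        screen.responses, curves, screen.layout, screen.standards
    )
    idx = screen.strain_samples
    strains = conc.loc[idx].set_axis(screen.layout.loc[idx, "strain_id"])
    batches = screen.layout.loc[idx, "batch"].set_axis(strains.index)
    normalized, factors = normalize.batch_normalize(strains, batches, return_factors=True)
    return normalized, factors


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in order and write all artifacts.

    Returns a dict of in-memory results; every table is also written as TSV
    under ``outdir`` together with the resolved config and a machine-readable
    manifest (stages, timings, record counts, output hashes).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_resolved.yaml")
    manifest: dict = {"stages": [], "seed": config.seed}
    results: dict = {}
    order = ["simulate", "quantify", "normalize", "test", "cluster", "enrich", "evaluate"]
    enabled = [s for s in order if s in config.stages]
    deps = {
        "quantify": "simulate",
        "normalize": "quantify",
        "test": "normalize",
        "cluster": "test",
        "enrich": "cluster",
        "evaluate": "cluster",
    }
    for s in enabled:
        if deps.get(s) and deps[s] not in enabled:
            raise ValueError(f"stage {s!r} requires stage {deps[s]!r}")

    def record(stage, start, **counts):
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.time() - start, 2), **counts}
        )

    try:
        for stage in enabled:
            start = time.time()
            if stage == "simulate":
                params = simulate.ScreenParams(**config.generator)
                screen = simulate.simulate_screen(
                    config.n_strains, config.n_metabolites, params, seed=config.seed
                )
                screen.write(outdir / "screen")
                results["screen"] = screen
                record(stage, start, samples=len(screen.responses))

            elif stage == "quantify":
                screen = results["screen"]
                curves = calibrate_screen(
                    screen.responses, screen.layout, screen.standards,
                    config.calibration_model,
                )
                conc, flags = quantify_responses(
                    screen.responses, curves, screen.layout, screen.standards
                )
                curve_summary(curves).to_csv(
                    outdir / "calibration_curves.tsv", sep="\t", index=False
                )
                conc.to_csv(outdir / "concentrations.tsv", sep="\t")
                qc_idx = screen.qc_samples
                tech_rsd = qc_technical_rsd(conc.loc[qc_idx])
                results.update(concentrations=conc, flags=flags, curves=curves,
                               technical_rsd=tech_rsd)
                record(stage, start, curves=len(curves), flagged=int(flags.values.sum()))

            elif stage == "normalize":
                screen = results["screen"]
                conc = results["concentrations"]
                strain_idx = screen.strain_samples
                strains = conc.loc[strain_idx].set_axis(
                    screen.layout.loc[strain_idx, "strain_id"]
                )
                batches = screen.layout.loc[strain_idx, "batch"].set_axis(strains.index)
                corrected, factors = normalize.batch_normalize(
                    strains, batches, return_factors=True
                )
                flags_slow, divisions = normalize.flag_slow_growers(
                    factors, config.median_divisions, config.pqn_cutoff
                )
                exclusions = dict(config.exclusions)
                exclusions["slow_grower"] = list(flags_slow.index[flags_slow])
                filtered, audit = normalize.filter_strains(corrected, exclusions)
                filtered.to_csv(outdir / "normalized.tsv", sep="\t")
                with open(outdir / "strain_audit.jsonl", "w") as fh:
                    for rec in audit:
                        fh.write(json.dumps(rec) + "\n")
                results.update(
                    normalized=filtered, dilution_factors=factors,
                    implied_divisions=divisions, audit=audit,
                )
                record(stage, start, strains=len(filtered),
                       removed=sum(r["removed"] for r in audit))

            elif stage == "test":
                model = robust.ScreenProfileModel(
                    results["normalized"], support_fraction=config.support_fraction
                )
                res = model.fit(seed=config.seed, alpha=config.alpha)
                res.report().to_csv(outdir / "significance.tsv", sep="\t")
                res.cell_report().to_csv(outdir / "significance_cells.tsv",
                                         sep="\t", index=False)
                results["profile"] = res
                record(stage, start,
                       significant=int(res.significant_strains().sum()))

            elif stage == "cluster":
                res = results["profile"]
                model = consensus.ConsensusClusterModel(
                    results["normalized"], covariance=res.estimate.covariance
                )
                cres = model.fit(
                    n_iterations=config.consensus_iterations,
                    removal_range=config.removal_range,
                    n_depths=config.n_depths,
                    seed=config.seed,
                )
                labels = cres.final_clusters(
                    min_cluster_size=config.min_cluster_size,
                    deep_split=config.deep_split,
                    respect_small_clusters=config.respect_small_clusters,
                )
                labels.rename_axis("strain").to_csv(outdir / "clusters.tsv", sep="\t")
                cres.consensus.to_csv(outdir / "consensus.tsv", sep="\t")
                results["consensus"] = cres
                results["labels"] = labels
                record(stage, start, clusters=int(labels.max()))

            elif stage == "enrich":
                screen = results["screen"]
                gene_sets, term_graph = simulate.generate_annotations(
                    screen.truth, n_terms=config.n_terms,
                    noise=config.annotation_noise, seed=config.seed,
                )
                collection = enrich.GeneSetCollection(
                    sets=gene_sets, universe=set(results["normalized"].index)
                )
                res = results["profile"]
                gsea = enrich.gsea_chi2(
                    res.d2, collection, n_perm=config.n_perm, seed=config.seed
                )
                gsea.to_csv(outdir / "gsea.tsv", sep="\t", index=False)
                cluster_terms, frac = enrich.annotate_clusters(
                    results["labels"], collection,
                    universe=set(results["normalized"].index),
                    alpha=config.enrich_alpha,
                )
                cluster_terms.to_csv(outdir / "cluster_enrichment.tsv",
                                     sep="\t", index=False)
                results.update(annotation=collection, term_graph=term_graph,
                               gsea=gsea, cluster_terms=cluster_terms,
                               fraction_annotated=frac)
                record(stage, start, terms=len(collection),
                       enriched=int((gsea["q"] < config.enrich_alpha).sum()))

            elif stage == "evaluate":
                screen = results["screen"]
                gold = simulate.generate_gold_standard(
                    screen.truth, tn_ratio=config.tn_ratio, seed=config.seed
                )
                gold.to_csv(outdir / "gold_standard.tsv", sep="\t", index=False)
                ranking = results["consensus"].pair_ranking()
                curve = network.precision_recall(ranking, gold)
                curve.to_csv(outdir / "precision_recall.tsv", sep="\t", index=False)
                graph = network.cluster_graph(results["labels"])
                pd.DataFrame(graph.edges, columns=["gene_a", "gene_b"]).to_csv(
                    outdir / "cluster_graph.tsv", sep="\t", index=False
                )
                results.update(gold=gold, pr_curve=curve, graph=graph)
                record(stage, start, edges=graph.number_of_edges(),
                       gold_pairs=len(gold))
    except Exception as err:
        (outdir / "FAILED").write_text(f"stage failed: {err}\n")
        raise

    manifest["outputs"] = {
        p.name: _sha(p) for p in sorted(outdir.glob("*.tsv"))
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
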