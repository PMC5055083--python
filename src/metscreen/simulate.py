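"""Synthetic amino acid screen generator.

Emulates the structure of a plate-based targeted-metabolomics deletion screen:
96-well plates grouped into analytical batches, a pooled quality-control (QC)
sample injected every 24 samples, and six-level external calibration series
spanning three orders of magnitude that bracket every 24-injection block.
Strain effects are sparse (a configurable fraction of strains perturbed, most
with one or two affected metabolites), metabolites carry correlated technical
noise in blocks, batches apply multiplicative per-metabolite scalings, and each
sample has its own dilution (growth) factor.  Planted functional clusters of
strains share a common effect signature and come with matching gold-standard
pair sets and term annotations, so downstream clustering and enrichment are
testable without any external data.

The generating model for the observed instrument response of sample *i*,
metabolite *m* is::

    response_im = g_m(conc_sm * f_i * b_{batch(i),m}) * (1 + eps_im)

with ``g_m`` a linear (gain) or power-law response function, ``f_i`` the
dilution factor, ``b`` the batch scaling and ``eps`` zero-mean Gaussian noise
with planted relative SD.  Everything that was planted is recorded exactly in
:class:`ScreenTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScreenParams",
    "ScreenTruth",
    "SyntheticScreen",
    "simulate_screen",
    "generate_gold_standard",
    "generate_annotations",
]

SAMPLE = "sample"
QC = "qc"
STANDARD = "standard"

#: Number of injections between two calibration-standard sets; a QC sample
#: occupies the last slot of every block.
BLOCK_SIZE = 24


@dataclass
class ScreenParams:
    """Generator settings; defaults describe the study conditions emulated.

    Concentrations are on a µM-like arbitrary scale.  ``effect_size_sd`` is in
    units of the metabolite-level SD (baseline × noise RSD) so that planted
    effects are calibrated across metabolites of very different abundance.
    """

    #: highest baseline concentration (glutamine-like) and dynamic range down
    #: to the least abundant metabolite (tryptophan-like), three orders.
    baseline_max: float = 1000.0
    dynamic_range: float = 1000.0
    #: explicit per-metabolite baselines; overrides the log-spaced default
    baselines: np.ndarray | None = None
    #: fraction of strains with at least one planted effect
    effect_density: float = 0.30
    #: distribution of the number of simultaneously affected metabolites,
    #: P(1), P(2), ...; most profiles change <= 2 metabolites
    n_changes_probs: tuple = (0.45, 0.30, 0.15, 0.07, 0.03)
    #: median planted effect magnitude, in metabolite SD units
    effect_size_sd: float = 6.0
    #: log-normal spread of effect magnitudes
    effect_size_sigma: float = 0.3
    #: metabolite indices grouped into correlated technical-noise blocks
    corr_blocks: tuple = ((0, 1, 2), (3, 4, 5), (6, 7))
    corr_rho: float = 0.5
    #: per-metabolite technical relative SD; drawn U(lo, hi) if None
    noise_rsd: np.ndarray | float | None = None
    noise_rsd_range: tuple = (0.04, 0.10)
    #: relative SD of calibration-standard injections; None = same as samples
    standard_noise_rsd: float | None = None
    n_batches: int = 11
    #: log-normal sigma of multiplicative per-batch, per-metabolite scalings
    batch_sigma: float = 0.10
    #: log-normal sigma of per-sample dilution factors (median 1)
    dilution_sigma: float = 0.25
    #: fraction of strains with a slow-grower dilution factor in slow_range
    slow_fraction: float = 0.02
    slow_range: tuple = (0.05, 0.20)
    #: instrument response model: "linear" (gain) or "power" (a * conc**b)
    response_model: str = "linear"
    power_exponent_range: tuple = (0.85, 0.98)
    #: calibration series: levels log-spaced over ``standard_decades`` orders
    #: of magnitude centred on each metabolite's baseline
    n_standard_levels: int = 6
    standard_decades: float = 3.0
    #: planted functional clusters: number and size of multi-member groups
    n_clusters: int = 8
    cluster_size: int = 5
    #: explicit cluster sizes (overrides n_clusters/cluster_size)
    cluster_sizes: tuple | None = None
    #: "random": cluster signatures drawn independently (may overlap in the
    #: affected metabolites); "disjoint": each cluster perturbs its own
    #: metabolite set, emulating functional modules hitting distinct pathways
    cluster_signature_mode: str = "random"

    def validate(self) -> None:
        if self.baseline_max <= 0 or self.dynamic_range <= 0:
            raise ValueError("baseline concentrations must be positive")
        if self.noise_rsd is not None and np.any(np.asarray(self.noise_rsd) < 0):
            raise ValueError("noise RSDs must be non-negative")
        if not 0 <= self.effect_density <= 1:
            raise ValueError("effect_density must be a fraction in [0, 1]")
        if self.response_model not in ("linear", "power"):
            raise ValueError(f"unknown response model {self.response_model!r}")


@dataclass
class ScreenTruth:
    """Exact record of everything the generator planted."""

    true_concentration: pd.DataFrame  # strain x metabolite
    effect_mask: pd.DataFrame  # strain x metabolite, bool
    effect_size: pd.DataFrame  # strain x metabolite, in SD units
    dilution_factor: pd.Series  # per sample (strains and QCs)
    batch_scale: pd.DataFrame  # batch x metabolite
    cluster_label: pd.Series  # per strain, 0 = unperturbed
    noise_rsd: pd.Series  # per metabolite, fraction
    baselines: pd.Series  # per metabolite

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_concentration": self.true_concentration.to_dict(),
            "effect_mask": self.effect_mask.astype(int).to_dict(),
            "effect_size": self.effect_size.to_dict(),
            "dilution_factor": self.dilution_factor.to_dict(),
            "batch_scale": self.batch_scale.to_dict(),
            "cluster_label": self.cluster_label.to_dict(),
            "noise_rsd": self.noise_rsd.to_dict(),
            "baselines": self.baselines.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class SyntheticScreen:
    """A complete simulated screen: responses, layout, standards and truth."""

    responses: pd.DataFrame  # sample x metabolite instrument responses
    layout: pd.DataFrame  # sample_id, strain_id, class, batch, plate, well, run_order, block
    standards: pd.DataFrame  # set_id, batch, run_order, metabolite, level, nominal_conc, response
    truth: ScreenTruth
    params: ScreenParams

    @property
    def strain_samples(self) -> pd.Index:
        return self.layout.index[self.layout["class"] == SAMPLE]

    @property
    def qc_samples(self) -> pd.Index:
        return self.layout.index[self.layout["class"] == QC]

    def write(self, outdir: str | Path) -> None:
        """Write responses/layout/standards as TSV and the truth as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.responses.rename_axis("sample_id").to_csv(outdir / "responses.tsv", sep="\t")
        self.layout.rename_axis("sample_id").to_csv(outdir / "layout.tsv", sep="\t")
        self.standards.to_csv(outdir / "standards.tsv", sep="\t", index=False)
        self.truth.to_json(outdir / "truth.json")


def _well_name(i: int) -> str:
    return f"{'ABCDEFGH'[(i % 96) // 12]}{(i % 96) % 12 + 1:02d}"


def _noise_correlation(n_mets: int, params: ScreenParams) -> np.ndarray:
    corr = np.eye(n_mets)
    for block in params.corr_blocks:
        block = [b for b in block if b < n_mets]
        for a, b in combinations(block, 2):
            corr[a, b] = corr[b, a] = params.corr_rho
    return corr


def simulate_screen(
    n_strains: int,
    n_metabolites: int = 19,
    params: ScreenParams | None = None,
    seed: int = 0,
) -> SyntheticScreen:
    """Simulate a full screen with planted truth.

    All randomness flows from one seeded generator; per-component sub-streams
    are spawned deterministically, so a fixed seed reproduces the screen
    byte-identically.
    """
    if n_strains < 2 or n_metabolites < 2:
        raise ValueError("need at least 2 strains and 2 metabolites")
    params = params or ScreenParams()
    params.validate()

    root = np.random.default_rng(seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("effects", "dilution", "batch", "noise", "layout", "response"),
            root.integers(0, 2**31 - 1, size=6),
        )
    }

    metabolites = [f"m{j:02d}" for j in range(n_metabolites)]
    strains = [f"g{i:04d}" for i in range(n_strains)]

    if params.baselines is not None:
        baselines = np.asarray(params.baselines, dtype=float)
        if baselines.shape != (n_metabolites,):
            raise ValueError("baselines length must equal n_metabolites")
    else:
        baselines = np.logspace(
            np.log10(params.baseline_max),
            np.log10(params.baseline_max / params.dynamic_range),
            n_metabolites,
        )
    if np.any(baselines <= 0):
        raise ValueError("baseline concentrations must be positive")

    if params.noise_rsd is None:
        noise_rsd = streams["noise"].uniform(*params.noise_rsd_range, size=n_metabolites)
    else:
        noise_rsd = np.broadcast_to(np.asarray(params.noise_rsd, dtype=float), (n_metabolites,)).copy()

    # --- planted effects and functional clusters -------------------------
    rng = streams["effects"]
    n_perturbed = int(round(params.effect_density * n_strains))
    perturbed = rng.choice(n_strains, size=n_perturbed, replace=False)
    effect_size = np.zeros((n_strains, n_metabolites))
    cluster_label = np.zeros(n_strains, dtype=int)

    def draw_signature(mets=None) -> np.ndarray:
        if mets is None:
            probs = np.asarray(params.n_changes_probs)
            k = rng.choice(np.arange(1, len(probs) + 1), p=probs / probs.sum())
            k = min(k, n_metabolites)
            mets = rng.choice(n_metabolites, size=k, replace=False)
        sig = np.zeros(n_metabolites)
        mags = params.effect_size_sd * np.exp(
            rng.normal(0.0, params.effect_size_sigma, size=len(mets))
        )
        sig[mets] = mags * rng.choice([-1.0, 1.0], size=len(mets))
        return sig

    if params.cluster_sizes is not None:
        sizes = list(params.cluster_sizes)
    else:
        sizes = [params.cluster_size] * params.n_clusters
    disjoint_pools = None
    if params.cluster_signature_mode == "disjoint":
        # carve the metabolite panel into one pool per cluster so distinct
        # modules perturb distinct pathways
        pool_split = np.array_split(rng.permutation(n_metabolites), len(sizes))
        disjoint_pools = [p for p in pool_split]

    pos = 0
    next_label = 1
    for ci, size in enumerate(sizes):
        members = perturbed[pos : pos + size]
        if len(members) == 0:
            break
        if disjoint_pools is not None:
            pool = disjoint_pools[ci]
            k = min(max(2, len(pool)), len(pool))
            sig = draw_signature(pool[:k])
        else:
            sig = draw_signature()
        for s in members:
            effect_size[s] = sig
            cluster_label[s] = next_label
        pos += len(members)
        next_label += 1
    for s in perturbed[pos:]:  # remaining perturbed strains: singleton groups
        effect_size[s] = draw_signature()
        cluster_label[s] = next_label
        next_label += 1

    # effect in SD units -> multiplicative shift of the true concentration;
    # the metabolite-level SD is baseline * noise RSD
    rel_shift = effect_size * noise_rsd[None, :]
    true_conc = baselines[None, :] * np.clip(1.0 + rel_shift, 0.05, None)
    effect_mask = effect_size != 0

    # --- dilution factors -------------------------------------------------
    rng = streams["dilution"]
    dilution = np.exp(rng.normal(0.0, params.dilution_sigma, size=n_strains))
    n_slow = int(round(params.slow_fraction * n_strains))
    if n_slow:
        slow = rng.choice(n_strains, size=n_slow, replace=False)
        dilution[slow] = rng.uniform(*params.slow_range, size=n_slow)

    # --- batch scalings ---------------------------------------------------
    rng = streams["batch"]
    batch_scale = np.exp(
        rng.normal(0.0, params.batch_sigma, size=(params.n_batches, n_metabolites))
    )

    # --- response functions ----------------------------------------------
    rng = streams["response"]
    gains = rng.uniform(50.0, 200.0, size=n_metabolites)
    if params.response_model == "power":
        exponents = rng.uniform(*params.power_exponent_range, size=n_metabolites)
    else:
        exponents = np.ones(n_metabolites)

    def respond(conc: np.ndarray) -> np.ndarray:
        # conc: (..., n_metabolites); linear model is the b == 1 special case
        return gains * np.power(conc, exponents)

    # --- plate / batch / run-order layout --------------------------------
    rng = streams["layout"]
    order = rng.permutation(n_strains)
    batch_of = np.array_split(order, params.n_batches)

    layout_rows = []
    response_rows = []
    standards_rows = []
    dilution_records = {}
    noise_corr = _noise_correlation(n_metabolites, params)
    noise_chol = np.linalg.cholesky(noise_corr)
    nrng = streams["noise"]

    std_levels = np.logspace(
        -params.standard_decades / 2.0,
        params.standard_decades / 2.0,
        params.n_standard_levels,
    )

    run_order = 0
    set_counter = 0
    plate_counter = 0

    def emit_standard_set(batch: int) -> int:
        nonlocal run_order, set_counter
        sid = set_counter
        set_counter += 1
        std_rsd = (
            noise_rsd
            if params.standard_noise_rsd is None
            else np.full(n_metabolites, params.standard_noise_rsd)
        )
        for lvl, mult in enumerate(std_levels):
            nominal = baselines * mult
            eps = noise_chol @ nrng.standard_normal(n_metabolites) * std_rsd
            resp = respond(nominal) * (1.0 + eps)
            for j, met in enumerate(metabolites):
                standards_rows.append(
                    (sid, batch, run_order, met, lvl, nominal[j], max(resp[j], 0.0))
                )
            run_order += 1
        return sid

    def emit_sample(sample_id, strain_idx, cls, batch):
        nonlocal run_order
        if cls == QC:
            conc = baselines.copy()
            f = 1.0
        else:
            conc = true_conc[strain_idx]
            f = dilution[strain_idx]
        observed = conc * f * batch_scale[batch]
        eps = noise_chol @ nrng.standard_normal(n_metabolites) * noise_rsd
        resp = np.clip(respond(observed) * (1.0 + eps), 0.0, None)
        response_rows.append((sample_id, resp))
        dilution_records[sample_id] = f
        layout_rows.append(
            {
                "sample_id": sample_id,
                "strain_id": strains[strain_idx] if strain_idx is not None else "",
                "class": cls,
                "batch": batch,
                "plate": plate_counter + strain_idx // 96 if strain_idx is not None else -1,
                "well": _well_name(strain_idx) if strain_idx is not None else "",
                "run_order": run_order,
                "block": None,  # filled below
            }
        )
        run_order += 1

    qc_counter = 0
    block_assign = []
    for batch, members in enumerate(batch_of):
        members = list(members)
        i = 0
        while i < len(members) or (i == 0 and not members):
            set_before = emit_standard_set(batch)
            block_members = members[i : i + BLOCK_SIZE - 1]
            block_id = len(block_assign)
            start = len(layout_rows)
            for s in block_members:
                emit_sample(f"s{len(response_rows):05d}", s, SAMPLE, batch)
            emit_sample(f"qc{qc_counter:04d}", None, QC, batch)
            qc_counter += 1
            for row in layout_rows[start:]:
                row["block"] = block_id
            block_assign.append((block_id, batch, set_before))
            i += BLOCK_SIZE - 1
        set_after = emit_standard_set(batch)
        # close the batch: the final set brackets the batch's last block(s)

    layout = pd.DataFrame(layout_rows).set_index("sample_id")
    responses = pd.DataFrame(
        {sid: resp for sid, resp in response_rows}, index=metabolites
    ).T
    responses.columns = metabolites
    standards = pd.DataFrame(
        standards_rows,
        columns=["set_id", "batch", "run_order", "metabolite", "level", "nominal_conc", "response"],
    )

    # index truth by strain id
    strain_order = layout.loc[layout["class"] == SAMPLE, "strain_id"]
    truth = ScreenTruth(
        true_concentration=pd.DataFrame(true_conc, index=strains, columns=metabolites),
        effect_mask=pd.DataFrame(effect_mask, index=strains, columns=metabolites),
        effect_size=pd.DataFrame(effect_size, index=strains, columns=metabolites),
        dilution_factor=pd.Series(dilution_records, name="dilution_factor"),
        batch_scale=pd.DataFrame(
            batch_scale, index=range(params.n_batches), columns=metabolites
        ),
        cluster_label=pd.Series(cluster_label, index=strains, name="cluster"),
        noise_rsd=pd.Series(noise_rsd, index=metabolites, name="noise_rsd"),
        baselines=pd.Series(baselines, index=metabolites, name="baseline"),
    )
    return SyntheticScreen(
        responses=responses, layout=layout, standards=standards, truth=truth, params=params
    )


def generate_gold_standard(
    truth: ScreenTruth, tn_ratio: int = 9, seed: int = 0
) -> pd.DataFrame:
    """Labeled gene-pair set from the planted clusters.

    True-positive pairs are all within-cluster pairs (clusters with >= 2
    members); true negatives are sampled from cross-cluster pairs and reduced
    to ``tn_ratio`` times the TP count, which fixes the precision of a random
    classifier at ``1 / (1 + tn_ratio)``.
    """
    if tn_ratio < 1:
        raise ValueError("tn_ratio must be >= 1")
    labels = truth.cluster_label[truth.cluster_label > 0]
    sizes = labels.value_counts()
    multi = sizes[sizes >= 2]
    if len(multi) < 2:
        raise ValueError("need at least 2 clusters with >= 2 members")
    rng = np.random.default_rng(seed)

    tp = []
    for cl in multi.index:
        members = sorted(labels.index[labels == cl])
        tp.extend(combinations(members, 2))

    genes = sorted(labels.index)
    candidates = [
        (a, b) for a, b in combinations(genes, 2) if labels[a] != labels[b]
    ]
    n_tn = tn_ratio * len(tp)
    if len(candidates) < n_tn:
        raise ValueError(
            f"insufficient cross-cluster pairs: need {n_tn}, have {len(candidates)}"
        )
    idx = rng.choice(len(candidates), size=n_tn, replace=False)
    tn = [candidates[i] for i in sorted(idx)]

    frame = pd.DataFrame(
        [(a, b, 1) for a, b in tp] + [(a, b, 0) for a, b in tn],
        columns=["gene_a", "gene_b", "label"],
    )
    return frame


def generate_annotations(
    truth: ScreenTruth,
    n_terms: int,
    noise: float = 0.0,
    seed: int = 0,
    min_random_size: int = 3,
    max_random_size: int = 15,
):
    """Gene-set collection plus a shallow term parent-child graph.

    One term per planted multi-member cluster containing its members (with a
    fraction ``noise`` of members swapped for random other genes), padded with
    random terms up to ``n_terms``; terms are linked to a handful of parent
    terms, which link to a single root.
    Returns ``(gene_sets: dict term -> set, term_graph: DataFrame[child, parent])``.
    """
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    labels = truth.cluster_label[truth.cluster_label > 0]
    sizes = labels.value_counts()
    clusters = sizes[sizes >= 2].index
    if n_terms < len(clusters):
        raise ValueError(f"n_terms must be >= number of clusters ({len(clusters)})")
    rng = np.random.default_rng(seed)
    all_genes = list(truth.cluster_label.index)

    gene_sets: dict[str, set] = {}
    for k, cl in enumerate(sorted(clusters)):
        members = sorted(labels.index[labels == cl])
        n_swap = int(np.floor(noise * len(members)))
        if n_swap:
            keep = list(rng.choice(members, size=len(members) - n_swap, replace=False))
            outside = [g for g in all_genes if g not in members]
            swapped = list(rng.choice(outside, size=n_swap, replace=False))
            members = sorted(keep + swapped)
        gene_sets[f"T{k:04d}"] = set(members)

    k = len(gene_sets)
    while len(gene_sets) < n_terms:
        size = rng.integers(min_random_size, max_random_size + 1)
        gene_sets[f"T{k:04d}"] = set(rng.choice(all_genes, size=size, replace=False))
        k += 1

    terms = sorted(gene_sets)
    n_parents = max(1, len(terms) // 5)
    edges = [(f"P{p:03d}", "ROOT") for p in range(n_parents)]
    for i, t in enumerate(terms):
        edges.append((t, f"P{i % n_parents:03d}"))
    term_graph = pd.DataFrame(edges, columns=["child", "parent"])
    return gene_sets, term_graph


def write_gmt(gene_sets: dict, path: str | Path, names: dict | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in gene_sets.items():
            name = (names or {}).get(term, term)
            fh.write("\t".join([term, name, *sorted(genes)]) + "\n")


def read_gmt(path: str | Path) -> dict:
    gene_sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                gene_sets[parts[0]] = set(parts[2:])
    return gene_sets
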