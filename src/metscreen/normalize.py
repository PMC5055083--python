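"""Dilution (PQN) and batch normalization, strain quality filters.

The probabilistic quotient normalization (PQN) factor of a sample is the
median, over metabolites, of its concentration ratios to a reference profile;
dividing the sample by its factor removes per-sample dilution, and the factor
itself is a proxy for biomass (growth).  Batch correction adapts a
plate-screen scaling workflow: batch means (computed after within-batch PQN)
are scaled to the global mean per metabolite, followed by a final global PQN
pass.  Samples with a dilution factor below 0.25 — about 0.8 cell divisions
when the median sample has undergone 2.79 — are flagged as slow growers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "pqn",
    "batch_normalize",
    "flag_slow_growers",
    "filter_strains",
    "estimate_intracellular",
]

#: dilution-factor threshold below which a strain counts as a slow grower
SLOW_GROWER_CUTOFF = 0.25
#: cell divisions undergone by the median sample of the screen
MEDIAN_DIVISIONS = 2.79


def pqn(matrix: pd.DataFrame, reference="median"):
    """Probabilistic quotient normalization.

    Returns ``(normalized, factors)`` with ``factors[i] = median_m(x_im /
    reference_m)`` and ``normalized = x / factors``.  ``reference`` is a
    per-metabolite profile or ``"median"`` for the matrix's own median
    profile.
    """
    if (matrix < 0).any().any():
        raise ValueError("PQN requires non-negative values")
    all_zero = (matrix == 0).all(axis=1)
    if all_zero.any():
        raise ValueError(f"all-zero samples: {list(matrix.index[all_zero])}")
    if isinstance(reference, str) and reference == "median":
        reference = matrix.median(axis=0)
    reference = pd.Series(reference, index=matrix.columns).astype(float)
    if (reference == 0).any():
        raise ValueError("reference profile has zero entries")
    ratios = matrix.div(reference, axis=1)
    factors = ratios.median(axis=1).rename("dilution_factor")
    if (factors <= 0).any():
        raise ValueError(
            f"non-positive PQN factors for samples: {list(factors.index[factors <= 0])}"
        )
    return matrix.div(factors, axis=0), factors


def batch_normalize(
    matrix: pd.DataFrame, batches: pd.Series, return_factors: bool = False
):
    """Scale per-metabolite batch means to the global mean.

    Order of operations: (1) overall per-metabolite mean over all samples;
    (2) PQN within each batch (dilution compensation before batch means are
    taken); (3) per-batch per-metabolite means of the PQN-corrected batch;
    (4) each sample divided by its batch mean and multiplied by the overall
    mean; (5) a final PQN pass over the full matrix.

    With ``return_factors=True`` also returns the final-pass PQN factors —
    the per-sample dilution estimates after batch correction, the quantity
    used for slow-grower flagging.
    """
    batches = batches.loc[matrix.index]
    if batches.isna().any():
        raise ValueError("every sample needs a batch assignment")
    overall_mean = matrix.mean(axis=0)
    corrected = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for batch, idx in matrix.groupby(batches).groups.items():
        sub = matrix.loc[idx]
        if len(sub) < 2:
            warnings.warn(
                f"batch {batch!r} has fewer than 2 samples; scaling skipped",
                stacklevel=2,
            )
            corrected.loc[idx] = sub
            continue
        sub_pqn, _ = pqn(sub)
        batch_mean = sub_pqn.mean(axis=0)
        corrected.loc[idx] = sub.div(batch_mean, axis=1).mul(overall_mean, axis=1)
    out, factors = pqn(corrected)
    if return_factors:
        return out, factors
    return out


def flag_slow_growers(
    factors: pd.Series,
    median_divisions: float = MEDIAN_DIVISIONS,
    cutoff: float = SLOW_GROWER_CUTOFF,
):
    """Implied cell divisions and slow-grower flags from dilution factors.

    A dilution factor f corresponds to ``median_divisions + log2(f)``
    divisions; samples with ``f < cutoff`` are flagged.  At the defaults a
    factor of 0.25 maps to ~0.8 divisions.
    """
    if (factors <= 0).any():
        raise ValueError("dilution factors must be positive")
    if median_divisions <= 0:
        raise ValueError("median_divisions must be positive")
    divisions = (median_divisions + np.log2(factors)).rename("implied_divisions")
    flags = (factors < cutoff).rename("slow_grower")
    return flags, divisions


def filter_strains(matrix: pd.DataFrame, exclusions: dict):
    """Remove strains listed in named exclusion categories.

    ``exclusions`` maps a category name (e.g. ``control_complemented``,
    ``cross_contaminated``, ``outdated_orf``, ``slow_grower``) to an iterable
    of strain ids.  Returns ``(filtered, audit)`` where ``audit`` is a list of
    per-category records; ids absent from the matrix raise a warning only.
    """
    audit = []
    drop: set = set()
    for category, ids in exclusions.items():
        ids = list(ids)
        present = [i for i in ids if i in matrix.index]
        missing = sorted(set(ids) - set(present))
        if missing:
            warnings.warn(
                f"exclusion category {category!r}: {len(missing)} ids not in matrix",
                stacklevel=2,
            )
        audit.append(
            {
                "category": category,
                "listed": len(ids),
                "removed": len(set(present) - drop),
                "missing": len(missing),
                "ids": sorted(present),
            }
        )
        drop.update(present)
    return matrix.drop(index=sorted(drop)), audit


def estimate_intracellular(
    extract_concentration,
    od: float = 1.46,
    extraction_volume: float = 200e-6,
    culture_volume: float = 1.685e-3,
    cells_per_od_ml: float = 3.2e7,
    cell_volume: float = 45.54e-15,
):
    """Convert extract concentrations to intracellular concentrations.

    With concentrations in µM and volumes in litres: the metabolite amount is
    ``extract_concentration * extraction_volume`` (µmol), the cell count is
    ``od * cells_per_od_ml * culture_volume_in_ml``, and the intracellular
    concentration is the amount divided by the total cell volume (µM again,
    since µmol / L = µM).  Defaults are the screen's preset: median OD 1.46,
    200 µl extraction, 1.685 ml culture, 3.2e7 cells/OD/ml, 45.54 fL cells.
    """
    for name, v in (
        ("od", od),
        ("extraction_volume", extraction_volume),
        ("culture_volume", culture_volume),
        ("cells_per_od_ml", cells_per_od_ml),
        ("cell_volume", cell_volume),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    amount = np.asarray(extract_concentration, dtype=float) * extraction_volume
    cell_count = od * cells_per_od_ml * culture_volume * 1e3  # volume ml -> cells
    if cell_count == 0:
        raise ValueError("zero cell count")
    return amount / (cell_count * cell_volume)
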