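"""Instrument response -> concentration via bracketed external calibration.

Calibration standards are measured before and after every block of 24
injections ("bracketing"); both flanking sets are pooled for the fit, which
corrects for instrumental drift.  Per metabolite the curve is either a linear
regression on the raw scale or a linear regression after log transformation
(a power-law fit, ``response = a * conc**b``); standard levels more than 4x
above the highest or 4x below the lowest concentrated sample in the block are
excluded before the final fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "calibrate_screen",
    "quantify",
    "qc_technical_rsd",
]

#: levels outside [sample_min / RANGE_FACTOR, sample_max * RANGE_FACTOR]
#: are excluded from the calibration fit
RANGE_FACTOR = 4.0


@dataclass
class CalibrationCurve:
    """A fitted per-metabolite, per-block calibration curve.

    For ``model == "linear"``: ``response = slope * conc + intercept``.
    For ``model == "power_law"``: ``log(response) = slope * log(conc) +
    intercept``, i.e. ``response = exp(intercept) * conc ** slope``.
    """

    metabolite: str
    model: str
    slope: float
    intercept: float
    r_squared: float
    included_levels: tuple = ()
    bracket: tuple = ()
    block: int | None = None

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        if self.model == "linear":
            return self.slope * conc + self.intercept
        return np.exp(self.intercept) * np.power(conc, self.slope)

    def inverse(self, response):
        """Concentration for a response; negatives floored at 0 (flagged by
        the caller via :func:`quantify`)."""
        response = np.asarray(response, dtype=float)
        if self.model == "linear":
            return (response - self.intercept) / self.slope
        out = np.zeros_like(response)
        pos = response > 0
        out[pos] = np.exp((np.log(response[pos]) - self.intercept) / self.slope)
        return out


def _ols(x: np.ndarray, y: np.ndarray):
    """Plain least squares y = b*x + a; returns (slope, intercept, r2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0:
        raise ValueError("degenerate calibration: all levels identical")
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    sst = ((y - ym) ** 2).sum()
    r2 = 1.0 if sst == 0 else 1.0 - (resid**2).sum() / sst
    return slope, intercept, float(np.clip(r2, 0.0, 1.0))


def _log_rss(conc, resp, curve: CalibrationCurve) -> float:
    pred = curve.predict(conc)
    ok = (pred > 0) & (resp > 0)
    if ok.sum() < 2:
        return np.inf
    return float(((np.log(resp[ok]) - np.log(pred[ok])) ** 2).sum())


def fit_calibration(
    standards: pd.DataFrame,
    sample_range: tuple | None = None,
    model: str = "auto",
    metabolite: str | None = None,
    block: int | None = None,
) -> CalibrationCurve:
    """Fit one calibration curve from pooled bracketing standards.

    Parameters
    ----------
    standards
        Records for one metabolite with columns ``nominal_conc``, ``response``
        and optionally ``level`` and ``set_id`` (both flanking sets pooled).
    sample_range
        ``(lo, hi)`` concentration range observed among the block's samples;
        levels with nominal concentration above ``4 * hi`` or below ``lo / 4``
        are excluded.  ``None`` disables the exclusion rule.
    model
        ``"linear"``, ``"power_law"`` or ``"auto"`` (the model with the
        smaller residual sum of squares on the log scale wins).
    """
    met = metabolite or (standards["metabolite"].iloc[0] if "metabolite" in standards else "?")
    conc = standards["nominal_conc"].to_numpy(dtype=float)
    resp = standards["response"].to_numpy(dtype=float)
    levels = (
        standards["level"].to_numpy()
        if "level" in standards
        else np.arange(len(standards))
    )
    bracket = tuple(sorted(set(standards["set_id"]))) if "set_id" in standards else ()

    keep = np.ones(len(conc), dtype=bool)
    if sample_range is not None:
        lo, hi = sample_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo > 0 and hi > 0):
            raise ValueError("sample_range must be finite and positive")
        keep = (conc >= lo / RANGE_FACTOR) & (conc <= hi * RANGE_FACTOR)
    if model in ("power_law", "auto"):
        positive = resp > 0
    else:
        positive = np.ones(len(conc), dtype=bool)

    def surviving(mask):
        if len(np.unique(conc[mask])) < 2:
            raise ValueError(
                f"calibration failed for metabolite {met!r}, block {block}: "
                "fewer than 2 standard levels survive exclusion"
            )
        return mask

    curves = {}
    if model in ("linear", "auto"):
        m = surviving(keep)
        s, a, r2 = _ols(conc[m], resp[m])
        curves["linear"] = (m, CalibrationCurve(met, "linear", s, a, r2, block=block))
    if model in ("power_law", "auto"):
        m = keep & positive
        if model == "power_law" and not np.all(positive[keep]):
            raise ValueError(
                f"non-positive responses for metabolite {met!r} under power_law"
            )
        m = surviving(m)
        s, a, r2 = _ols(np.log(conc[m]), np.log(resp[m]))
        curves["power_law"] = (m, CalibrationCurve(met, "power_law", s, a, r2, block=block))
    if model == "auto":
        chosen = min(
            curves, key=lambda k: _log_rss(conc[curves[k][0]], resp[curves[k][0]], curves[k][1])
        )
    else:
        chosen = model
    mask, curve = curves[chosen]
    curve.included_levels = tuple(sorted(set(levels[mask])))
    curve.bracket = bracket
    return curve


def _blocks_from_layout(layout: pd.DataFrame, standards: pd.DataFrame) -> pd.Series:
    if "block" in layout and layout["block"].notna().all():
        return layout["block"].astype(int)
    # derive blocks: samples between consecutive standard-set run positions
    set_pos = standards.groupby("set_id")["run_order"].min().sort_values()
    bounds = set_pos.to_numpy()
    block = np.searchsorted(bounds, layout["run_order"].to_numpy(), side="right") - 1
    return pd.Series(np.clip(block, 0, None), index=layout.index)


def _flanking_sets(block_samples: pd.DataFrame, standards: pd.DataFrame):
    """Standard sets immediately before and after a block's run-order span;
    partial terminal blocks fall back to the nearest two sets."""
    lo = block_samples["run_order"].min()
    hi = block_samples["run_order"].max()
    set_pos = standards.groupby("set_id")["run_order"].min().sort_values()
    before = set_pos[set_pos < lo]
    after = set_pos[set_pos > hi]
    sets = []
    if len(before):
        sets.append(before.index[-1])
    if len(after):
        sets.append(after.index[0])
    if len(sets) < 2:  # terminal block: take the two nearest sets
        nearest = (set_pos - (lo + hi) / 2.0).abs().sort_values().index[:2]
        sets = list(nearest)
    return sets


def calibrate_screen(
    responses: pd.DataFrame,
    layout: pd.DataFrame,
    standards: pd.DataFrame,
    model_choice: dict | str = "auto",
) -> dict:
    """Fit bracketed calibration curves for every (block, metabolite).

    A first pass on all pooled levels gives provisional concentrations that
    define each block's sample concentration range; the 4x exclusion rule is
    then applied and the curve refitted on the surviving levels.
    ``model_choice`` is either a per-metabolite mapping (the screen's
    configured choice) or a single mode for all metabolites.
    """
    blocks = _blocks_from_layout(layout, standards)
    curves: dict[tuple, CalibrationCurve] = {}
    for block_id, members in layout.groupby(blocks):
        pool_sets = _flanking_sets(members, standards)
        pool = standards[standards["set_id"].isin(pool_sets)]
        for met in responses.columns:
            met_std = pool[pool["metabolite"] == met]
            mode = model_choice if isinstance(model_choice, str) else model_choice.get(met, "auto")
            pre = fit_calibration(met_std, None, mode, metabolite=met, block=block_id)
            sample_resp = responses.loc[members.index, met]
            prelim = pre.inverse(sample_resp.to_numpy())
            prelim = prelim[prelim > 0]
            if len(prelim) == 0:
                curves[(block_id, met)] = pre
                continue
            curves[(block_id, met)] = fit_calibration(
                met_std,
                (float(prelim.min()), float(prelim.max())),
                mode,
                metabolite=met,
                block=block_id,
            )
    return curves


def quantify(
    responses: pd.DataFrame,
    curves: dict,
    layout: pd.DataFrame | None = None,
    standards: pd.DataFrame | None = None,
):
    """Apply inverse calibration; returns ``(concentrations, flags)``.

    Negative or non-invertible predictions are floored at zero and flagged.
    """
    if layout is not None:
        blocks = _blocks_from_layout(layout, standards if standards is not None else pd.DataFrame())
    else:
        blocks = pd.Series(0, index=responses.index)
    conc = pd.DataFrame(index=responses.index, columns=responses.columns, dtype=float)
    flags = pd.DataFrame(False, index=responses.index, columns=responses.columns)
    for block_id, idx in responses.groupby(blocks.loc[responses.index]).groups.items():
        for met in responses.columns:
            key = (block_id, met)
            if key not in curves:
                raise KeyError(f"no calibration curve for block {block_id}, metabolite {met!r}")
            curve = curves[key]
            values = curve.inverse(responses.loc[idx, met].to_numpy())
            neg = values < 0
            bad_power = (curve.model == "power_law") & (
                responses.loc[idx, met].to_numpy() <= 0
            )
            values[neg] = 0.0
            conc.loc[idx, met] = values
            flags.loc[idx, met] = neg | bad_power
    return conc, flags


def curve_summary(curves: dict) -> pd.DataFrame:
    rows = [
        {
            "block": blk,
            "metabolite": met,
            "model": c.model,
            "slope": c.slope,
            "intercept": c.intercept,
            "r_squared": c.r_squared,
            "included_levels": ",".join(map(str, c.included_levels)),
        }
        for (blk, met), c in curves.items()
    ]
    return pd.DataFrame(rows)


def qc_technical_rsd(qc_concentrations: pd.DataFrame) -> pd.Series:
    """Technical relative SD per metabolite from repeated QC injections.

    RSD = SD / mean, as a fraction; requires at least 3 QC records.
    """
    if len(qc_concentrations) < 3:
        raise ValueError("need at least 3 QC records")
    mean = qc_concentrations.mean(axis=0)
    if (mean == 0).any():
        bad = list(mean.index[mean == 0])
        raise ValueError(f"zero QC mean for metabolites: {bad}")
    return (qc_concentrations.std(axis=0, ddof=1) / mean).rename("technical_rsd")
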