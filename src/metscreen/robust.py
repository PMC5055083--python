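"""Robust multivariate model of the unperturbed metabolome.

The unperturbed amino acid profile is estimated with the Minimum Covariance
Determinant (MCD) estimator, a high-breakdown robust estimate of multivariate
location and scatter that ignores the contribution of the minority of
genuinely perturbed strains.  Every strain is then tested against the robust
estimate both multivariately — squared Mahalanobis distance, referred to a χ²
distribution with one degree of freedom per metabolite — and univariately,
with per-metabolite two-sided Z tests.  p values are adjusted for multiple
testing with Benjamini-Hochberg, separately for the multivariate family
(across strains) and for each metabolite's univariate family.

Usage follows the model/results split::

    model = ScreenProfileModel(conc_matrix, support_fraction=0.75)
    res = model.fit(seed=0)
    res.significant_strains(alpha=0.01)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

__all__ = ["ScreenProfileModel", "ScreenProfileResults", "RobustEstimate"]


@dataclass
class RobustEstimate:
    """MCD location/scatter and derived quantities."""

    location: pd.Series
    covariance: pd.DataFrame
    correlation: pd.DataFrame
    robust_sd: pd.Series
    support_fraction: float
    seed: int


class ScreenProfileModel:
    """Robust profile model for a strain x metabolite concentration matrix.

    Parameters
    ----------
    data
        Concentration matrix (rows: strains, columns: metabolites), already
        normalized for dilution and batch.
    support_fraction
        MCD support fraction h in (0.5, 1]; ``h == 1`` reduces to the
        classical mean/covariance.
    """

    def __init__(self, data: pd.DataFrame, support_fraction: float = 0.75):
        data = pd.DataFrame(data).astype(float)
        n, p = data.shape
        if n <= 2 * p:
            raise ValueError(
                f"need more than 2 x {p} strains for a stable MCD estimate, got {n}"
            )
        if not 0.5 < support_fraction <= 1.0:
            raise ValueError("support_fraction must be in (0.5, 1]")
        self.data = data
        self.support_fraction = float(support_fraction)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, metabolites=None, **kw):
        cols = list(metabolites) if metabolites is not None else list(frame.columns)
        return cls(frame[cols], **kw)

    def fit(self, seed: int = 0, alpha: float = 0.01, bh_family: str = "per_metabolite"):
        """Fit the MCD estimate and run all significance tests.

        ``bh_family``: ``"per_metabolite"`` adjusts each metabolite's Z tests
        across strains (and the χ² tests across strains); ``"global"`` pools
        all univariate p values into one family.
        """
        X = self.data.to_numpy()
        if self.support_fraction >= 1.0:
            # h = 1: the classical estimate, consistency factor exactly 1
            location = X.mean(axis=0)
            covariance = np.cov(X, rowvar=False)
        else:
            mcd = MinCovDet(
                support_fraction=self.support_fraction, random_state=seed
            ).fit(X)
            location = mcd.location_
            covariance = mcd.covariance_
        sd = np.sqrt(np.diag(covariance))
        if np.any(sd == 0):
            raise ValueError("singular robust covariance: zero-variance metabolite")
        corr = covariance / np.outer(sd, sd)
        cols = self.data.columns
        estimate = RobustEstimate(
            location=pd.Series(location, index=cols, name="location"),
            covariance=pd.DataFrame(covariance, index=cols, columns=cols),
            correlation=pd.DataFrame(corr, index=cols, columns=cols),
            robust_sd=pd.Series(sd, index=cols, name="robust_sd"),
            support_fraction=self.support_fraction,
            seed=seed,
        )
        return ScreenProfileResults(self, estimate, alpha=alpha, bh_family=bh_family)


def mahalanobis_d2(X: np.ndarray, location: np.ndarray, covariance: np.ndarray):
    """Squared Mahalanobis distances of rows of X from ``location``."""
    delta = X - location
    try:
        solved = np.linalg.solve(covariance, delta.T)
    except np.linalg.LinAlgError as err:
        raise ValueError("robust covariance is not invertible") from err
    return np.einsum("ij,ji->i", delta, solved)


class ScreenProfileResults:
    """Significance report and effect summaries for a fitted profile model."""

    def __init__(
        self,
        model: ScreenProfileModel,
        estimate: RobustEstimate,
        alpha: float = 0.01,
        bh_family: str = "per_metabolite",
    ):
        self.model = model
        self.estimate = estimate
        self.alpha = float(alpha)
        data = model.data
        X = data.to_numpy()
        loc = estimate.location.to_numpy()
        cov = estimate.covariance.to_numpy()
        sd = estimate.robust_sd.to_numpy()

        d2 = mahalanobis_d2(X, loc, cov)
        if np.any(d2 < 0):
            raise ValueError("robust covariance is not positive definite")
        p = data.shape[1]
        self.d2 = pd.Series(d2, index=data.index, name="d2")
        self.p_multi = pd.Series(
            stats.chi2.sf(d2, df=p), index=data.index, name="p_multi"
        )
        self.q_multi = pd.Series(
            multipletests(self.p_multi, method="fdr_bh")[1],
            index=data.index,
            name="q_multi",
        )

        self.z = pd.DataFrame((X - loc) / sd, index=data.index, columns=data.columns)
        p_uni = 2.0 * stats.norm.sf(np.abs(self.z.to_numpy()))
        self.p_uni = pd.DataFrame(p_uni, index=data.index, columns=data.columns)
        if bh_family == "global":
            q = multipletests(p_uni.ravel(), method="fdr_bh")[1].reshape(p_uni.shape)
        else:
            q = np.column_stack(
                [
                    multipletests(p_uni[:, j], method="fdr_bh")[1]
                    for j in range(p_uni.shape[1])
                ]
            )
        self.q_uni = pd.DataFrame(q, index=data.index, columns=data.columns)

    # -- significance calls -------------------------------------------------

    def multivariate_calls(self, alpha: float | None = None) -> pd.Series:
        a = self.alpha if alpha is None else alpha
        return (self.q_multi < a).rename("multivariate")

    def univariate_calls(self, alpha: float | None = None) -> pd.DataFrame:
        a = self.alpha if alpha is None else alpha
        return self.q_uni < a

    def significant_strains(self, alpha: float | None = None) -> pd.Series:
        """A strain is significant if its profile changes multivariately or
        any single metabolite changes univariately (BH-adjusted p < alpha)."""
        return (
            self.multivariate_calls(alpha) | self.univariate_calls(alpha).any(axis=1)
        ).rename("significant")

    # -- summaries ----------------------------------------------------------

    def summarize_effects(self, alpha: float | None = None) -> dict:
        """Effect structure of the screen.

        Returns per-metabolite relative SD (robust SD / robust mean),
        per-metabolite significant-strain counts and their median, the
        per-strain count of simultaneously changed metabolites, and the
        cumulative distribution of simultaneous changes among significant
        strains.
        """
        uni = self.univariate_calls(alpha)
        per_met_counts = uni.sum(axis=0).rename("n_significant")
        per_strain = uni.sum(axis=1).rename("n_changes")
        sig = self.significant_strains(alpha)
        changed = per_strain[sig]
        if len(changed):
            counts = changed.value_counts().sort_index()
            cumulative = counts.cumsum() / counts.sum()
        else:
            cumulative = pd.Series(dtype=float)
        return {
            "rsd": (self.estimate.robust_sd / self.estimate.location).rename("rsd"),
            "per_metabolite_counts": per_met_counts,
            "median_per_metabolite": float(per_met_counts.median()),
            "per_strain_changes": per_strain,
            "cumulative_changes": cumulative,
            "n_significant": int(sig.sum()),
            "n_multivariate": int(self.multivariate_calls(alpha).sum()),
            "n_univariate": int(self.univariate_calls(alpha).any(axis=1).sum()),
        }

    def standardize_profile(self, profile: pd.Series, wt_profile: pd.Series) -> pd.Series:
        """Standardize an externally measured profile into screen units:
        subtract the matched untreated reference, divide by the robust SD."""
        sd = self.estimate.robust_sd
        if (sd == 0).any():
            raise ValueError("zero robust SD")
        profile = pd.Series(profile).reindex(sd.index)
        wt_profile = pd.Series(wt_profile).reindex(sd.index)
        return ((profile - wt_profile) / sd).rename(getattr(profile, "name", None))

    def report(self, alpha: float | None = None) -> pd.DataFrame:
        """Per-strain summary table of the significance tests."""
        a = self.alpha if alpha is None else alpha
        return pd.DataFrame(
            {
                "d2": self.d2,
                "p_multi": self.p_multi,
                "q_multi": self.q_multi,
                "n_univariate_changes": self.univariate_calls(a).sum(axis=1),
                "significant": self.significant_strains(a),
            }
        )

    def cell_report(self) -> pd.DataFrame:
        """Long-format strain x metabolite table (z, p, q)."""
        z = self.z.stack().rename("z")
        p = self.p_uni.stack().rename("p")
        q = self.q_uni.stack().rename("q")
        out = pd.concat([z, p, q], axis=1).reset_index()
        out.columns = ["strain", "metabolite", "z", "p", "q"]
        return out

    def plot_signature(self, strain, ax=None):
        from .plots import plot_signature

        return plot_signature(self, strain, ax=ax)

    def summary(self, alpha: float | None = None) -> str:
        a = self.alpha if alpha is None else alpha
        eff = self.summarize_effects(a)
        n, p = self.model.data.shape
        lines = [
            "Robust screen profile model",
            "=" * 44,
            f"strains: {n}    metabolites: {p}",
            f"MCD support fraction: {self.estimate.support_fraction:.2f}"
            f"    seed: {self.estimate.seed}",
            f"alpha (BH-adjusted): {a:g}",
            "-" * 44,
            f"significant strains:        {eff['n_significant']}"
            f" ({eff['n_significant'] / n:.1%})",
            f"  multivariate (chi2 on D2): {eff['n_multivariate']}",
            f"  univariate (any Z):        {eff['n_univariate']}",
            f"median hits per metabolite: {eff['median_per_metabolite']:.0f}",
            "-" * 44,
            "per-metabolite relative SD:",
        ]
        rsd = eff["rsd"]
        lines += [f"  {m:<12s} {v:6.1%}" for m, v in rsd.items()]
        return "\n".join(lines)
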