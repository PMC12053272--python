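"""Likelihood-based fit indices shared by the network and factor models.

All fitted structures report chi-square against the saturated model,
CFI against the independence baseline, RMSEA with a 90% CI from inversion
of the noncentral chi-square distribution, and the AIC/BIC information
criteria.  The same baseline (diagonal covariance, free means) is used for
every model fitted to the same data, so CFI values are comparable across
the network and factor models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

__all__ = ["FitIndices", "compute_fit_indices", "rmsea_ci"]


@dataclass(frozen=True)
class FitIndices:
    """Chi-square and derived fit measures for one fitted structure."""

    chi2: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    rmsea_ci: Tuple[float, float]   # 90% CI
    aic: float
    bic: float
    n: int
    n_params: int
    rmsea_defined: bool = True      # False when df = 0

    def as_dict(self) -> dict:
        return {
            "chi2": self.chi2, "df": self.df, "p_value": self.p_value,
            "cfi": self.cfi, "rmsea": self.rmsea,
            "rmsea_ci_low": self.rmsea_ci[0], "rmsea_ci_high": self.rmsea_ci[1],
            "aic": self.aic, "bic": self.bic, "n": self.n,
            "n_params": self.n_params,
        }


def _ncp_for_quantile(chi2: float, df: int, q: float,
                      tol: float = 1e-6) -> float:
    """Noncentrality lambda with ``ncx2.cdf(chi2, df, lambda) == q``.

    Bisection on [0, 10*chi2]; returns 0 when even the central distribution
    puts less than ``q`` mass below the statistic.
    """
    if stats.ncx2.cdf(chi2, df, 0.0) < q:
        return 0.0
    lo, hi = 0.0, max(10.0 * chi2, 1.0)
    while stats.ncx2.cdf(chi2, df, hi) > q:
        hi *= 2.0
        if hi > 1e8:
            break
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stats.ncx2.cdf(chi2, df, mid) > q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def rmsea_ci(chi2: float, df: int, n: int,
             level: float = 0.90) -> Tuple[float, float]:
    """90% RMSEA confidence interval via noncentral chi-square inversion."""
    if df <= 0 or n <= 1 or not np.isfinite(chi2):
        return (0.0, 0.0)
    a = (1.0 - level) / 2.0
    lam_lo = _ncp_for_quantile(chi2, df, 1.0 - a)
    lam_hi = _ncp_for_quantile(chi2, df, a)
    scale = df * (n - 1)
    return (float(np.sqrt(max(lam_lo, 0.0) / scale)),
            float(np.sqrt(max(lam_hi, 0.0) / scale)))


def compute_fit_indices(
    loglike: float,
    n_params: int,
    df: int,
    loglike_sat: float,
    loglike_base: float,
    df_base: int,
    n: int,
) -> FitIndices:
    """Assemble the fit-index set from log-likelihoods.

    ``chi2 = 2 (LL_sat - LL_model)``;
    ``CFI = 1 - max(chi2_M - df_M, 0) / max(chi2_B - df_B, chi2_M - df_M, 0)``;
    ``RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1)))`` (0, flagged undefined,
    when df = 0); ``AIC = -2 LL + 2 k``; ``BIC = -2 LL + k ln n``.
    """
    chi2 = max(2.0 * (loglike_sat - loglike), 0.0)
    chi2_base = max(2.0 * (loglike_sat - loglike_base), 0.0)
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, num, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0
    if df > 0:
        rmsea = float(np.sqrt(num / (df * (n - 1))))
        ci = rmsea_ci(chi2, df, n)
        defined = True
    else:
        rmsea, ci, defined = 0.0, (0.0, 0.0), False
    aic = -2.0 * loglike + 2.0 * n_params
    bic = -2.0 * loglike + n_params * np.log(n)
    return FitIndices(
        chi2=float(chi2), df=int(df), p_value=p_value, cfi=float(cfi),
        rmsea=rmsea, rmsea_ci=ci, aic=float(aic), bic=float(bic),
        n=int(n), n_params=int(n_params), rmsea_defined=defined,
    )
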