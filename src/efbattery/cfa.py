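"""Confirmatory factor models: correlated factors and bifactor.

Two theory-driven alternatives to the network description of task
performance:

* the **correlated-factor** model — each task loads on exactly one of the
  hypothesised constructs (by default set reconfiguration, attentional
  control, interference resolution) and the factors correlate freely;
* the **bifactor** model — a general executive-function factor on every
  task plus orthogonal construct-specific factors.

Estimation is maximum likelihood on the covariance structure
``Sigma = Lambda Phi Lambda' + Theta`` (unit factor variances for
identification), by quasi-Newton with the analytic gradient and random
restarts on non-convergence.  Residual variances are *not* bounded away
from zero, so improper (Heywood) solutions — a known failure mode of
bifactor models with two-indicator specific factors — surface as explicit
warnings instead of being silently truncated.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fitindices import FitIndices, compute_fit_indices

__all__ = [
    "FactorModel",
    "FactorResults",
    "HeywoodWarning",
    "default_pattern",
    "compare_models",
]


class HeywoodWarning(UserWarning):
    """An improper solution: a negative residual variance."""


def default_pattern() -> Dict[str, Tuple[str, ...]]:
    """Default loading pattern over the ten task metrics."""
    return {
        "set_reconfiguration": ("span_fwd", "span_bwd", "taskswitch"),
        "attentional_control": ("cpt_impulsive", "cpt_sustained"),
        "interference_resolution": ("flanker", "stroop", "boxed", "compass",
                                    "tap_trace"),
    }


class FactorModel:
    """Confirmatory factor model for a participant x task score table.

    Parameters
    ----------
    data : DataFrame
        Rows are participants, columns observed task metrics.  Rows with
        any missing entry are dropped (complete-case analysis).
    pattern : mapping factor -> variables
        Simple-structure loading pattern.  For the correlated model each
        variable must appear under exactly one factor; for the bifactor
        model the same pattern defines the specific factors while the
        general factor loads on every variable.
    kind : {"correlated", "bifactor"}
    bound_theta : bool
        When True, residual variances are constrained non-negative
        (Heywood cases become boundary solutions instead of warnings).
    """

    def __init__(self, data: pd.DataFrame,
                 pattern: Optional[Dict[str, Sequence[str]]] = None,
                 kind: str = "correlated", bound_theta: bool = False):
        if kind not in ("correlated", "bifactor"):
            raise ValueError("kind must be 'correlated' or 'bifactor'")
        pattern = pattern or default_pattern()
        data = data.astype(float).dropna()
        self.data = data
        self.variables = list(data.columns)
        self.kind = kind
        self.bound_theta = bound_theta
        self.p = len(self.variables)
        self.n = len(data)
        if self.n <= self.p:
            raise ValueError(f"n={self.n} <= p={self.p}")

        seen: Dict[str, str] = {}
        for f, vs in pattern.items():
            for v in vs:
                if v not in self.variables:
                    raise ValueError(f"pattern variable {v!r} not in data")
                if v in seen:
                    raise ValueError(
                        f"variable {v!r} appears under factors "
                        f"{seen[v]!r} and {f!r}; simple structure required"
                    )
                seen[v] = f
        if set(seen) != set(self.variables):
            missing = set(self.variables) - set(seen)
            raise ValueError(f"pattern does not cover variables {sorted(missing)}")
        self.pattern = {f: tuple(vs) for f, vs in pattern.items()}
        self.specific_factors = list(self.pattern)
        if kind == "bifactor":
            self.factors = ["general"] + self.specific_factors
        else:
            self.factors = list(self.specific_factors)
        self.q = len(self.factors)

        arr = data.to_numpy()
        self.sample_cov = np.cov(arr, rowvar=False, bias=True)
        self.sample_mean = arr.mean(axis=0)

        # free-loading positions (variable idx, factor idx)
        vidx = {v: i for i, v in enumerate(self.variables)}
        fidx = {f: i for i, f in enumerate(self.factors)}
        self._free_loadings: List[Tuple[int, int]] = []
        if kind == "bifactor":
            for v in self.variables:
                self._free_loadings.append((vidx[v], fidx["general"]))
        for f, vs in self.pattern.items():
            for v in vs:
                self._free_loadings.append((vidx[v], fidx[f]))
        # free factor correlations (correlated model only)
        self._free_phi: List[Tuple[int, int]] = []
        if kind == "correlated":
            for a in range(self.q):
                for b in range(a + 1, self.q):
                    self._free_phi.append((a, b))

    # -- likelihood anchors ----------------------------------------------

    def saturated_loglike(self) -> float:
        sign, logdet = np.linalg.slogdet(self.sample_cov)
        return -0.5 * self.n * (self.p * np.log(2 * np.pi) + logdet + self.p)

    def baseline_loglike(self) -> float:
        var = np.diag(self.sample_cov)
        return -0.5 * self.n * (self.p * np.log(2 * np.pi)
                                + np.log(var).sum() + self.p)

    def baseline_df(self) -> int:
        return self.p * (self.p + 3) // 2 - 2 * self.p

    @property
    def n_params(self) -> int:
        # means + loadings + factor correlations + residual variances
        return self.p + len(self._free_loadings) + len(self._free_phi) + self.p

    @property
    def df(self) -> int:
        return self.p * (self.p + 3) // 2 - self.n_params

    # -- parameter vector -------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        nl = len(self._free_loadings)
        lam = np.zeros((self.p, self.q))
        for k, (i, j) in enumerate(self._free_loadings):
            lam[i, j] = theta[k]
        phi = np.eye(self.q)
        for k, (a, b) in enumerate(self._free_phi):
            phi[a, b] = phi[b, a] = theta[nl + k]
        th = theta[nl + len(self._free_phi):]
        return lam, phi, th

    def _nll_grad(self, theta: np.ndarray):
        lam, phi, th = self._unpack(theta)
        sigma = lam @ phi @ lam.T + np.diag(th)
        # large finite penalty instead of inf: L-BFGS-B's line search
        # backtracks on big values but aborts on non-finite ones
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(theta)
        if len(self._free_phi):
            if np.linalg.eigvalsh(phi).min() <= 1e-10:
                return 1e12, np.zeros_like(theta)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        inv = np.linalg.inv(sigma)
        nll = 0.5 * self.n * (self.p * np.log(2 * np.pi) + logdet
                              + float(np.sum(inv * self.sample_cov)))
        G = 0.5 * self.n * (inv - inv @ self.sample_cov @ inv)
        grad_lam_full = 2.0 * G @ lam @ phi
        grad_phi_full = lam.T @ G @ lam
        grad = np.empty_like(theta)
        nl = len(self._free_loadings)
        for k, (i, j) in enumerate(self._free_loadings):
            grad[k] = grad_lam_full[i, j]
        for k, (a, b) in enumerate(self._free_phi):
            grad[nl + k] = 2.0 * grad_phi_full[a, b]
        grad[nl + len(self._free_phi):] = np.diag(G)
        return nll, grad

    # -- fitting ----------------------------------------------------------

    def fit(self, n_restarts: int = 10, seed: int = 0) -> "FactorResults":
        """Maximum-likelihood fit with random restarts on non-convergence.

        Never raises on non-convergence: the status and last iterate are
        reported on the results object.  Negative residual variances raise
        a :class:`HeywoodWarning` naming the offending variables.
        """
        rng = np.random.default_rng(seed)
        sd = np.sqrt(np.diag(self.sample_cov))
        lam0 = 0.7 * sd
        theta0 = np.concatenate([
            [lam0[i] * (0.7 if self.kind == "bifactor" else 1.0)
             for i, _ in self._free_loadings],
            [0.3] * len(self._free_phi),
            0.5 * np.diag(self.sample_cov),
        ])
        bounds = None
        nl = len(self._free_loadings)
        if self._free_phi or self.bound_theta:
            bounds = [(None, None)] * nl
            bounds += [(-0.999, 0.999)] * len(self._free_phi)
            bounds += [(1e-8, None) if self.bound_theta else (None, None)] * self.p

        best = None
        start = theta0
        for attempt in range(max(1, n_restarts)):
            res = optimize.minimize(self._nll_grad, start, jac=True,
                                    method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 5000, "ftol": 1e-13,
                                             "gtol": 1e-7})
            if best is None or res.fun < best.fun:
                best = res
            if res.success and np.isfinite(res.fun):
                break
            jitter = rng.normal(0.0, 0.2, size=theta0.size)
            start = theta0 * (1.0 + jitter) + 0.05 * rng.normal(size=theta0.size)

        lam, phi, th = self._unpack(best.x)
        warn_list: List[str] = []
        heywood = [self.variables[i] for i in np.flatnonzero(th < 0)]
        if heywood:
            msg = ("improper solution: negative residual variance for "
                   + ", ".join(heywood))
            warn_list.append(msg)
            _warnings.warn(msg, HeywoodWarning)
        if not best.success:
            warn_list.append(f"optimizer did not converge: {best.message}")
        return FactorResults(
            model=self, loadings_raw=lam, phi=phi, theta=th,
            loglike=-float(best.fun), converged=bool(best.success),
            heywood=heywood, warnings=warn_list,
        )


@dataclass
class FactorResults:
    """Estimates and diagnostics of a fitted factor model."""

    model: FactorModel
    loadings_raw: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    loglike: float
    converged: bool
    heywood: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def df(self) -> int:
        return self.model.df

    def implied_cov(self) -> np.ndarray:
        return (self.loadings_raw @ self.phi @ self.loadings_raw.T
                + np.diag(self.theta))

    @property
    def loadings(self) -> pd.DataFrame:
        """Standardised loadings (unit factor variances; rows scaled by the
        model-implied SD of each variable).  Pattern zeros are exact zeros."""
        sd = np.sqrt(np.abs(np.diag(self.implied_cov())))
        lam = self.loadings_raw / sd[:, None]
        # resolve sign indeterminacy: each factor's loading sum positive
        signs = np.where(lam.sum(axis=0) < 0, -1.0, 1.0)
        lam = lam * signs
        return pd.DataFrame(lam, index=self.model.variables,
                            columns=self.model.factors)

    @property
    def factor_correlations(self) -> pd.DataFrame:
        lam = self.loadings_raw
        signs = np.where((lam / np.sqrt(np.abs(np.diag(self.implied_cov())))[:, None])
                         .sum(axis=0) < 0, -1.0, 1.0)
        phi = self.phi * np.outer(signs, signs)
        return pd.DataFrame(phi, index=self.model.factors,
                            columns=self.model.factors)

    @property
    def residual_variances(self) -> pd.Series:
        """Standardised residual variances (negative = Heywood case)."""
        sd2 = np.abs(np.diag(self.implied_cov()))
        return pd.Series(self.theta / sd2, index=self.model.variables)

    def fit_indices(self) -> FitIndices:
        return compute_fit_indices(
            loglike=self.loglike,
            n_params=self.n_params,
            df=self.df,
            loglike_sat=self.model.saturated_loglike(),
            loglike_base=self.model.baseline_loglike(),
            df_base=self.model.baseline_df(),
            n=self.model.n,
        )

    def summary(self) -> str:
        fi = self.fit_indices()
        lines = [
            f"{self.model.kind} factor model "
            f"({self.model.q} factors, n={self.model.n})",
            f"  loglike = {self.loglike:.3f}   params = {self.n_params}"
            f"   converged = {self.converged}",
            f"  chi2({fi.df}) = {fi.chi2:.2f}, p = {fi.p_value:.3f}   "
            f"CFI = {fi.cfi:.3f}   RMSEA = {fi.rmsea:.3f}",
            f"  AIC = {fi.aic:.2f}   BIC = {fi.bic:.2f}",
            "",
            "Standardised loadings:",
            self.loadings.round(3).to_string(),
        ]
        if self.model.kind == "correlated":
            lines += ["", "Factor correlations:",
                      self.factor_correlations.round(3).to_string()]
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)


def compare_models(fits: Dict[str, object]) -> pd.DataFrame:
    """Side-by-side fit comparison of fitted structures.

    ``fits`` maps a model name to any results object exposing
    ``fit_indices()`` (network or factor results).  Returns one row per
    model with chi2 (df), p, CFI, RMSEA (CI), AIC, BIC, and a ``best_*``
    flag per criterion (lowest chi2/RMSEA/AIC/BIC, highest CFI).
    """
    rows = {}
    for name, res in fits.items():
        fi = res.fit_indices()
        rows[name] = {
            "chi2": fi.chi2, "df": fi.df, "p": fi.p_value, "cfi": fi.cfi,
            "rmsea": fi.rmsea, "rmsea_low": fi.rmsea_ci[0],
            "rmsea_high": fi.rmsea_ci[1], "aic": fi.aic, "bic": fi.bic,
        }
    table = pd.DataFrame(rows).T
    table["best_chi2"] = table["chi2"] == table["chi2"].min()
    table["best_cfi"] = table["cfi"] == table["cfi"].max()
    table["best_rmsea"] = table["rmsea"] == table["rmsea"].min()
    table["best_aic"] = table["aic"] == table["aic"].min()
    table["best_bic"] = table["bic"] == table["bic"].min()
    return table
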