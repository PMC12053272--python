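"""Partial-correlation network model (Gaussian graphical model).

The model follows the standard psychometric-network parameterisation

    Sigma = Delta (I - Omega)^{-1} Delta

where ``Omega`` is the symmetric partial-correlation ("edge weight") matrix
with zero diagonal and ``Delta`` a positive diagonal scaling matrix; the mean
vector ``mu`` completes the parameter set (p means + p scalings +
p(p-1)/2 edges saturate the mean-and-covariance structure).  Estimation is
maximum likelihood; rows with missing entries contribute their casewise
(pattern-marginal) multivariate-normal likelihood ("full information" ML).

The analysis pipeline mirrors common practice for task-battery data:

1. fit the saturated network;
2. prune edges whose two-sided p-value exceeds alpha and refit under the
   zero constraints;
3. detect communities of tasks with the spin-glass algorithm (which accepts
   negative edges), replicated with distinct seeds and summarised by the
   modal partition and its selection frequency;
4. bootstrap edge stability; compute node centralities;
5. test multigroup invariance through a ladder of equality constraints
   (edges; + means; + scalings) compared by likelihood-ratio tests and
   information criteria.

:class:`GaussianGraphicalModel` is the model object; :meth:`~GaussianGraphicalModel.fit`
returns a :class:`GGMResults` carrying estimates, edge p-values, fit indices
and a ``summary()`` table, statsmodels-style.
"""

from __future__ import annotations

import dataclasses
import random as _pyrandom
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import igraph
import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fitindices import FitIndices, compute_fit_indices

__all__ = [
    "GaussianGraphicalModel",
    "GGMResults",
    "Partition",
    "InvarianceResults",
    "invariance_ladder",
    "spinglass_communities",
    "bootstrap_edges",
    "centrality",
    "concurrent_correlations",
    "effect_size_label",
]


# ---------------------------------------------------------------------------
# Data preparation: missingness patterns
# ---------------------------------------------------------------------------


@dataclass
class _PatternData:
    """Sufficient statistics of one missingness pattern."""

    n: int
    obs: np.ndarray        # indices of observed variables
    mean: np.ndarray       # pattern sample mean (observed vars)
    scatter: np.ndarray    # ML covariance within pattern (observed vars)


def _patterns_from(data: np.ndarray) -> List[_PatternData]:
    mask = ~np.isnan(data)
    out: List[_PatternData] = []
    keys, inv = np.unique(mask, axis=0, return_inverse=True)
    for k in range(keys.shape[0]):
        obs = np.flatnonzero(keys[k])
        if obs.size == 0:
            continue
        rows = data[inv == k][:, obs]
        xbar = rows.mean(axis=0)
        dev = rows - xbar
        out.append(_PatternData(n=rows.shape[0], obs=obs, mean=xbar,
                                scatter=dev.T @ dev / rows.shape[0]))
    return out


def _em_mvnorm(data: np.ndarray, max_iter: int = 500,
               tol: float = 1e-10) -> Tuple[np.ndarray, np.ndarray]:
    """EM estimate of (mu, Sigma) of a multivariate normal with MAR data."""
    p = data.shape[1]
    col_mean = np.nanmean(data, axis=0)
    filled = np.where(np.isnan(data), col_mean, data)
    mu = filled.mean(axis=0)
    sigma = np.cov(filled, rowvar=False, bias=True) + 1e-6 * np.eye(p)
    n = data.shape[0]
    miss = np.isnan(data)
    if not miss.any():
        return mu, np.cov(data, rowvar=False, bias=True)
    prev = -np.inf
    for _ in range(max_iter):
        ex = np.zeros(p)
        exx = np.zeros((p, p))
        for i in range(n):
            o = np.flatnonzero(~miss[i])
            m = np.flatnonzero(miss[i])
            xi = np.array(data[i], copy=True)
            if m.size:
                soo = sigma[np.ix_(o, o)]
                smo = sigma[np.ix_(m, o)]
                sol = np.linalg.solve(soo, (data[i, o] - mu[o]))
                xi[m] = mu[m] + smo @ sol
                cond = sigma[np.ix_(m, m)] - smo @ np.linalg.solve(soo, smo.T)
            ex += xi
            exx += np.outer(xi, xi)
            if m.size:
                exx[np.ix_(m, m)] += cond
        mu_new = ex / n
        sigma_new = exx / n - np.outer(mu_new, mu_new)
        ll = _casewise_loglike(mu_new, sigma_new, _patterns_from(data))
        if abs(ll - prev) < tol * (abs(prev) + 1.0):
            return mu_new, sigma_new
        prev = ll
        mu, sigma = mu_new, sigma_new
    return mu, sigma


def _casewise_loglike(mu: np.ndarray, sigma: np.ndarray,
                      patterns: Sequence[_PatternData]) -> float:
    ll = 0.0
    for pat in patterns:
        o = pat.obs
        soo = sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(soo)
        if sign <= 0:
            return -np.inf
        d = pat.mean - mu[o]
        a = pat.scatter + np.outer(d, d)
        ll -= 0.5 * pat.n * (o.size * np.log(2 * np.pi) + logdet
                             + float(np.trace(np.linalg.solve(soo, a))))
    return float(ll)


# ---------------------------------------------------------------------------
# Parameterisation helpers
# ---------------------------------------------------------------------------


def _omega_delta_from_sigma(sigma: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Invert Sigma = Delta (I - Omega)^-1 Delta at the saturated solution."""
    K = np.linalg.inv(sigma)
    d = 1.0 / np.sqrt(np.diag(K))
    omega = np.eye(len(d)) - K * np.outer(d, d)
    np.fill_diagonal(omega, 0.0)
    return omega, d


def _sigma_from(omega: np.ndarray, delta: np.ndarray) -> Optional[np.ndarray]:
    ImO = np.eye(omega.shape[0]) - omega
    try:
        B = np.linalg.inv(ImO)
    except np.linalg.LinAlgError:
        return None
    sigma = (B * delta).T * delta  # Delta B Delta for diagonal Delta
    sigma = (sigma + sigma.T) / 2.0
    # positive definiteness of Sigma requires I - Omega to be PD
    if np.linalg.eigvalsh(ImO).min() <= 1e-12:
        return None
    return sigma


def _edge_pvalues(omega: np.ndarray, n: int) -> np.ndarray:
    """Two-sided edge p-values from the Fisher-z approximation.

    A partial correlation controls the remaining p-2 variables, so the
    z-transform has standard error 1/sqrt(n - (p - 2) - 3).
    """
    p = omega.shape[0]
    se_df = n - (p - 2) - 3
    if se_df <= 0:
        return np.ones_like(omega)
    z = np.arctanh(np.clip(omega, -0.999999, 0.999999))
    stat = np.abs(z) * np.sqrt(se_df)
    pv = 2.0 * stats.norm.sf(stat)
    np.fill_diagonal(pv, 1.0)
    return pv


# ---------------------------------------------------------------------------
# The model object
# ---------------------------------------------------------------------------


class GaussianGraphicalModel:
    """Partial-correlation network model for a participant x task table.

    Parameters
    ----------
    data : DataFrame
        Rows are participants, columns task metrics; NaN marks missing.
    groups : Series, optional
        Group label per row; enables multigroup fits with equality
        constraints (see :func:`invariance_ladder`).
    missing : {"fiml", "listwise"}
        Casewise ML over missingness patterns (default) or row deletion.
    """

    def __init__(self, data: pd.DataFrame, groups: Optional[pd.Series] = None,
                 missing: str = "fiml"):
        if missing not in ("fiml", "listwise"):
            raise ValueError("missing must be 'fiml' or 'listwise'")
        if data.shape[1] < 2:
            raise ValueError("need at least 2 variables")
        data = data.astype(float)
        if missing == "listwise":
            keep = data.notna().all(axis=1)
            data = data.loc[keep]
            groups = groups.loc[keep] if groups is not None else None
        # drop rows with nothing observed
        some = data.notna().any(axis=1)
        data = data.loc[some]
        groups = groups.loc[some] if groups is not None else None
        self.data = data
        self.variables = list(data.columns)
        self.p = data.shape[1]
        self.groups = groups
        if groups is None:
            self.group_labels = ["all"]
            self._group_rows = {"all": data}
        else:
            self.group_labels = sorted(pd.unique(groups))
            self._group_rows = {g: data.loc[groups == g] for g in self.group_labels}
        self.n_obs = {g: len(df) for g, df in self._group_rows.items()}
        self.n_total = sum(self.n_obs.values())
        for g, df in self._group_rows.items():
            if len(df) <= self.p:
                raise ValueError(f"group {g!r} has n={len(df)} <= p={self.p}")
        self._patterns = {g: _patterns_from(df.to_numpy())
                          for g, df in self._group_rows.items()}
        self._check_collinearity()
        self._sat_cache: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, float]]] = None
        self._base_ll: Optional[float] = None

    # -- saturated & baseline anchors ------------------------------------

    def _check_collinearity(self) -> None:
        for g, df in self._group_rows.items():
            sub = df.dropna()
            if len(sub) < 3:
                continue
            corr = sub.corr().to_numpy()
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            if abs(corr[i, j]) > 1.0 - 1e-10:
                raise ValueError(
                    f"singular covariance in group {g!r}: variables "
                    f"{self.variables[i]!r} and {self.variables[j]!r} are collinear"
                )

    def _saturated(self) -> Dict[str, Tuple[np.ndarray, np.ndarray, float]]:
        """Per group: (mu_hat, sigma_hat, casewise loglike) of the saturated model."""
        if self._sat_cache is None:
            cache = {}
            for g, df in self._group_rows.items():
                arr = df.to_numpy()
                if np.isnan(arr).any():
                    mu, sigma = _em_mvnorm(arr)
                else:
                    mu = arr.mean(axis=0)
                    sigma = np.cov(arr, rowvar=False, bias=True)
                ll = _casewise_loglike(mu, sigma, self._patterns[g])
                cache[g] = (mu, sigma, ll)
            self._sat_cache = cache
        return self._sat_cache

    def saturated_loglike(self) -> float:
        return sum(ll for _, _, ll in self._saturated().values())

    def baseline_loglike(self) -> float:
        """Independence model: all edges zero, means and scalings free."""
        if self._base_ll is None:
            mask = np.zeros((self.p, self.p), dtype=bool)
            res = self.fit(mask=mask)
            self._base_ll = res.loglike
        return self._base_ll

    def baseline_df(self) -> int:
        G = len(self.group_labels)
        moments = G * self.p * (self.p + 3) // 2
        return moments - G * 2 * self.p

    # -- fitting ----------------------------------------------------------

    def fit(self, mask: Optional[np.ndarray] = None, *,
            equal_edges: bool = False, equal_means: bool = False,
            equal_scalings: bool = False) -> "GGMResults":
        """Fit the network by (casewise) maximum likelihood.

        ``mask`` is a symmetric boolean matrix marking FREE edges
        (None = saturated).  The saturated single- or multi-group fit with
        no equality constraints is solved analytically (EM under missing
        data); anything else is optimised by L-BFGS with the analytic
        gradient.
        """
        if mask is None:
            mask_arr = ~np.eye(self.p, dtype=bool)
        else:
            mask_arr = np.asarray(mask, dtype=bool)
            if mask_arr.shape != (self.p, self.p) or not (mask_arr == mask_arr.T).all():
                raise ValueError("mask must be a symmetric p x p boolean matrix")
            mask_arr = mask_arr & ~np.eye(self.p, dtype=bool)
        saturated = mask_arr.sum() == self.p * (self.p - 1) and not (
            equal_edges or equal_means or equal_scalings
        )
        if saturated:
            return self._fit_saturated(mask_arr)
        return self._fit_constrained(mask_arr, equal_edges, equal_means,
                                     equal_scalings)

    def _fit_saturated(self, mask_arr: np.ndarray) -> "GGMResults":
        omega, delta, mu, ll = {}, {}, {}, 0.0
        for g in self.group_labels:
            mu_g, sigma_g, ll_g = self._saturated()[g]
            om, de = _omega_delta_from_sigma(sigma_g)
            omega[g], delta[g], mu[g] = om, de, mu_g
            ll += ll_g
        return GGMResults(self, omega, delta, mu, mask_arr,
                          equal_edges=False, equal_means=False,
                          equal_scalings=False, loglike=ll, converged=True)

    def _fit_constrained(self, mask_arr: np.ndarray, equal_edges: bool,
                         equal_means: bool,
                         equal_scalings: bool) -> "GGMResults":
        no_sharing = not (equal_edges or equal_means or equal_scalings)
        if no_sharing and len(self.group_labels) > 1:
            # groups share no parameters: the joint optimum is the
            # combination of the per-group optima
            omega, delta, mu = {}, {}, {}
            ll = 0.0
            ok = True
            for g in self.group_labels:
                sub = GaussianGraphicalModel(self._group_rows[g])
                res_g = sub.fit(mask=mask_arr)
                omega[g], delta[g] = res_g._omega["all"], res_g._delta["all"]
                mu[g] = res_g._mu["all"]
                ll += res_g.loglike
                ok = ok and res_g.converged
            return GGMResults(self, omega, delta, mu, mask_arr,
                              equal_edges=False, equal_means=False,
                              equal_scalings=False, loglike=ll, converged=ok)
        theta0, unpack, nll_grad = self._make_objective(
            mask_arr, equal_edges, equal_means, equal_scalings)
        opts = {"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-8}
        res = optimize.minimize(nll_grad, theta0, jac=True, method="L-BFGS-B",
                                options=opts)
        # a line search that probes the non-PD boundary can trigger an early
        # ftol stop; restarting from the current iterate is cheap and makes
        # the solution reliable
        for _ in range(4):
            if np.abs(res.jac).max() < 1e-3:
                break
            res2 = optimize.minimize(nll_grad, res.x, jac=True,
                                     method="L-BFGS-B", options=opts)
            if res2.fun >= res.fun - 1e-12:
                res = res2 if res2.fun < res.fun else res
                break
            res = res2
        omegas, deltas, mus = unpack(res.x)
        return GGMResults(self, omegas, deltas, mus, mask_arr,
                          equal_edges=equal_edges, equal_means=equal_means,
                          equal_scalings=equal_scalings,
                          loglike=-float(res.fun), converged=bool(res.success))

    def _make_objective(self, mask_arr: np.ndarray, equal_edges: bool,
                        equal_means: bool, equal_scalings: bool):
        """Build (start, unpack, objective) for the constrained ML problem."""
        G = self.group_labels
        iu = np.triu_indices(self.p, 1)
        free_edge = mask_arr[iu]
        m = int(free_edge.sum())
        edge_groups = ["shared"] if equal_edges else G
        scale_groups = ["shared"] if equal_scalings else G
        mean_groups = ["shared"] if equal_means else G

        # start values from (pooled) saturated estimates
        sat = self._saturated()
        start_parts = []
        pooled_sigma = sum(self.n_obs[g] * sat[g][1] for g in G) / self.n_total
        pooled_mu = sum(self.n_obs[g] * sat[g][0] for g in G) / self.n_total
        pooled_om, pooled_de = _omega_delta_from_sigma(pooled_sigma)

        def feasible_edges(om: np.ndarray, de: np.ndarray) -> np.ndarray:
            """Shrink a masked edge start toward zero until Sigma is PD."""
            ev = (om * mask_arr)[iu][free_edge]
            for _ in range(20):
                full = np.zeros(len(free_edge))
                full[free_edge] = ev
                cand = np.zeros((self.p, self.p))
                cand[iu] = full
                if _sigma_from(cand + cand.T, de) is not None:
                    return ev
                ev = 0.8 * ev
            return np.zeros_like(ev)

        for eg in edge_groups:
            if eg == "shared":
                start_parts.append(feasible_edges(pooled_om, pooled_de))
            else:
                om_g, de_g = _omega_delta_from_sigma(sat[eg][1])
                start_parts.append(feasible_edges(om_g, de_g))
        for eg in scale_groups:
            de = pooled_de if eg == "shared" else _omega_delta_from_sigma(sat[eg][1])[1]
            start_parts.append(np.log(de))
        for mg in mean_groups:
            mu0 = pooled_mu if mg == "shared" else sat[mg][0]
            start_parts.append(mu0)
        theta0 = np.concatenate(start_parts)

        def unpack(theta: np.ndarray):
            pos = 0
            omegas, deltas, mus = {}, {}, {}
            edge_vals = {}
            for eg in edge_groups:
                edge_vals[eg] = theta[pos:pos + m]
                pos += m
            for sg in scale_groups:
                deltas[sg] = np.exp(theta[pos:pos + self.p])
                pos += self.p
            for mg in mean_groups:
                mus[mg] = theta[pos:pos + self.p]
                pos += self.p
            for g in G:
                ev = edge_vals["shared" if equal_edges else g]
                om = np.zeros((self.p, self.p))
                vals = np.zeros(len(free_edge))
                vals[free_edge] = ev
                om[iu] = vals
                om = om + om.T
                omegas[g] = om
            return (omegas,
                    {g: deltas["shared" if equal_scalings else g] for g in G},
                    {g: mus["shared" if equal_means else g] for g in G})

        def nll_grad(theta: np.ndarray):
            omegas, deltas, mus = unpack(theta)
            nll = 0.0
            g_edges = {eg: np.zeros(m) for eg in edge_groups}
            g_scale = {sg: np.zeros(self.p) for sg in scale_groups}
            g_mean = {mg: np.zeros(self.p) for mg in mean_groups}
            for g in G:
                om, de, mu = omegas[g], deltas[g], mus[g]
                sigma = _sigma_from(om, de)
                if sigma is None:
                    # large finite penalty: the Fortran line search of
                    # L-BFGS-B backtracks on big values but aborts on inf
                    return 1e12, np.zeros_like(theta)
                # accumulate casewise NLL and dNLL/dSigma, dNLL/dmu
                Gmat = np.zeros((self.p, self.p))
                gmu = np.zeros(self.p)
                nll_g = 0.0
                for pat in self._patterns[g]:
                    o = pat.obs
                    soo = sigma[np.ix_(o, o)]
                    try:
                        chol = np.linalg.cholesky(soo)
                    except np.linalg.LinAlgError:
                        return 1e12, np.zeros_like(theta)
                    logdet = 2.0 * np.log(np.diag(chol)).sum()
                    inv = np.linalg.inv(soo)
                    d = pat.mean - mu[o]
                    a = pat.scatter + np.outer(d, d)
                    nll_g += 0.5 * pat.n * (
                        o.size * np.log(2 * np.pi) + logdet
                        + float(np.sum(inv * a))
                    )
                    Gpat = 0.5 * pat.n * (inv - inv @ a @ inv)
                    Gmat[np.ix_(o, o)] += Gpat
                    gmu[o] += -pat.n * (inv @ d)
                nll += nll_g
                # chain rule to omega, delta, mu
                B = np.linalg.inv(np.eye(self.p) - om)
                BD = B * de                    # B @ Delta (columns scaled)
                Mmat = BD @ Gmat @ BD.T        # B Delta G Delta B
                grad_edge_full = 2.0 * Mmat[iu][free_edge]
                # d/d delta_k = 2 (B Delta G)_kk ; chain to log-delta
                grad_logdelta = 2.0 * np.einsum("ij,ji->i", BD, Gmat) * de
                g_edges["shared" if equal_edges else g] += grad_edge_full
                g_scale["shared" if equal_scalings else g] += grad_logdelta
                g_mean["shared" if equal_means else g] += gmu
            grad = np.concatenate(
                [g_edges[eg] for eg in edge_groups]
                + [g_scale[sg] for sg in scale_groups]
                + [g_mean[mg] for mg in mean_groups]
            )
            return nll, grad

        return theta0, unpack, nll_grad


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------


class GGMResults:
    """Estimates, uncertainties and diagnostics of a fitted network model."""

    def __init__(self, model: GaussianGraphicalModel,
                 omega: Dict[str, np.ndarray], delta: Dict[str, np.ndarray],
                 mu: Dict[str, np.ndarray], mask: np.ndarray, *,
                 equal_edges: bool, equal_means: bool, equal_scalings: bool,
                 loglike: float, converged: bool,
                 pruned_at: Optional[float] = None):
        self.model = model
        self._omega = omega
        self._delta = delta
        self._mu = mu
        self.mask = mask
        self.equal_edges = equal_edges
        self.equal_means = equal_means
        self.equal_scalings = equal_scalings
        self.loglike = loglike
        self.converged = converged
        self.pruned_at = pruned_at

    # -- accessors --------------------------------------------------------

    @property
    def is_multigroup(self) -> bool:
        return len(self.model.group_labels) > 1

    def omega(self, group: Optional[str] = None) -> pd.DataFrame:
        g = group or self.model.group_labels[0]
        v = self.model.variables
        return pd.DataFrame(self._omega[g], index=v, columns=v)

    def delta(self, group: Optional[str] = None) -> pd.Series:
        g = group or self.model.group_labels[0]
        return pd.Series(self._delta[g], index=self.model.variables)

    def means(self, group: Optional[str] = None) -> pd.Series:
        g = group or self.model.group_labels[0]
        return pd.Series(self._mu[g], index=self.model.variables)

    @property
    def n_params(self) -> int:
        iu = np.triu_indices(self.model.p, 1)
        m = int(self.mask[iu].sum())
        G = len(self.model.group_labels)
        n_edges = m if self.equal_edges or G == 1 else m * G
        n_scale = self.model.p if self.equal_scalings or G == 1 else self.model.p * G
        n_mean = self.model.p if self.equal_means or G == 1 else self.model.p * G
        return n_edges + n_scale + n_mean

    @property
    def df(self) -> int:
        G = len(self.model.group_labels)
        moments = G * self.model.p * (self.model.p + 3) // 2
        return moments - self.n_params

    def edge_pvalues(self, group: Optional[str] = None) -> pd.DataFrame:
        g = group or self.model.group_labels[0]
        n = self.model.n_total if self.equal_edges else self.model.n_obs[g]
        pv = _edge_pvalues(self._omega[g], n)
        v = self.model.variables
        return pd.DataFrame(pv, index=v, columns=v)

    # -- pipeline steps ---------------------------------------------------

    def prune_and_refit(self, alpha: float = 0.05,
                        refit: bool = True) -> "GGMResults":
        """Fix non-significant edges (two-sided p > alpha) to zero and refit.

        One-shot pruning: the significance decision is taken on this model's
        edge p-values, then the constrained model is re-estimated once.
        With ``refit=False`` the pruned edges are zeroed without
        re-estimating (used by large resampling loops where the mask, not
        the refit, is the quantity of interest).
        """
        pv = np.ones((self.model.p, self.model.p))
        for g in self.model.group_labels:
            pv = np.minimum(pv, self.edge_pvalues(g).to_numpy())
        keep = (pv <= alpha) & self.mask
        keep = keep & keep.T
        if refit:
            res = self.model.fit(mask=keep, equal_edges=self.equal_edges,
                                 equal_means=self.equal_means,
                                 equal_scalings=self.equal_scalings)
        else:
            omega = {g: self._omega[g] * keep for g in self.model.group_labels}
            sigma_ok = all(_sigma_from(omega[g], self._delta[g]) is not None
                           for g in self.model.group_labels)
            ll = -np.inf
            if sigma_ok:
                ll = sum(
                    _casewise_loglike(self._mu[g],
                                      _sigma_from(omega[g], self._delta[g]),
                                      self.model._patterns[g])
                    for g in self.model.group_labels
                )
            res = GGMResults(self.model, omega, self._delta, self._mu, keep,
                             equal_edges=self.equal_edges,
                             equal_means=self.equal_means,
                             equal_scalings=self.equal_scalings,
                             loglike=float(ll), converged=True)
        res.pruned_at = alpha
        return res

    def fit_indices(self) -> FitIndices:
        """Chi-square, CFI, RMSEA (90% CI), AIC and BIC for this model."""
        return compute_fit_indices(
            loglike=self.loglike,
            n_params=self.n_params,
            df=self.df,
            loglike_sat=self.model.saturated_loglike(),
            loglike_base=self.model.baseline_loglike(),
            df_base=self.model.baseline_df(),
            n=self.model.n_total,
        )

    def n_edges(self) -> int:
        iu = np.triu_indices(self.model.p, 1)
        return int(self.mask[iu].sum())

    def edge_list(self, group: Optional[str] = None) -> pd.DataFrame:
        """Tidy edge list: node_i, node_j, weight, p, retained."""
        g = group or self.model.group_labels[0]
        om = self._omega[g]
        pv = self.edge_pvalues(g).to_numpy()
        v = self.model.variables
        rows = []
        for i in range(self.model.p):
            for j in range(i + 1, self.model.p):
                rows.append({
                    "node_i": v[i], "node_j": v[j],
                    "weight": float(om[i, j]), "p": float(pv[i, j]),
                    "retained": bool(self.mask[i, j]),
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        fi = self.fit_indices()
        lines = [
            "Gaussian graphical model (partial-correlation network)",
            f"  variables: {self.model.p}   groups: {len(self.model.group_labels)}"
            f"   n = {self.model.n_total}",
            f"  free edges: {self.n_edges()} / {self.model.p * (self.model.p - 1) // 2}"
            + (f"   (pruned at alpha={self.pruned_at})" if self.pruned_at else ""),
            f"  loglike = {self.loglike:.3f}   params = {self.n_params}"
            f"   converged = {self.converged}",
            f"  chi2({fi.df}) = {fi.chi2:.2f}, p = {fi.p_value:.3f}",
            f"  CFI = {fi.cfi:.3f}   RMSEA = {fi.rmsea:.3f} "
            f"(90% CI {fi.rmsea_ci[0]:.3f}-{fi.rmsea_ci[1]:.3f})",
            f"  AIC = {fi.aic:.2f}   BIC = {fi.bic:.2f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, layout: str = "spring"):
        """Draw the pruned network with edge width proportional to |weight|."""
        import matplotlib.pyplot as plt

        gr = nx.Graph()
        gr.add_nodes_from(self.model.variables)
        for _, row in self.edge_list().iterrows():
            if row["retained"] and row["weight"] != 0:
                gr.add_edge(row["node_i"], row["node_j"], weight=row["weight"])
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        pos = nx.spring_layout(gr, seed=0) if layout == "spring" \
            else nx.circular_layout(gr)
        weights = [abs(gr[u][v]["weight"]) * 10 for u, v in gr.edges]
        colors = ["tab:blue" if gr[u][v]["weight"] > 0 else "tab:red"
                  for u, v in gr.edges]
        nx.draw_networkx(gr, pos=pos, ax=ax, width=weights, edge_color=colors,
                         node_color="lightgray", font_size=8)
        ax.set_axis_off()
        return ax


# ---------------------------------------------------------------------------
# Community detection
# ---------------------------------------------------------------------------


@dataclass
class Partition:
    """Modal community partition over spin-glass replications."""

    labels: Dict[str, int]
    frequency: float
    n_reps: int
    counts: Dict[Tuple[int, ...], int] = field(default_factory=dict)

    def as_sets(self) -> List[set]:
        out: Dict[int, set] = {}
        for v, c in self.labels.items():
            out.setdefault(c, set()).add(v)
        return [out[k] for k in sorted(out)]


def _canonical(membership: Sequence[int]) -> Tuple[int, ...]:
    remap: Dict[int, int] = {}
    out = []
    for x in membership:
        if x not in remap:
            remap[x] = len(remap)
        out.append(remap[x])
    return tuple(out)


def _spinglass_quality(omega: np.ndarray, membership: Sequence[int],
                       gamma: float, lambda_neg: float = 1.0) -> float:
    """Negative-weight spin-glass quality (higher is better).

    Positive and negative edge layers get separate configuration null
    models (Traag–Bruggeman): Q = sum over within-community pairs of
    (w+ - gamma * s+_i s+_j / 2m+) - (w- - lambda * s-_i s-_j / 2m-).
    """
    wp = np.clip(omega, 0.0, None)
    wn = np.clip(-omega, 0.0, None)
    sp, sn = wp.sum(axis=1), wn.sum(axis=1)
    m2p, m2n = sp.sum(), sn.sum()
    memb = np.asarray(membership)
    same = memb[:, None] == memb[None, :]
    np.fill_diagonal(same, False)
    q = wp[same].sum()
    if m2p > 0:
        q -= gamma * (np.outer(sp, sp)[same]).sum() / m2p
    q -= wn[same].sum()
    if m2n > 0:
        q += lambda_neg * (np.outer(sn, sn)[same]).sum() / m2n
    return 0.5 * q


def _greedy_refine(omega: np.ndarray, membership: List[int],
                   gamma: float) -> List[int]:
    """Deterministic single-node-move polish to a local quality optimum.

    The annealer occasionally returns a near-optimal partition even on
    trivially separable graphs; hill-climbing on the same objective makes
    each replication land on a local optimum without touching the
    stochastic search itself.
    """
    memb = list(membership)
    p = len(memb)
    improved = True
    while improved:
        improved = False
        for v in range(p):
            current = memb[v]
            best_q = _spinglass_quality(omega, memb, gamma)
            best_c = current
            candidates = set(memb) | {max(memb) + 1}
            for c in sorted(candidates):
                if c == current:
                    continue
                memb[v] = c
                q = _spinglass_quality(omega, memb, gamma)
                if q > best_q + 1e-12:
                    best_q, best_c = q, c
            memb[v] = best_c
            if best_c != current:
                improved = True
    return memb


def _spinglass_once(omega: np.ndarray, variables: Sequence[str], seed: int,
                    gamma: float, spins: int) -> List[int]:
    p = len(variables)
    membership = [0] * p
    g = igraph.Graph.Weighted_Adjacency(omega.tolist(), mode="undirected",
                                        attr="weight")
    rng = _pyrandom.Random(int(seed))
    igraph.set_random_number_generator(rng)
    next_label = 0
    for comp in g.connected_components():
        if len(comp) == 1:
            membership[comp[0]] = next_label
            next_label += 1
            continue
        if len(comp) == 2:
            # a single edge: positive weight binds the pair into one
            # community, a negative weight splits it (ground states of the
            # two-spin Hamiltonian; the annealer is skipped)
            w = g[comp[0], comp[1]]
            membership[comp[0]] = next_label
            membership[comp[1]] = next_label if w > 0 else next_label + 1
            next_label += 1 if w > 0 else 2
            continue
        sub = g.subgraph(comp)
        has_neg = any(w < 0 for w in sub.es["weight"])
        part = sub.community_spinglass(
            weights="weight", spins=min(spins, len(comp)), gamma=gamma,
            implementation="negative" if has_neg else "original",
            # slower annealing schedule than igraph's default: reliability on
            # small graphs matters more here than per-replication speed
            start_temp=1.0, stop_temp=0.005, cool_fact=0.995,
        )
        refined = _greedy_refine(omega[np.ix_(comp, comp)],
                                 list(part.membership), gamma)
        for local, node in enumerate(comp):
            membership[node] = next_label + refined[local]
        next_label += max(refined) + 1
    return membership


def spinglass_communities(
    results: "GGMResults",
    n_reps: int = 1000,
    rng: Optional[np.random.Generator] = None,
    gamma: float = 1.0,
    spins: int = 10,
    group: Optional[str] = None,
) -> Partition:
    """Replicated spin-glass community detection on the pruned network.

    The spin-glass objective (with the negative-weight extension when needed)
    is minimised by simulated annealing ``n_reps`` times with distinct seeds;
    partitions are canonicalised up to label permutation and the modal
    partition is returned with its selection frequency.  Disconnected
    components are detected separately; isolated nodes form their own
    communities.
    """
    rng = rng or np.random.default_rng(0)
    g = group or results.model.group_labels[0]
    omega = results._omega[g] * results.mask
    variables = results.model.variables
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_reps)
    counts: Dict[Tuple[int, ...], int] = {}
    for s in seeds:
        memb = _canonical(_spinglass_once(omega, variables, int(s), gamma, spins))
        counts[memb] = counts.get(memb, 0) + 1
    modal, freq = max(counts.items(), key=lambda kv: kv[1])
    return Partition(
        labels=dict(zip(variables, modal)),
        frequency=freq / n_reps,
        n_reps=n_reps,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Bootstrap, centrality, concurrent validity
# ---------------------------------------------------------------------------


def bootstrap_edges(
    data: pd.DataFrame,
    n_boot: int = 2500,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    refit: bool = False,
    missing: str = "fiml",
) -> pd.DataFrame:
    """Case-resampling bootstrap of the saturated-then-pruned pipeline.

    Each resample refits the saturated network and re-applies the pruning
    decision; reported per edge are the 95% percentile CI of the saturated
    edge weight and the inclusion frequency (how often pruning retained the
    edge).  With ``refit=True`` the recorded weights come from the pruned
    re-estimate instead (slower; retained-edge weights shift only slightly
    at typical sample sizes, and pruned edges become exact zeros, which
    makes the percentile CI degenerate for weak edges).
    """
    rng = rng or np.random.default_rng(0)
    n = len(data)
    variables = list(data.columns)
    p = len(variables)
    iu = np.triu_indices(p, 1)
    weights = np.empty((n_boot, iu[0].size))
    included = np.zeros(iu[0].size)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx].reset_index(drop=True)
        model = GaussianGraphicalModel(sample, missing=missing)
        sat = model.fit()
        pruned = sat.prune_and_refit(alpha=alpha, refit=refit)
        om = (pruned if refit else sat)._omega[model.group_labels[0]]
        weights[b] = om[iu]
        included += pruned.mask[iu]
    lo = np.percentile(weights, 2.5, axis=0)
    hi = np.percentile(weights, 97.5, axis=0)
    return pd.DataFrame({
        "node_i": [variables[i] for i in iu[0]],
        "node_j": [variables[j] for j in iu[1]],
        "mean_weight": weights.mean(axis=0),
        "ci_low": lo,
        "ci_high": hi,
        "inclusion_frequency": included / n_boot,
    })


def centrality(results: "GGMResults", group: Optional[str] = None) -> pd.DataFrame:
    """Node centralities of the pruned network.

    Strength is the sum of absolute edge weights; expected influence the
    signed sum; closeness and betweenness are computed on the weighted graph
    with distance 1/|weight|.
    """
    g = group or results.model.group_labels[0]
    om = results._omega[g] * results.mask
    v = results.model.variables
    strength = np.abs(om).sum(axis=1)
    ei = om.sum(axis=1)
    gr = nx.Graph()
    gr.add_nodes_from(v)
    for i in range(len(v)):
        for j in range(i + 1, len(v)):
            if om[i, j] != 0:
                gr.add_edge(v[i], v[j], distance=1.0 / abs(om[i, j]))
    close = nx.closeness_centrality(gr, distance="distance")
    betw = nx.betweenness_centrality(gr, weight="distance", normalized=False)
    return pd.DataFrame({
        "strength": pd.Series(strength, index=v),
        "expected_influence": pd.Series(ei, index=v),
        "closeness": pd.Series(close),
        "betweenness": pd.Series(betw),
    })


def effect_size_label(r: float) -> str:
    """Correlation-size label: small 0.10, moderate 0.30, large 0.50."""
    a = abs(r)
    if a >= 0.50:
        return "large"
    if a >= 0.30:
        return "moderate"
    if a >= 0.10:
        return "small"
    return "negligible"


def concurrent_correlations(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    pairing: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between two task batteries.

    ``pairing`` maps columns of ``table_a`` to columns of ``table_b``
    (identity on shared columns by default).  Returns r, n, two-sided p and
    the small/moderate/large label per pair; at least 3 complete pairs are
    required per task pair.
    """
    if pairing is None:
        pairing = {c: c for c in table_a.columns if c in table_b.columns}
    rows = []
    for a_col, b_col in pairing.items():
        joined = pd.concat(
            [table_a[a_col].rename("a"), table_b[b_col].rename("b")], axis=1
        ).dropna()
        n = len(joined)
        if n < 3:
            raise ValueError(f"pair ({a_col}, {b_col}) has fewer than 3 complete pairs")
        r, p = stats.pearsonr(joined["a"], joined["b"])
        rows.append({"task_a": a_col, "task_b": b_col, "r": float(r),
                     "n": n, "p": float(p), "label": effect_size_label(r)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Multigroup invariance
# ---------------------------------------------------------------------------


@dataclass
class InvarianceResults:
    """Ladder of equality-constrained multigroup network fits."""

    fits: Dict[str, "GGMResults"]
    table: pd.DataFrame
    preferred_by_lrt: str
    preferred_by_aic: str
    preferred_by_bic: str
    full_constraint_lrt: Dict[str, float]

    def summary(self) -> str:
        lines = ["Multigroup network invariance ladder", self.table.to_string()]
        lines.append(f"preferred by LRT: {self.preferred_by_lrt}; "
                     f"by AIC: {self.preferred_by_aic}; "
                     f"by BIC: {self.preferred_by_bic}")
        return "\n".join(lines)


LADDER = ("unconstrained", "equal_edges", "equal_edges_means",
          "equal_edges_means_scalings")


def invariance_ladder(
    data: pd.DataFrame,
    groups: pd.Series,
    mask: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    missing: str = "fiml",
) -> InvarianceResults:
    """Fit the four-model invariance ladder and compare adjacent models.

    Models: unconstrained (same sparsity pattern, free parameters per
    group); equal edge weights; + equal means; + equal scalings.  Adjacent
    models are compared by chi-square likelihood-ratio tests with df equal
    to the difference in free parameters, and all models by AIC/BIC.  When
    ``mask`` is None the sparsity pattern is derived by pruning the pooled
    (single-group) saturated network at ``alpha``.
    """
    if mask is None:
        pooled = GaussianGraphicalModel(data, missing=missing)
        mask = pooled.fit().prune_and_refit(alpha=alpha, refit=False).mask
    model = GaussianGraphicalModel(data, groups=groups, missing=missing)
    constraints = {
        "unconstrained": {},
        "equal_edges": {"equal_edges": True},
        "equal_edges_means": {"equal_edges": True, "equal_means": True},
        "equal_edges_means_scalings": {"equal_edges": True, "equal_means": True,
                                       "equal_scalings": True},
    }
    fits: Dict[str, GGMResults] = {}
    rows = []
    prev = None
    for name in LADDER:
        res = model.fit(mask=mask, **constraints[name])
        fits[name] = res
        fi = res.fit_indices()
        row = {"model": name, "chi2": fi.chi2, "df": fi.df, "p": fi.p_value,
               "cfi": fi.cfi, "rmsea": fi.rmsea, "aic": fi.aic, "bic": fi.bic,
               "n_params": res.n_params}
        if prev is not None:
            d_chi2 = max(2.0 * (fits[prev].loglike - res.loglike), 0.0)
            d_df = fits[prev].n_params - res.n_params
            row["delta_chi2"] = d_chi2
            row["delta_df"] = d_df
            row["delta_p"] = float(stats.chi2.sf(d_chi2, d_df)) if d_df > 0 else 1.0
        else:
            row["delta_chi2"] = np.nan
            row["delta_df"] = np.nan
            row["delta_p"] = np.nan
        rows.append(row)
        prev = name
    table = pd.DataFrame(rows).set_index("model")

    preferred_lrt = LADDER[0]
    for name in LADDER[1:]:
        if table.loc[name, "delta_p"] > alpha:
            preferred_lrt = name
        else:
            break
    preferred_aic = str(table["aic"].idxmin())
    preferred_bic = str(table["bic"].idxmin())

    full = fits[LADDER[-1]]
    base = fits[LADDER[0]]
    d_chi2 = max(2.0 * (base.loglike - full.loglike), 0.0)
    d_df = base.n_params - full.n_params
    full_lrt = {"delta_chi2": float(d_chi2), "delta_df": int(d_df),
                "p": float(stats.chi2.sf(d_chi2, d_df)) if d_df > 0 else 1.0}

    return InvarianceResults(
        fits=fits, table=table,
        preferred_by_lrt=preferred_lrt,
        preferred_by_aic=preferred_aic,
        preferred_by_bic=preferred_bic,
        full_constraint_lrt=full_lrt,
    )
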