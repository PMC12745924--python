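"""Cormack-Jolly-Seber survival estimation with time-varying covariates.

Open-population capture-recapture, conditioned on each animal's first
capture, separating apparent monthly survival ``phi_t`` from detection
``p_t``.  Both are logit-linear in monthly covariates (maximum temperature,
precipitation, mean SVL of captures), which are z-scored before fitting for
optimiser stability.  The full additive model set crosses every covariate
subset on ``phi`` with every subset on ``p`` (2^3 x 2^3 = 64 models, the
intercept always present) and is ranked by AIC.

The likelihood handles the unobserved fate after the last capture with the
standard chi recursion::

    chi_T = 1
    chi_t = (1 - phi_t) + phi_t (1 - p_{t+1}) chi_{t+1}

Because covariates vary over time but not among individuals, per-occasion
survival/detection series are shared across animals and each likelihood
evaluation is O(n_occasions + n_detections).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from sklearn.base import BaseEstimator

COVARIATES = ("tmax", "precip", "mean_svl")

__all__ = [
    "CJSModelSpec",
    "CJSModel",
    "cjs_loglik",
    "enumerate_models",
    "fit_all_and_select",
    "monthly_survival_series",
]


@dataclass(frozen=True)
class CJSModelSpec:
    """One additive model: covariate subsets entering phi and p."""

    phi_terms: tuple = ()
    p_terms: tuple = ()

    def __post_init__(self):
        for terms in (self.phi_terms, self.p_terms):
            bad = set(terms) - set(COVARIATES)
            if bad:
                raise ValueError(f"unknown covariates {sorted(bad)}")

    @property
    def n_params(self):
        return 2 + len(self.phi_terms) + len(self.p_terms)

    def label(self):
        phi = "+".join(("1",) + self.phi_terms)
        p = "+".join(("1",) + self.p_terms)
        return f"phi({phi}) p({p})"


def enumerate_models():
    """All 64 additive models: 2^3 phi-subsets x 2^3 p-subsets, fixed order."""
    subsets = []
    for r in range(len(COVARIATES) + 1):
        subsets.extend(itertools.combinations(COVARIATES, r))
    return [
        CJSModelSpec(phi_terms=phi, p_terms=p)
        for phi in subsets
        for p in subsets
    ]


def _design(covariates: pd.DataFrame, terms):
    """Intercept + selected z-scored covariate columns, one row per occasion."""
    X = [np.ones(len(covariates))]
    for t in terms:
        X.append(covariates[t].to_numpy(dtype=float))
    return np.column_stack(X)


def standardize_covariates(covariates: pd.DataFrame):
    """z-score the covariate columns; returns (frame, means, sds)."""
    out = covariates.copy()
    means, sds = {}, {}
    for c in COVARIATES:
        if c in out.columns:
            v = out[c].to_numpy(dtype=float)
            means[c] = float(v.mean())
            sds[c] = float(v.std()) or 1.0
            out[c] = (v - means[c]) / sds[c]
    return out, means, sds


def _history_stats(histories):
    H = np.asarray(histories, dtype=int)
    if H.ndim != 2:
        raise ValueError("histories must be a 2-D 0/1 matrix")
    if not H.any(axis=1).all():
        raise ValueError("every history must contain at least one capture")
    f = H.argmax(axis=1)
    last = H.shape[1] - 1 - H[:, ::-1].argmax(axis=1)
    return H, f, last


def _loglik_core(beta_phi, beta_p, Xphi, Xp, H, f, last):
    """CJS log-likelihood given per-occasion design matrices.

    ``phi_t`` is survival from occasion t to t+1 (covariates of occasion t);
    ``p_t`` is detection at occasion t.
    """
    T = H.shape[1]
    tiny = 1e-300
    phi = np.clip(expit(Xphi @ beta_phi)[: T - 1], tiny, 1.0 - 1e-16)
    p = np.clip(expit(Xp @ beta_p), tiny, 1.0 - 1e-16)

    with np.errstate(divide="ignore"):
        logphi = np.log(phi)
        logp = np.log(p)
        log1mp = np.log1p(-p)
    # chi_t: Pr(never seen after t | alive at t)
    chi = np.ones(T)
    for t in range(T - 2, -1, -1):
        chi[t] = (1.0 - phi[t]) + phi[t] * (1.0 - p[t + 1]) * chi[t + 1]

    cum_logphi = np.concatenate([[0.0], np.cumsum(logphi)])
    cum_log1mp = np.concatenate([[0.0], np.cumsum(log1mp)])

    n = H.shape[0]
    rows, cols = np.nonzero(H)
    seen_after_first = cols > f[rows]
    det_term = float(np.sum((logp - log1mp)[cols[seen_after_first]]))

    ll = (
        float(np.sum(cum_logphi[last] - cum_logphi[f]))
        + float(np.sum(cum_log1mp[last + 1] - cum_log1mp[f + 1]))
        + det_term
        + float(np.sum(np.log(chi[last])))
    )
    if not np.isfinite(ll):
        return -np.inf
    return ll


def cjs_loglik(histories, covariates: pd.DataFrame, spec: CJSModelSpec, beta):
    """CJS log-likelihood for one parameter vector.

    ``beta`` concatenates the phi coefficients (intercept first, then
    ``spec.phi_terms``) and the p coefficients likewise.
    """
    H, f, last = _history_stats(histories)
    if len(covariates) < H.shape[1]:
        raise ValueError("covariates must cover every occasion")
    n_phi = 1 + len(spec.phi_terms)
    beta = np.asarray(beta, dtype=float)
    Xphi = _design(covariates, spec.phi_terms)
    Xp = _design(covariates, spec.p_terms)
    return _loglik_core(beta[:n_phi], beta[n_phi:], Xphi, Xp, H, f, last)


class CJSModel(BaseEstimator):
    """Maximum-likelihood CJS fit for one model specification.

    Parameters
    ----------
    spec : CJSModelSpec
        Covariate subsets on phi and p.
    standardize : bool
        z-score covariates before fitting (recommended); the scaling is
        stored so the fitted model can be applied to new covariate values on
        the original scale.
    n_starts : int
        Extra random optimiser starts beyond the zero start.

    Attributes
    ----------
    beta_phi_, beta_p_ : ndarray
        Logit-scale coefficients (intercept first), on the standardized scale.
    loglik_, aic_ : float
    converged_ : bool
    """

    def __init__(self, spec=CJSModelSpec(), standardize=True, n_starts=0, seed=0):
        self.spec = spec
        self.standardize = standardize
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, histories, covariates: pd.DataFrame, y=None):
        H, f, last = _history_stats(histories)
        if H.shape[1] < 3:
            raise ValueError("need at least 3 occasions")
        cov = pd.DataFrame(covariates)
        if self.standardize:
            cov, self.cov_means_, self.cov_sds_ = standardize_covariates(cov)
        else:
            self.cov_means_ = {c: 0.0 for c in COVARIATES if c in cov.columns}
            self.cov_sds_ = {c: 1.0 for c in COVARIATES if c in cov.columns}
        Xphi = _design(cov, self.spec.phi_terms)
        Xp = _design(cov, self.spec.p_terms)
        n_phi = 1 + len(self.spec.phi_terms)
        k = self.spec.n_params

        def nll(beta):
            return -_loglik_core(beta[:n_phi], beta[n_phi:], Xphi, Xp, H, f, last)

        rng = np.random.default_rng(self.seed)
        starts = [np.zeros(k)] + [rng.normal(0, 0.5, k) for _ in range(self.n_starts)]
        best = None
        for x0 in starts:
            res = optimize.minimize(nll, x0, method="L-BFGS-B")
            if best is None or res.fun < best.fun:
                best = res
        self.converged_ = bool(best.success)
        self.beta_phi_ = best.x[:n_phi]
        self.beta_p_ = best.x[n_phi:]
        self.loglik_ = -float(best.fun)
        self.aic_ = -2.0 * self.loglik_ + 2.0 * k
        self.n_params_ = k
        return self

    def _standardized(self, covariates):
        cov = pd.DataFrame(covariates).copy()
        for c in self.cov_means_:
            if c in cov.columns:
                cov[c] = (cov[c] - self.cov_means_[c]) / self.cov_sds_[c]
        return cov

    def predict_phi(self, covariates):
        """Monthly survival probabilities for covariates on the original scale."""
        cov = self._standardized(covariates)
        return expit(_design(cov, self.spec.phi_terms) @ self.beta_phi_)

    def predict_p(self, covariates):
        cov = self._standardized(covariates)
        return expit(_design(cov, self.spec.p_terms) @ self.beta_p_)

    def coef_phi(self):
        """phi coefficients as {\"intercept\": ., covariate: .} (standardized scale)."""
        return {
            name: float(v)
            for name, v in zip(("intercept",) + self.spec.phi_terms, self.beta_phi_)
        }

    def to_dict(self):
        return {
            "phi_terms": list(self.spec.phi_terms),
            "p_terms": list(self.spec.p_terms),
            "beta_phi": [float(b) for b in self.beta_phi_],
            "beta_p": [float(b) for b in self.beta_p_],
            "loglik": self.loglik_,
            "aic": self.aic_,
            "cov_means": self.cov_means_,
            "cov_sds": self.cov_sds_,
        }

    @classmethod
    def from_dict(cls, d):
        m = cls(CJSModelSpec(tuple(d["phi_terms"]), tuple(d["p_terms"])))
        m.beta_phi_ = np.asarray(d["beta_phi"], dtype=float)
        m.beta_p_ = np.asarray(d["beta_p"], dtype=float)
        m.loglik_ = d["loglik"]
        m.aic_ = d["aic"]
        m.n_params_ = m.spec.n_params
        m.cov_means_ = d["cov_means"]
        m.cov_sds_ = d["cov_sds"]
        m.converged_ = True
        return m


def fit_all_and_select(histories, covariates, n_starts=0, seed=0):
    """Fit all 64 candidate models, rank by AIC, return (table, best fit).

    Ties in AIC are broken toward fewer parameters.  Models whose optimiser
    did not converge are flagged in the table, never dropped.
    """
    rows, fits = [], []
    for spec in enumerate_models():
        m = CJSModel(spec, n_starts=n_starts, seed=seed).fit(histories, covariates)
        fits.append(m)
        rows.append(
            {
                "model": spec.label(),
                "phi_terms": "+".join(spec.phi_terms) or "1",
                "p_terms": "+".join(spec.p_terms) or "1",
                "n_params": m.n_params_,
                "loglik": m.loglik_,
                "aic": m.aic_,
                "converged": m.converged_,
            }
        )
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    w = np.exp(-0.5 * table["delta_aic"])
    table["aic_weight"] = w / w.sum()
    order = np.lexsort((table["n_params"].to_numpy(), table["aic"].to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    best = fits[int(order[0])]
    return table, best


def monthly_survival_series(fit: CJSModel, covariates):
    """Estimated survival probability phi_t for every month of ``covariates``."""
    return fit.predict_phi(covariates)
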