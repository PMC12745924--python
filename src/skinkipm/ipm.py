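"""Monthly integral projection models and eigenvalue demography.

The population is structured by snout-vent length x on [L, U] mm.  The
continuous kernel ``K(y, x) = P(y, x) + F(y, x)`` is discretised by the
midpoint rule on 50 equal cells (about 1 mm resolution):

* ``P`` (survival-growth): ``P[j, i] = G[j | i] * S(x_i)`` where ``G`` is the
  monthly von Bertalanffy growth transition and ``S`` the monthly survival
  probability, combining the size-dependent (Gompertz, via the age-length
  map) and environment-dependent (CJS) survival models on the logit scale;
* ``F`` (fecundity): mature females (SVL >= 54 mm) recruit offspring into a
  discretised Gaussian neonate size distribution, only during the breeding
  season (September-January), with the annual litter divided evenly across
  the window and a 0.5 female sex ratio.

Yearly dynamics are the chronological product of 12 monthly kernels; the
asymptotic growth rate lambda is its dominant eigenvalue, with stable size
structure w, reproductive values v, net reproductive rate R0 and generation
time derived from the same machinery, plus kernel- and vital-rate-level
perturbation (sensitivity/elasticity) analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .gompertz import survival_by_size

__all__ = [
    "make_mesh",
    "IPMKernel",
    "LambdaResult",
    "build_P",
    "build_F",
    "combine_survival",
    "assemble_month",
    "yearly_matrix",
    "lambda_eigen",
    "perturbation_analysis",
    "monthly_lambda_series",
]

MESH_POINTS = 50
SVL_LOWER = 30.0
SVL_UPPER = 85.0
DEFAULT_BREEDING = (9, 10, 11, 12, 1)


def make_mesh(n=MESH_POINTS, lower=SVL_LOWER, upper=SVL_UPPER):
    """Midpoint-rule mesh: returns (midpoints, cell width)."""
    h = (upper - lower) / n
    return lower + h * (np.arange(n) + 0.5), h


@dataclass
class IPMKernel:
    """One month x one location: mesh, sub-kernels and their ingredients."""

    mesh: np.ndarray
    h: float
    P: np.ndarray
    F: np.ndarray
    month: int
    env: dict = field(default_factory=dict)
    S: np.ndarray | None = None  # survival vector used in P
    G: np.ndarray | None = None  # growth transition used in P

    @property
    def K(self):
        return self.P + self.F


@dataclass
class LambdaResult:
    """Dominant-eigenvalue summary of a projection matrix."""

    lam: float
    w: np.ndarray
    v: np.ndarray
    R0: float | None = None
    T_gen: float | None = None


def build_P(mesh, survival, G):
    """Survival-growth sub-kernel ``P[j, i] = G[j, i] * S(x_i)``.

    ``survival`` may be a callable of SVL or a precomputed vector; columns of
    ``G`` must each sum to one so that column i of P sums to exactly S(x_i).
    """
    mesh = np.asarray(mesh, dtype=float)
    S = survival(mesh) if callable(survival) else np.asarray(survival, dtype=float)
    if np.any(S < 0) or np.any(S > 1):
        raise ValueError("survival must map sizes into [0, 1]")
    return G * S[None, :]


def build_F(
    mesh,
    month,
    litter_mean,
    maturity_svl=54.0,
    breeding_months=DEFAULT_BREEDING,
    neonate_mu=35.0,
    neonate_sd=1.5,
    sex_ratio=0.5,
):
    """Fecundity sub-kernel for one calendar month.

    Zero outside the breeding window.  Inside it, every mature female (SVL at
    or above ``maturity_svl``) contributes
    ``litter_mean * sex_ratio / len(breeding_months)`` female recruits,
    distributed over sizes by a discretised Gaussian neonate distribution
    (renormalised to sum to one over the mesh).
    """
    mesh = np.asarray(mesh, dtype=float)
    n = mesh.size
    if not (mesh.min() <= maturity_svl <= mesh.max()):
        raise ValueError("maturity threshold must lie within the mesh")
    if month not in breeding_months:
        return np.zeros((n, n))
    phi = stats.norm.pdf(mesh, loc=neonate_mu, scale=neonate_sd)
    h = mesh[1] - mesh[0]
    mass_inside = phi.sum() * h  # fraction of neonate mass the mesh captures
    if mass_inside < 0.99:
        raise ValueError(
            f"neonate size distribution loses {1 - mass_inside:.1%} of its mass "
            "outside the mesh; widen the size bounds"
        )
    phi = phi / phi.sum()
    mature = (mesh >= maturity_svl).astype(float)
    per_month = litter_mean * sex_ratio / len(breeding_months)
    return per_month * phi[:, None] * mature[None, :]


def combine_survival(svl, env_row, gompertz_fit, cjs_fit, growth_fit):
    """Monthly survival combining size-dependent and environment-dependent parts.

    On the logit scale the CJS environmental deviation from the mean
    environment is added to the size-specific (Gompertz) survival::

        logit S(x, e) = logit S_size(x) + [logit phi_cjs(e) - logit phi_cjs(mean e)]

    so that under the average environment S reduces exactly to the
    size-dependent survival.  ``env_row`` is a mapping with the covariates on
    their original scale.
    """
    import pandas as pd

    s_size = np.atleast_1d(survival_by_size(svl, gompertz_fit, growth_fit, clamp_warn=False))
    row = pd.DataFrame([dict(env_row)])
    mean_row = pd.DataFrame([{c: cjs_fit.cov_means_[c] for c in cjs_fit.cov_means_}])
    dev = float(
        logit(cjs_fit.predict_phi(row))[0] - logit(cjs_fit.predict_phi(mean_row))[0]
    )
    s = expit(logit(np.clip(s_size, 1e-12, 1 - 1e-12)) + dev)
    return s if s.size > 1 else float(s[0])


def assemble_month(
    mesh,
    month,
    env_row,
    growth_fit,
    gompertz_fit,
    cjs_fit,
    litter_mean,
    maturity_svl=54.0,
    breeding_months=DEFAULT_BREEDING,
    neonate_mu=35.0,
    neonate_sd=1.5,
    sex_ratio=0.5,
    G=None,
):
    """Assemble the full kernel ``K = P + F`` for one month.

    ``G`` may be passed in to avoid recomputing the (environment-independent)
    growth transition for every month.
    """
    from .growth import growth_transition

    mesh = np.asarray(mesh, dtype=float)
    if G is None:
        G = growth_transition(mesh, growth_fit)
    S = combine_survival(mesh, env_row, gompertz_fit, cjs_fit, growth_fit)
    P = build_P(mesh, np.atleast_1d(S), G)
    F = build_F(
        mesh,
        month,
        litter_mean,
        maturity_svl=maturity_svl,
        breeding_months=breeding_months,
        neonate_mu=neonate_mu,
        neonate_sd=neonate_sd,
        sex_ratio=sex_ratio,
    )
    h = mesh[1] - mesh[0]
    return IPMKernel(mesh=mesh, h=h, P=P, F=F, month=month, env=dict(env_row), S=np.atleast_1d(S), G=G)


def yearly_matrix(kernels):
    """Chronological product ``A = K_12 ... K_2 K_1`` of 12 monthly kernels.

    ``A @ n_t`` equals stepping ``n_t`` through the 12 months in order.
    """
    if len(kernels) != 12:
        raise ValueError(f"a year needs exactly 12 monthly kernels, got {len(kernels)}")
    mats = [k.K if hasattr(k, "K") else np.asarray(k) for k in kernels]
    A = np.eye(mats[0].shape[0])
    for K in mats:
        A = K @ A
    return A


def _power_iteration(A, tol=1e-10, max_iter=100_000):
    """Perron root and eigenvector of a nonnegative matrix.

    A positive diagonal shift makes the iteration converge even for periodic
    (imprimitive) nonzero patterns; the shift is subtracted back out exactly.
    """
    n = A.shape[0]
    shift = 0.05 * float(np.abs(A).sum(axis=0).max()) + 1e-12
    B = A + shift * np.eye(n)
    w = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(max_iter):
        w_new = B @ w
        lam_new = np.linalg.norm(w_new, 1)
        if lam_new == 0:
            raise ValueError("matrix annihilates the positive cone; no dominant eigenvalue")
        w_new = w_new / lam_new
        if abs(lam_new - lam) < tol * max(lam_new, 1.0) and np.max(np.abs(w_new - w)) < tol:
            return lam_new - shift, w_new
        lam, w = lam_new, w_new
    return lam - shift, w


def _check_primitive(A):
    """Irreducibility check on the nonzero pattern (boolean reachability)."""
    n = A.shape[0]
    R = (A > 0) | np.eye(n, dtype=bool)
    steps = int(np.ceil(np.log2(max(n, 2))))
    for _ in range(steps):
        R = R.astype(np.int64) @ R.astype(np.int64) > 0
    if not R.all():
        rows = np.nonzero(~R.all(axis=1))[0]
        raise ValueError(
            f"projection matrix is reducible (rows {rows[:5].tolist()} cannot reach "
            "all states); lambda analysis requires a primitive matrix"
        )


def lambda_eigen(A, tol=1e-10, mean_P=None, mean_F=None, months_per_step=12.0):
    """Dominant-eigenvalue analysis of a nonnegative projection matrix.

    Power iteration gives lambda and the stable structure ``w``; iterating the
    transpose gives reproductive values ``v``.  If the mean monthly
    sub-kernels are supplied, the net reproductive rate
    ``R0 = rho(F (I - P)^-1)`` and generation time
    ``T = ln R0 / ln lambda`` (converted to months) are also reported; at
    lambda = 1 the generation time is undefined and returned as NaN.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("projection matrix must be nonnegative")
    _check_primitive(A)
    lam, w = _power_iteration(A, tol)
    _, v = _power_iteration(A.T, tol)
    w = w / w.sum()
    v = v / (v @ w)

    R0 = T = None
    if mean_P is not None and mean_F is not None:
        N = np.linalg.inv(np.eye(A.shape[0]) - mean_P)  # fundamental matrix
        R0, _ = _power_iteration(mean_F @ N, tol)
        if abs(lam - 1.0) < 1e-12 or R0 <= 0:
            T = float("nan")
        else:
            T = math.log(R0) / math.log(lam) * months_per_step
    return LambdaResult(lam=float(lam), w=w, v=v, R0=R0, T_gen=T)


def perturbation_analysis(kernels, rel=1e-3, growth_fit=None):
    """Sensitivity and elasticity of yearly lambda, at kernel and vital-rate level.

    Kernel-level: ``s(j, i) = v_j w_i / <v, w>`` on the yearly matrix and
    ``e = (A / lambda) * s`` (elasticities sum to one).  Vital-rate level:
    symmetric multiplicative perturbation (default +/-0.1%) of the survival
    probabilities, the fecundity sub-kernel, and — when ``growth_fit`` is
    given — the growth coefficient ``k`` (the growth transition is rebuilt,
    since rescaling a column-normalised transition is a no-op), recomputing
    lambda from the rebuilt yearly product each time.
    """
    from .growth import growth_transition, GrowthFit

    A = yearly_matrix(kernels)
    res = lambda_eigen(A)
    v, w, lam = res.v, res.w, res.lam
    sens = np.outer(v, w) / float(v @ w)
    elas = (A / lam) * sens

    def lam_scaled(which, factor):
        mats = []
        G_scaled = None
        if which == "growth":
            f = GrowthFit(
                linf=growth_fit.linf_,
                k=growth_fit.k_ * factor,
                sigma=growth_fit.sigma_,
                birth_svl=getattr(growth_fit, "birth_svl", 35.0),
            )
            G_scaled = growth_transition(kernels[0].mesh, f)
        for k in kernels:
            P, F = k.P, k.F
            if which == "survival":
                P = P * factor
            elif which == "growth":
                P = G_scaled * k.S[None, :]
            mats.append(P + F)
        return lambda_eigen(yearly_matrix([_Mat(m) for m in mats])).lam

    which_rates = ["survival", "fecundity"] + (["growth"] if growth_fit else [])

    def lam_fec(factor):
        return lambda_eigen(
            yearly_matrix([_Mat(k.P + k.F * factor) for k in kernels])
        ).lam

    vital = {}
    for which in which_rates:
        fn = lam_fec if which == "fecundity" else (lambda f, w=which: lam_scaled(w, f))
        vital[which] = (fn(1.0 + rel) - fn(1.0 - rel)) / (2.0 * rel * lam)
    return {
        "lambda": lam,
        "sensitivity": sens,
        "elasticity": elas,
        "vital_rate_elasticity": vital,
    }


class _Mat:
    """Adapter so plain matrices can flow through yearly_matrix."""

    def __init__(self, K):
        self.K = K


def monthly_lambda_series(kernels):
    """Per-month dominant eigenvalue and its geometric mean over the series.

    Each month's lambda is the dominant eigenvalue of that single monthly
    kernel (kernels outside the breeding season have lambda < 1, breeding
    months > 1).  Returns ``(lambdas, geometric_mean)``.
    """
    lams = []
    for k in kernels:
        K = k.K if hasattr(k, "K") else np.asarray(k)
        lam, _ = _power_iteration(K)
        lams.append(lam)
    lams = np.asarray(lams)
    return lams, float(np.exp(np.mean(np.log(lams))))
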