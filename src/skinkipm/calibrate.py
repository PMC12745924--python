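"""Truth-side IPM construction and stationarity calibration.

Given the generator's ground-truth parameters, these helpers assemble the
*true* monthly kernels (no estimation involved) and solve for the litter
size that makes the population exactly stationary (geometric-mean monthly
lambda = 1) under a given environmental series.  Recovery tests and the
end-to-end stationary run use this to fix the study conditions; the fitted
pipeline is then expected to reproduce lambda near 1 from data alone.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from . import ipm as ipm_mod
from .gompertz import monthly_survival_at_age
from .growth import GrowthFit, growth_transition
from .synthetic import TruthParams, _zscore

__all__ = [
    "effective_litter_mean",
    "truth_monthly_kernels",
    "truth_lambda_geometric_mean",
    "calibrate_litter_for_stationarity",
]


def effective_litter_mean(litter_mean, cap=8):
    """E[min(Y, cap)] for Y ~ Poisson(litter_mean) truncated at >= 1.

    The generator truncates litters at one offspring and caps them at eight,
    so the realised mean litter differs slightly from the Poisson rate.
    """
    ys = np.arange(1, cap)
    pmf = stats.poisson.pmf(ys, litter_mean) / -np.expm1(-litter_mean)
    tail = max(0.0, 1.0 - pmf.sum())
    return float(pmf @ ys + tail * cap)


def _truth_growth(params: TruthParams):
    from .growth import process_growth_sd

    # transition spread induced by individual k variation over one month
    sigma = process_growth_sd(params.Linf_f, params.k_sd)
    return GrowthFit(
        linf=params.Linf_f,
        k=params.k_mean,
        k_sd=params.k_sd,
        sigma=sigma,
        birth_svl=params.birth_svl_mean,
    )


def _truth_size_survival(params: TruthParams, mesh):
    age = (
        np.log(
            (params.Linf_f - params.birth_svl_mean)
            / (params.Linf_f - np.minimum(mesh, params.Linf_f - 1e-6))
        )
        / params.k_mean
    )
    age = np.maximum(age, 0.0)
    return monthly_survival_at_age(age, params.gompertz_b0, params.gompertz_b1)


def truth_monthly_kernels(params: TruthParams, env, litter_mean=None, mesh_points=50):
    """True monthly kernels over an environmental series.

    Survival combines the Gompertz size baseline with the generator's
    logit-additive environmental effect (z-scored covariates, exactly the
    simulator's convention).  ``litter_mean`` defaults to the capped
    truncated-Poisson mean implied by the truth parameter.
    """
    mesh, h = ipm_mod.make_mesh(mesh_points)
    G = growth_transition(mesh, _truth_growth(params))
    s_size = np.clip(_truth_size_survival(params, mesh), 1e-12, 1 - 1e-12)
    ls = logit(s_size)

    tmax_z = _zscore(env["tmax"].to_numpy(dtype=float))
    precip_z = _zscore(env["precip"].to_numpy(dtype=float))
    bphi = np.asarray(params.beta_phi, dtype=float)
    litter = (
        effective_litter_mean(params.litter_mean) if litter_mean is None else litter_mean
    )

    kernels = []
    for m in range(len(env)):
        dev = bphi[0] + bphi[1] * tmax_z[m] + bphi[2] * precip_z[m]
        S = expit(ls + dev)
        P = G * S[None, :]
        F = ipm_mod.build_F(
            mesh,
            int(env["calendar_month"].iloc[m]),
            litter,
            maturity_svl=params.maturity_svl,
            breeding_months=tuple(params.breeding_months),
            neonate_mu=params.birth_svl_mean,
            neonate_sd=params.birth_svl_sd,
        )
        kernels.append(
            ipm_mod.IPMKernel(
                mesh=mesh,
                h=h,
                P=P,
                F=F,
                month=int(env["calendar_month"].iloc[m]),
                S=S,
                G=G,
            )
        )
    return kernels


def truth_lambda_geometric_mean(params: TruthParams, env, litter_mean=None):
    """Geometric mean of true monthly lambdas over the series."""
    kernels = truth_monthly_kernels(params, env, litter_mean=litter_mean)
    _, gm = ipm_mod.monthly_lambda_series(kernels)
    return gm


def calibrate_litter_for_stationarity(params: TruthParams, env, bracket=(0.5, 40.0)):
    """Litter-size rate that makes the true population exactly stationary.

    Solves ``geometric mean monthly lambda = 1`` for the generator's
    ``litter_mean`` (accounting for truncation and the cap of eight) and
    returns the calibrated :class:`TruthParams`.
    """

    # kernels are affine in the litter size: K_m = P_m + litter * F_m(unit),
    # so build the ingredients once and re-solve only the eigenvalues
    base = truth_monthly_kernels(params, env, litter_mean=1.0)
    log_lam_P = np.array(
        [
            0.0 if k.F.any() else np.log(ipm_mod._power_iteration(k.P)[0])
            for k in base
        ]
    )
    breeding = [k for k in base if k.F.any()]
    n = len(base)

    def f(litter_param):
        eff = effective_litter_mean(litter_param)
        tot = float(log_lam_P.sum())
        for k in breeding:
            tot += np.log(ipm_mod._power_iteration(k.P + eff * k.F)[0])
        return tot / n  # log geometric-mean monthly lambda

    lo, hi = bracket
    if f(lo) > 0:
        raise ValueError("population grows even at the minimal litter size")
    if f(hi) < 0:
        raise ValueError("population declines even at the maximal litter size")
    root = optimize.brentq(f, lo, hi, xtol=1e-6)
    return params.with_(litter_mean=float(root))
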