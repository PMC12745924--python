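"""Synthetic mark-recapture, fecundity and climate data with known truth.

Every pipeline input can be generated here with ground-truth parameters, so
each downstream estimator is testable by parameter recovery without any
external download.  The generative model mirrors the biology of a small
viviparous Neotropical skink monitored by monthly pitfall trapping:

* individuals grow deterministically along a von Bertalanffy curve from a
  Gaussian neonate size, with individual variation in the growth
  coefficient ``k`` (truncated positive);
* mortality follows a Gompertz hazard in age, modulated additively on the
  logit of monthly survival by environmental covariates (the same
  convention the survival combiner in the IPM uses);
* parturition is restricted to a breeding window (September-January by
  default), matching a single annual litter whose size is capped at eight;
* detection is imperfect and monthly, logit-linear in the environment;
* the climate is a seasonal sinusoid plus linear trend plus noise, with a
  wet season spanning October-May.

The time step is one calendar month throughout; ages are in months.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .gompertz import monthly_survival_at_age

__all__ = [
    "TruthParams",
    "simulate_environment",
    "simulate_population",
    "simulate_gravid_females",
    "simulate_climate_rasters",
    "inject_missing_svl",
]

DEFAULT_BREEDING_MONTHS = frozenset({9, 10, 11, 12, 1})


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth generative parameters (monthly time step, mm sizes).

    Defaults describe the study population: female asymptote 79 mm, male
    71 mm, neonates near 35 mm, maturity from 54 mm, one litter per year in
    the September-January window, moderate senescence, and an adverse effect
    of maximum temperature on survival.
    """

    Linf_f: float = 79.0
    Linf_m: float = 71.0
    k_mean: float = 0.094
    k_sd: float = 0.012
    birth_svl_mean: float = 35.0
    birth_svl_sd: float = 1.5
    gompertz_b0: float = -3.5
    gompertz_b1: float = 0.02
    beta_phi: tuple = (0.0, -0.5, 0.0, 0.0)  # intercept, tmax, precip, mean_svl
    beta_p: tuple = (-1.7, 0.0, 0.0, 0.0)
    litter_mean: float = 4.0
    breeding_months: frozenset = DEFAULT_BREEDING_MONTHS
    maturity_svl: float = 54.0
    svl_obs_sd: float = 0.5
    sex_unknown_frac: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if not (self.Linf_f > self.birth_svl_mean > 0):
            raise ValueError("need Linf_f > birth_svl_mean > 0")
        if not (self.Linf_m > self.birth_svl_mean):
            raise ValueError("need Linf_m > birth_svl_mean")
        if self.k_mean <= 0:
            raise ValueError("k_mean must be positive")
        if self.gompertz_b1 < 0:
            raise ValueError("gompertz_b1 must be non-negative")
        if self.litter_mean <= 0:
            raise ValueError("litter_mean must be positive")
        if not set(self.breeding_months) <= set(range(1, 13)):
            raise ValueError("breeding_months must be calendar months 1..12")

    def with_(self, **kw):
        return replace(self, **kw)


def _calendar_months(n_months, start_month=1):
    return ((start_month - 1 + np.arange(n_months)) % 12) + 1


def simulate_environment(
    n_months,
    seasonal_amp=3.0,
    trend=0.0,
    noise_sd=0.8,
    seed=0,
    tmax_base=28.0,
    precip_amp=150.0,
    precip_base=90.0,
    start_month=1,
):
    """Monthly maximum-temperature and precipitation series.

    ``tmax`` = base + seasonal sinusoid (period 12, peaking in September at
    the end of the dry season) + linear trend (degrees C per decade) +
    Gaussian noise.  ``precip`` is a truncated sinusoid whose wet season spans
    October-May (peak mid-January), clipped at zero, with multiplicative
    noise.

    Returns a DataFrame with columns month (1-based index), calendar_month,
    tmax, precip.
    """
    if n_months < 24:
        raise ValueError("need at least 24 months (seasonal structure undefined)")
    rng = np.random.default_rng(seed)
    t = np.arange(n_months, dtype=float)
    cal = _calendar_months(n_months, start_month)
    tmax = (
        tmax_base
        + seasonal_amp * np.cos(2.0 * np.pi * (cal - 9) / 12.0)
        + trend / 120.0 * t
        + rng.normal(0.0, noise_sd, n_months)
    )
    precip = np.clip(
        precip_amp * np.cos(2.0 * np.pi * (cal - 1.5) / 12.0) + precip_base, 0.0, None
    )
    if noise_sd > 0:
        precip = precip * np.exp(rng.normal(0.0, 0.15, n_months))
    return pd.DataFrame(
        {
            "month": np.arange(1, n_months + 1),
            "calendar_month": cal,
            "tmax": tmax,
            "precip": precip,
        }
    )


def _zscore(v):
    s = v.std()
    return (v - v.mean()) / (s if s > 0 else 1.0)


def simulate_population(
    params: TruthParams,
    n_individuals,
    n_months,
    env: pd.DataFrame,
    burn_in_months=24,
):
    """Individual-based simulation of the monitored population.

    Births occur only in breeding-window months (including a pre-study
    burn-in so the standing population has mixed ages); each individual grows
    deterministically with its own ``k``; monthly death follows the Gompertz
    hazard modulated on the logit-survival scale by the environmental
    coefficients; detection is an independent monthly Bernoulli for months
    the animal is alive within the study window.

    Returns ``(captures, truth)``: the capture table (one row per detection)
    and the latent truth table (birth/death months, individual k, sex).
    """
    if len(env) < n_months:
        raise ValueError("environment series must cover n_months")
    rng = np.random.default_rng(params.seed)
    cal = env["calendar_month"].to_numpy()
    tmax_z = _zscore(env["tmax"].to_numpy(dtype=float))
    precip_z = _zscore(env["precip"].to_numpy(dtype=float))

    # candidate birth months: breeding-window months from -burn_in to end
    all_months = np.arange(-burn_in_months, n_months)
    all_cal = (all_months + cal[0] - 1) % 12 + 1
    birth_pool = all_months[np.isin(all_cal, list(params.breeding_months))]
    if birth_pool.size == 0:
        raise ValueError("no breeding months inside the simulated window")

    birth_month = rng.choice(birth_pool, size=n_individuals)
    sexes = rng.choice(["F", "M"], size=n_individuals)
    unknown = rng.random(n_individuals) < params.sex_unknown_frac
    k_i = params.k_mean + params.k_sd * rng.standard_normal(n_individuals)
    while np.any(k_i <= 0):  # truncated-positive individual growth coefficients
        bad = k_i <= 0
        k_i[bad] = params.k_mean + params.k_sd * rng.standard_normal(bad.sum())
    birth_svl = rng.normal(params.birth_svl_mean, params.birth_svl_sd, n_individuals)
    linf = np.where(sexes == "F", params.Linf_f, params.Linf_m)
    birth_svl = np.minimum(birth_svl, linf - 5.0)

    bphi = np.asarray(params.beta_phi, dtype=float)
    bp = np.asarray(params.beta_p, dtype=float)

    cap_rows = []
    death_month = np.full(n_individuals, 10**9)
    # covariate vector per month: intercept, z-scored tmax and precip; the
    # mean-SVL slot is held at 0 (population-structure feedback not simulated)
    for i in range(n_individuals):
        m = int(birth_month[i])
        alive = True
        while alive and m < n_months:
            age = m - birth_month[i]
            if m >= 0:
                svl = linf[i] - (linf[i] - birth_svl[i]) * np.exp(-k_i[i] * age)
                x = np.array([1.0, tmax_z[m], precip_z[m], 0.0])
                p_det = expit(bp @ x)
                if rng.random() < p_det:
                    svl_obs = svl + (
                        rng.normal(0.0, params.svl_obs_sd)
                        if params.svl_obs_sd > 0
                        else 0.0
                    )
                    cap_rows.append((i, m + 1, svl_obs, svl))
                s_base = monthly_survival_at_age(
                    float(age), params.gompertz_b0, params.gompertz_b1
                )
                logit_s = np.log(s_base / (1.0 - s_base)) + bphi @ x
                s = expit(logit_s)
            else:
                s = monthly_survival_at_age(
                    float(age), params.gompertz_b0, params.gompertz_b1
                )
            if rng.random() >= s:
                alive = False
                death_month[i] = m + 1
            m += 1

    truth = pd.DataFrame(
        {
            "id": np.arange(n_individuals),
            "sex": sexes,
            "birth_month": birth_month + 1,
            "death_month": np.where(death_month > n_months, np.nan, death_month),
            "k": k_i,
            "birth_svl": birth_svl,
        }
    )

    if cap_rows:
        ids, sessions, svl_obs, svl_true = map(np.array, zip(*cap_rows))
    else:
        ids = sessions = svl_obs = svl_true = np.array([])
    sex_col = np.where(unknown[ids.astype(int)], "U", sexes[ids.astype(int)])
    mass = 2.5e-5 * svl_true**2.9 * np.exp(rng.normal(0.0, 0.08, ids.size))
    tail_intact = rng.random(ids.size) < 0.8
    tail = 1.3 * svl_true * np.where(tail_intact, 1.0, 0.6) + rng.normal(
        0.0, 2.0, ids.size
    )
    captures = pd.DataFrame(
        {
            "id": ids.astype(int),
            "session": sessions.astype(int),
            "sex": sex_col,
            "svl": svl_obs,
            "mass": mass,
            "tail_len": tail,
            "tail_intact": tail_intact.astype(int),
        }
    ).sort_values(["session", "id"], kind="stable").reset_index(drop=True)
    return captures, truth


def simulate_gravid_females(params: TruthParams, n, seed=0, svl_slope=0.05):
    """Gravid-female table: SVL (>= maturity) and embryo count.

    Embryos ~ Poisson(exp(a + b * svl_centered)) truncated at >= 1 and capped
    at the biological maximum of eight, where ``exp(a)`` is the truth litter
    mean at the average reproductive size.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = params.maturity_svl, params.Linf_f - 2.0
    svl = rng.uniform(lo, hi, n)
    mu = params.litter_mean * np.exp(svl_slope * (svl - svl.mean()))
    emb = rng.poisson(mu)
    while np.any(emb < 1):  # truncation at one offspring
        bad = emb < 1
        emb[bad] = rng.poisson(mu[bad])
    emb = np.minimum(emb, 8)
    return pd.DataFrame({"svl": svl, "embryos": emb})


def inject_missing_svl(table: pd.DataFrame, fraction, seed=0):
    """Blank exactly ``round(fraction * n)`` SVL entries (mass/tail retained)."""
    if not 0 <= fraction < 0.1:
        raise ValueError("fraction must be in [0, 0.1)")
    out = table.copy()
    n_blank = int(round(fraction * len(out)))
    if n_blank == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(out), size=n_blank, replace=False)
    out.iloc[idx, out.columns.get_loc("svl")] = np.nan
    return out


def simulate_climate_rasters(
    nx,
    ny,
    n_months,
    gradient=0.0,
    seed=0,
    start_month=1,
    **env_kwargs,
):
    """Pixel-wise monthly climate grids with a deterministic tmax gradient.

    Every pixel carries the scalar :func:`simulate_environment` series; a
    west-to-east linear gradient (degrees C per cell along x) is added to
    tmax so that projected lambda maps have a known spatial ordering.

    Returns ``(tmax_cube, precip_cube, env)`` where the cubes have shape
    (n_months, ny, nx) and ``env`` is the gradient-free scalar series.
    """
    if nx < 2 or ny < 2:
        raise ValueError("grid must be at least 2 x 2")
    env = simulate_environment(n_months, seed=seed, start_month=start_month, **env_kwargs)
    tmax = np.broadcast_to(
        env["tmax"].to_numpy(dtype=float)[:, None, None], (n_months, ny, nx)
    ).copy()
    precip = np.broadcast_to(
        env["precip"].to_numpy(dtype=float)[:, None, None], (n_months, ny, nx)
    ).copy()
    tmax += gradient * np.arange(nx)[None, None, :]
    return tmax, precip, env
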