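"""End-to-end orchestration: simulate/ingest, fit, project, report.

A single YAML-able configuration drives the whole pipeline:
preprocessing -> growth -> age-dependent survival -> environment-dependent
survival -> fecundity -> monthly IPMs (lambda series, perturbation) ->
time-series decomposition -> optional spatial projection.  Every stage's
randomness is drawn from named substreams of one root seed, every artifact is
written to the output directory, and a JSON manifest records stages, seeds
and file hashes so that reruns are bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import ipm as ipm_mod
from .calibrate import calibrate_litter_for_stationarity
from .cjs import fit_all_and_select, monthly_survival_series
from .decompose import decompose, variance_shares
from .fecundity import LitterSizeModel
from .gompertz import GompertzSurvivalModel
from .growth import FabensGrowthModel, growth_transition
from .preprocess import build_recapture_intervals, impute_svl, monthly_covariates
from .synthetic import (
    TruthParams,
    inject_missing_svl,
    simulate_climate_rasters,
    simulate_environment,
    simulate_gravid_females,
    simulate_population,
)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "build_histories"]

STAGES = (
    "simulate",
    "preprocess",
    "growth",
    "survival_gompertz",
    "survival_cjs",
    "fecundity",
    "ipm",
    "decompose",
    "spatial",
)

DEFAULT_CONFIG = {
    "seed": 1,
    "output_dir": "skinkipm_out",
    "synthetic": {
        "n_individuals": 800,
        "n_months": 120,
        "gravid_n": 30,
        "missing_svl_fraction": 0.01,
        "calibrate_stationary": True,
        "env": {"seasonal_amp": 3.0, "trend": 0.0, "noise_sd": 0.8},
        "truth": {},
    },
    "mesh": {"points": 50, "lower": 30.0, "upper": 85.0},
    "maturity_svl": 54.0,
    "breeding_months": [9, 10, 11, 12, 1],
    "neonate": {"mu": 35.0, "sd": 1.5},
    "sex_ratio": 0.5,
    "mcmc": {
        "gompertz": {"n_walkers": 24, "n_steps": 2500, "n_burn": 1000, "thin": 5},
        "litter": {"n_walkers": 20, "n_steps": 3500, "n_burn": 1500, "thin": 5},
    },
    "spatial": None,
}

_KNOWN_KEYS = set(DEFAULT_CONFIG) | {"notes"}


def _merge(base, override):
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config):
    """Schema and cross-field checks; returns {'valid', 'violations', 'warnings'}."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    violations, warnings = [], []
    for k in config or {}:
        if k not in _KNOWN_KEYS:
            warnings.append(f"unknown config key: {k!r}")
    mesh = cfg["mesh"]
    if not (0 < mesh["lower"] < mesh["upper"]):
        violations.append("mesh bounds must satisfy 0 < lower < upper")
    if mesh["points"] < 2:
        violations.append("mesh needs at least 2 points")
    if not (mesh["lower"] <= cfg["maturity_svl"] <= mesh["upper"]):
        violations.append(
            f"maturity SVL {cfg['maturity_svl']} outside mesh "
            f"[{mesh['lower']}, {mesh['upper']}]"
        )
    bad = [m for m in cfg["breeding_months"] if m not in range(1, 13)]
    if bad:
        violations.append(f"breeding months must be calendar months 1..12, got {bad}")
    if not (mesh["lower"] <= cfg["neonate"]["mu"] <= mesh["upper"]):
        violations.append("neonate mean size outside the mesh")
    syn = cfg.get("synthetic") or {}
    if syn and syn.get("n_months", 24) < 24:
        violations.append("synthetic n_months must be >= 24")
    return {"valid": not violations, "violations": violations, "warnings": warnings}


def _stage_seeds(root_seed):
    children = np.random.SeedSequence(root_seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(STAGES, children)
    }


def build_histories(captures: pd.DataFrame, n_months, subset=None):
    """Pivot a capture table into a 0/1 detection matrix (ids as row index)."""
    tab = captures if subset is None else captures[subset]
    ids = np.sort(tab["id"].unique())
    idx = {v: i for i, v in enumerate(ids)}
    H = np.zeros((len(ids), n_months), dtype=int)
    H[[idx[i] for i in tab["id"]], tab["session"].to_numpy() - 1] = 1
    return H, ids


def _sha256(path: Path):
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config=None, progress=None):
    """Run the full pipeline from a config dict; returns the manifest dict.

    Raises with the failing stage's name; artifacts of completed stages are
    already persisted when that happens.
    """
    report = validate_config(config)
    if not report["valid"]:
        raise ValueError(f"invalid config: {report['violations']}")
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])
    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "stage_seeds": seeds,
        "config": cfg,
        "stages": [],
        "artifacts": {},
        "results": {},
    }

    def save_df(df, name):
        p = out / name
        df.to_csv(p, index=False)
        manifest["artifacts"][name] = _sha256(p)

    def save_json(obj, name):
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
        manifest["artifacts"][name] = _sha256(p)

    def done(stage):
        manifest["stages"].append(stage)
        if progress:
            progress(stage)

    stage = "simulate"
    try:
        syn = cfg["synthetic"]
        truth = TruthParams(seed=seeds["simulate"], **syn.get("truth", {}))
        env = simulate_environment(
            syn["n_months"], seed=seeds["simulate"], **syn.get("env", {})
        )
        if syn.get("calibrate_stationary"):
            truth = calibrate_litter_for_stationarity(truth, env)
        captures, latent = simulate_population(
            truth, syn["n_individuals"], syn["n_months"], env
        )
        gravid = simulate_gravid_females(
            truth, syn["gravid_n"], seed=seeds["simulate"] + 1, svl_slope=0.0
        )
        captures = inject_missing_svl(
            captures, syn["missing_svl_fraction"], seed=seeds["simulate"] + 2
        )
        save_df(captures, "captures.csv")
        save_df(gravid, "gravid.csv")
        save_df(env, "environment.csv")
        save_json({"litter_mean": truth.litter_mean}, "truth_summary.json")
        done(stage)

        stage = "preprocess"
        captures, imp_report = impute_svl(captures, seed=seeds["preprocess"])
        intervals, int_report = build_recapture_intervals(captures)
        cov = monthly_covariates(captures, env)
        save_df(intervals, "recapture_intervals.csv")
        save_df(cov, "monthly_covariates.csv")
        save_json({**imp_report, **int_report}, "preprocess_report.json")
        done(stage)

        stage = "growth"
        growth_fits = {}
        for sex in ("F", "M"):
            sub = intervals[(intervals["sex"] == sex) & ~intervals["linf_violation"]]
            growth_fits[sex] = FabensGrowthModel(
                birth_svl=cfg["neonate"]["mu"]
            ).fit(sub)
        save_json({s: m.to_dict() for s, m in growth_fits.items()}, "growth_fit.json")
        done(stage)

        stage = "survival_gompertz"
        mc = cfg["mcmc"]["gompertz"]
        gomp_fits = {}
        for sex in ("F", "M"):
            sel = captures["sex"] == sex
            H, ids = build_histories(captures, syn["n_months"], subset=sel)
            first = captures[sel].groupby("id")["session"].idxmin()
            first_rows = captures.loc[first].set_index("id")
            svl0 = first_rows.loc[ids, "svl"].to_numpy(dtype=float)
            g = growth_fits[sex]
            svl0 = np.clip(svl0, cfg["neonate"]["mu"] + 0.1, g.linf_ - 0.5)
            ages0 = g.age_of(svl0)
            gomp_fits[sex] = GompertzSurvivalModel(
                seed=seeds["survival_gompertz"], **mc
            ).fit(H, ages0)
        save_json({s: m.to_dict() for s, m in gomp_fits.items()}, "gompertz_fit.json")
        done(stage)

        stage = "survival_cjs"
        H_all, _ = build_histories(captures, syn["n_months"])
        aic_table, best = fit_all_and_select(H_all, cov)
        phi_series = monthly_survival_series(best, cov)
        save_df(aic_table, "cjs_aic_table.csv")
        save_json(best.to_dict(), "cjs_best_model.json")
        save_df(
            pd.DataFrame({"month": cov["month"], "phi": phi_series}),
            "monthly_survival.csv",
        )
        done(stage)

        stage = "fecundity"
        litter = LitterSizeModel(seed=seeds["fecundity"], **cfg["mcmc"]["litter"]).fit(
            gravid
        )
        save_json(litter.to_dict(), "fecundity_fit.json")
        done(stage)

        stage = "ipm"
        mesh, h = ipm_mod.make_mesh(
            cfg["mesh"]["points"], cfg["mesh"]["lower"], cfg["mesh"]["upper"]
        )
        gf = growth_fits["F"]
        # projection kernels use the process growth spread (individual k
        # heterogeneity), not the raw Fabens residual SD, which also carries
        # measurement error
        from .growth import GrowthFit, process_growth_sd

        gk = GrowthFit(
            linf=gf.linf_,
            k=gf.k_,
            k_sd=gf.k_sd_,
            sigma=process_growth_sd(gf.linf_, gf.k_sd_),
            birth_svl=gf.birth_svl,
        )
        G = growth_transition(mesh, gk)
        kernels = []
        for _, row in cov.iterrows():
            kernels.append(
                ipm_mod.assemble_month(
                    mesh,
                    int(row["calendar_month"]),
                    {c: row[c] for c in ("tmax", "precip", "mean_svl")},
                    gk,
                    gomp_fits["F"],
                    best,
                    litter.mean_litter_,
                    maturity_svl=cfg["maturity_svl"],
                    breeding_months=tuple(cfg["breeding_months"]),
                    neonate_mu=cfg["neonate"]["mu"],
                    neonate_sd=cfg["neonate"]["sd"],
                    sex_ratio=cfg["sex_ratio"],
                    G=G,
                )
            )
        lambdas, geo_mean = ipm_mod.monthly_lambda_series(kernels)
        n_years = syn["n_months"] // 12
        yearly = []
        for y in range(n_years):
            A = ipm_mod.yearly_matrix(kernels[12 * y : 12 * (y + 1)])
            mean_P = np.mean([k.P for k in kernels[12 * y : 12 * (y + 1)]], axis=0)
            mean_F = np.mean([k.F for k in kernels[12 * y : 12 * (y + 1)]], axis=0)
            res = ipm_mod.lambda_eigen(A, mean_P=mean_P, mean_F=mean_F)
            yearly.append({"year": y + 1, "lambda": res.lam, "R0": res.R0,
                           "T_gen_months": res.T_gen})
        perturb = ipm_mod.perturbation_analysis(kernels[:12], growth_fit=gk)
        save_df(pd.DataFrame({"month": cov["month"], "lambda": lambdas}),
                "monthly_lambda.csv")
        save_df(pd.DataFrame(yearly), "yearly_lambda.csv")
        save_json(
            {
                "lambda_geometric_mean": geo_mean,
                "vital_rate_elasticity": perturb["vital_rate_elasticity"],
                "generation_time_months": float(
                    np.nanmean([r["T_gen_months"] for r in yearly])
                ),
            },
            "ipm_summary.json",
        )
        manifest["results"]["lambda_geometric_mean"] = geo_mean
        done(stage)

        stage = "decompose"
        dec_phi = decompose(phi_series)
        dec_lam = decompose(lambdas)
        save_json(
            {
                "survival_shares": variance_shares(dec_phi),
                "lambda_shares": variance_shares(dec_lam),
            },
            "decomposition.json",
        )
        done(stage)

        stage = "spatial"
        if cfg.get("spatial"):
            from .spatial import project_lambda

            sp = cfg["spatial"]
            tmax, precip, _ = simulate_climate_rasters(
                sp.get("nx", 6),
                sp.get("ny", 6),
                12 * sp.get("n_years", 3),
                gradient=sp.get("gradient", 0.3),
                seed=seeds["spatial"],
            )
            years = list(range(sp.get("n_years", 3)))
            field = project_lambda(
                tmax,
                precip,
                gk,
                gomp_fits["F"],
                best,
                litter.mean_litter_,
                years,
                scenario=sp.get("scenario", "synthetic"),
                periods={"all": (years[0], years[-1])},
            )
            np.savetxt(out / "lambda_mean_map.csv", field.period_mean["all"],
                       delimiter=",")
            manifest["artifacts"]["lambda_mean_map.csv"] = _sha256(
                out / "lambda_mean_map.csv"
            )
        done(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
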