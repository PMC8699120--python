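"""Pipeline driver: generate -> NCA -> fit -> bootstrap -> pcVPC -> simulate.

Each stage is an importable function writing delimited-text artifacts into
a run directory; :func:`run_pipeline` chains them and records a manifest
(seed, configuration, config hash, package version, per-stage status)
sufficient to re-run any stage reproducibly.  A stage failure halts the
stages downstream of it; artifacts already written are preserved.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .data import PKDataset, read_dataset, write_dataset
from .foce import FitOptions, FOCEResult, PopModel, fit_foce
from .model import PKParams
from .nca import nca_table, urine_summary
from .renal import anchor_regression, correlate_markers, fit_cr_cl_regression, monte_carlo_exposure
from .simulate import (
    MarkerModel,
    RenalEffectModel,
    StudyDesign,
    default_pop_model,
    generate_study,
)
from .validate import bootstrap, pcvpc

__all__ = [
    "run_pipeline",
    "stage_generate",
    "stage_nca",
    "stage_fit",
    "stage_bootstrap",
    "stage_vpc",
    "stage_simulate",
]


def _truth_pop(cfg: AnalysisConfig) -> PopModel:
    pop = default_pop_model()
    theta = pop.theta
    if cfg.truth_theta is not None:
        theta = PKParams(*cfg.truth_theta)
    omega2 = pop.omega2
    if cfg.truth_iiv_pct is not None:
        omega2 = tuple((p / 100.0) ** 2 for p in cfg.truth_iiv_pct)
    sigma = pop.sigma if cfg.truth_sigma_pct is None else cfg.truth_sigma_pct / 100.0
    return PopModel(theta=theta, omega2=omega2, sigma=sigma)


def stage_generate(cfg: AnalysisConfig, outdir: Path) -> PKDataset:
    design = StudyDesign(n_per_arm=cfg.n_per_arm, doses=tuple(cfg.doses))
    pop = _truth_pop(cfg)
    renal = RenalEffectModel() if cfg.renal_effect else None
    data, truth = generate_study(
        design, pop, MarkerModel(), renal, seed=cfg.seed, return_truth=True
    )
    write_dataset(data, outdir / "dataset.csv")
    truth.to_csv(outdir / "truth.csv", index=False)
    return data


def stage_nca(data: PKDataset, cfg: AnalysisConfig, outdir: Path) -> pd.DataFrame:
    tab = nca_table(data, n_terminal=cfg.n_terminal)
    tab.to_csv(outdir / "nca.csv", index=False)
    urine = urine_summary(data)
    urine.to_csv(outdir / "urine_summary.csv", index=False)

    # marker-PK correlations on the arm with urine data (the 8 mg/kg arms)
    cov = data.covariates()
    merged = tab.set_index("ID").join(cov)
    high = merged[merged["DOSEGRP"] == cfg.sim_dose]
    if len(high) >= 3:
        urine_map = urine.set_index("ID")["ae_ug"] if len(urine) else None
        ae = urine_map.reindex(high.index).to_numpy() if urine_map is not None else None
        corr = correlate_markers(
            high["cl_tot"].to_numpy(), high[["BUN", "CR", "CCR"]], ae
        )
        corr.to_csv(outdir / "marker_correlations.csv")
    return tab


def stage_fit(data: PKDataset, cfg: AnalysisConfig, outdir: Path) -> FOCEResult:
    fit = fit_foce(data, options=FitOptions(se_method=cfg.se_method))
    params = fit.parameter_table()
    params.to_csv(outdir / "fit_params.csv", index=False)
    with open(outdir / "fit_report.txt", "w") as fh:
        fh.write("Population pharmacokinetic parameter estimates (FOCE-ELS)\n\n")
        fh.write(params.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        fh.write(f"\n\n-2LL: {fit.minus2ll:.3f}\n")
        fh.write(f"converged: {fit.converged} ({fit.n_iter} outer iterations)\n")
        fh.write(f"observations: {fit.n_obs} (excluded below LLOQ: {fit.n_blq_excluded})\n")
    fit.eta_hat.to_csv(outdir / "ebe.csv", index=False)
    fit.gof.to_csv(outdir / "gof.csv", index=False)
    return fit


def stage_bootstrap(data: PKDataset, fit: FOCEResult, cfg: AnalysisConfig, outdir: Path):
    boot = bootstrap(data, init=fit.pop_hat, n=cfg.bootstrap_n, seed=cfg.seed)
    boot.summary.to_csv(outdir / "bootstrap.csv")
    boot.estimates.to_csv(outdir / "bootstrap_replicates.csv", index=False)
    return boot


def stage_vpc(data: PKDataset, fit: FOCEResult, cfg: AnalysisConfig, outdir: Path):
    vpc = pcvpc(fit, data, n_sim=cfg.vpc_n, seed=cfg.seed)
    vpc.table().to_csv(outdir / "vpc.csv", index=False)
    return vpc


def stage_simulate(data: PKDataset, fit: FOCEResult, cfg: AnalysisConfig, outdir: Path):
    if cfg.use_anchor_regression:
        reg = anchor_regression()
    else:
        cov = data.covariates()
        ebe = fit.eta_hat.set_index("ID")
        cr = cov["CR"].reindex(ebe.index).to_numpy(dtype=float)
        reg = fit_cr_cl_regression(ebe["CL_i"].to_numpy(), cr)
    with open(outdir / "cr_cl_regression.json", "w") as fh:
        json.dump(
            {
                "intercept_L_h_kg": reg.a,
                "slope_L_h_kg_per_mg_dL": reg.b,
                "r2": reg.r2,
                "n": reg.n,
                "cr_range": list(reg.cr_range),
            },
            fh,
            indent=2,
        )
    lo, hi = reg.cr_range
    grid = np.array([c for c in cfg.cr_grid if lo - 1e-9 <= c <= hi + 1e-9])
    grid = np.clip(grid, lo, hi)
    summary = monte_carlo_exposure(
        fit.pop_hat, reg, grid, dose=cfg.sim_dose, n=cfg.mc_n, seed=cfg.seed
    )
    summary.table().to_csv(outdir / "exposure.csv", index=False)
    prof = pd.DataFrame(summary.conc_median, index=summary.cr_levels, columns=summary.times)
    prof.to_csv(outdir / "exposure_profiles_median.csv")
    return summary


_STAGES = ("generate", "nca", "fit", "bootstrap", "vpc", "simulate")


def run_pipeline(cfg: AnalysisConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest: dict = {
        "package": "oxalipk",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "stages": {},
    }

    def _write_manifest() -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    state: dict = {}
    plan = {
        "generate": lambda: state.update(data=stage_generate(cfg, outdir)),
        "nca": lambda: stage_nca(state["data"], cfg, outdir),
        "fit": lambda: state.update(fit=stage_fit(state["data"], cfg, outdir)),
        "bootstrap": lambda: stage_bootstrap(state["data"], state["fit"], cfg, outdir),
        "vpc": lambda: stage_vpc(state["data"], state["fit"], cfg, outdir),
        "simulate": lambda: stage_simulate(state["data"], state["fit"], cfg, outdir),
    }
    for name in _STAGES:
        t0 = time.perf_counter()
        try:
            plan[name]()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": repr(exc)}
            _write_manifest()
            raise
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }
    if cfg.plots:
        from . import plots

        run_fit = state["fit"]
        plots.gof_plots(run_fit, outdir / "gof.png")
    _write_manifest()
    return outdir
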