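"""Model qualification: nonparametric bootstrap and prediction-corrected VPC.

The bootstrap resamples subjects with replacement (stratified by renal
group and dose arm so every replicate keeps the 6-arm design), refits
each replicate and summarises the estimates by median and 2.5th-97.5th
percentiles.  The pcVPC simulates replicate studies from the fitted model
on the original design, normalises observed and simulated values by the
bin-median population prediction (removing dose/covariate heterogeneity)
and overlays observed percentiles on the simulated confidence bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PKDataset
from .foce import FOCEResult, FitOptions, PopModel, _extract_arrays, fit_foce
from .model import PKValidationError, TwoCompartmentIVBolus

__all__ = ["BootstrapResult", "VPCResult", "bootstrap", "pcvpc"]

_BOOT_COLUMNS = [
    "V1",
    "V2",
    "CL",
    "CL2",
    "omega_V1_pct",
    "omega_CL_pct",
    "omega_CL2_pct",
    "sigma_pct",
]


@dataclass
class BootstrapResult:
    n_requested: int
    n_converged: int
    summary: pd.DataFrame = field(repr=False)  # median, p2.5, p97.5 per parameter
    estimates: pd.DataFrame = field(repr=False)  # one row per converged replicate
    seed: int | None = None

    @property
    def failure_fraction(self) -> float:
        return 1.0 - self.n_converged / self.n_requested


def _pop_to_row(pop: PopModel) -> dict:
    iiv = pop.iiv_percent
    return {
        "V1": pop.theta.v1,
        "V2": pop.theta.v2,
        "CL": pop.theta.cl,
        "CL2": pop.theta.cl2,
        "omega_V1_pct": iiv[0],
        "omega_CL_pct": iiv[1],
        "omega_CL2_pct": iiv[2],
        "sigma_pct": pop.sigma_percent,
    }


def bootstrap(
    data: PKDataset,
    init: PopModel,
    n: int = 1000,
    seed: int | None = None,
    stratify: bool = True,
    options: FitOptions | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap of the population-model estimates.

    ``init`` should be the original fit's estimates: replicates start
    there, which speeds convergence (and is the reason replicate fits are
    described as potentially optimistic about convergence rates).
    """
    rng = np.random.default_rng(seed)
    cov = data.covariates()
    ids = cov.index.to_numpy()
    if stratify:
        strata = [
            grp.index.to_numpy()
            for _, grp in cov.groupby(["RENGRP", "DOSEGRP"], sort=True)
        ]
    else:
        strata = [ids]

    if options is None:
        options = FitOptions(compute_se=False)

    rows = []
    n_converged = 0
    for _ in range(n):
        sample = np.concatenate(
            [s[rng.integers(0, len(s), size=len(s))] for s in strata]
        )
        replicate = data.subset(sample, relabel=True)
        try:
            fit = fit_foce(replicate, init=init, options=options)
        except Exception:
            continue
        if not fit.converged:
            continue
        n_converged += 1
        rows.append(_pop_to_row(fit.pop_hat))

    if n_converged == 0:
        raise PKValidationError("no bootstrap replicate converged")
    est = pd.DataFrame(rows, columns=_BOOT_COLUMNS)
    summary = pd.DataFrame(
        {
            "median": est.median(),
            "p2.5": est.quantile(0.025),
            "p97.5": est.quantile(0.975),
        }
    )
    result = BootstrapResult(
        n_requested=n, n_converged=n_converged, summary=summary, estimates=est, seed=seed
    )
    if result.failure_fraction > 0.20:
        warnings.warn(
            f"bootstrap: {result.failure_fraction:.0%} of replicates failed to converge",
            stacklevel=2,
        )
    return result


# ---------------------------------------------------------------------------
# Prediction-corrected visual predictive check
# ---------------------------------------------------------------------------


@dataclass
class VPCResult:
    bins: np.ndarray  # representative time per bin, h
    obs_p5: np.ndarray
    obs_p50: np.ndarray
    obs_p95: np.ndarray
    sim_ci: dict = field(repr=False)  # {"p5"|"p50"|"p95": (lo, hi) arrays}
    n_sim: int = 0
    seed: int | None = None
    merged_bins: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.bins,
                "obs_p5": self.obs_p5,
                "obs_p50": self.obs_p50,
                "obs_p95": self.obs_p95,
                "sim_p5_lo": self.sim_ci["p5"][0],
                "sim_p5_hi": self.sim_ci["p5"][1],
                "sim_p50_lo": self.sim_ci["p50"][0],
                "sim_p50_hi": self.sim_ci["p50"][1],
                "sim_p95_lo": self.sim_ci["p95"][0],
                "sim_p95_hi": self.sim_ci["p95"][1],
            }
        )

    def median_coverage(self) -> int:
        """Number of bins whose observed median lies inside its simulated CI."""
        lo, hi = self.sim_ci["p50"]
        return int(np.sum((self.obs_p50 >= lo) & (self.obs_p50 <= hi)))


def _assign_bins(times: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Bin observations by their (nominal) sampling time; merge bins < 2 obs."""
    uniq = np.unique(times)
    edges = list(uniq)
    idx = np.searchsorted(uniq, times)
    counts = np.bincount(idx, minlength=len(uniq))
    merged = 0
    while len(edges) > 1 and counts.min() < 2:
        k = int(np.argmin(counts))
        j = k - 1 if k > 0 else k + 1
        keep = min(j, k)
        drop = max(j, k)
        idx[idx == drop] = keep
        idx[idx > drop] -= 1
        edges.pop(drop)
        counts = np.bincount(idx, minlength=len(edges))
        merged += 1
    return idx, np.asarray(edges), merged


def pcvpc(
    fit: FOCEResult,
    data: PKDataset,
    n_sim: int = 1000,
    seed: int | None = None,
    model=TwoCompartmentIVBolus,
) -> VPCResult:
    """Prediction-corrected visual predictive check of a fitted model.

    Both observed and simulated values are corrected by
    ``pcY = Y * median(PRED in bin) / PRED``; simulated datasets reuse the
    original design matrix (same subjects, times and doses).
    """
    pop = fit.pop_hat
    arrays = _extract_arrays(data)
    theta = pop.theta.as_array()
    S, T = arrays.t.shape
    mask = arrays.mask.astype(bool)

    pred = model.predict(theta, np.zeros((S, model.n_eta)), arrays.dose, arrays.t)
    t_flat = arrays.t[mask]
    y_flat = arrays.y[mask]
    pred_flat = pred[mask]

    bin_idx, bin_times, merged = _assign_bins(t_flat)
    n_bins = len(bin_times)
    bin_median_pred = np.array(
        [np.median(pred_flat[bin_idx == b]) for b in range(n_bins)]
    )
    correction = bin_median_pred[bin_idx] / pred_flat
    pc_obs = y_flat * correction

    obs_p5 = np.array([np.percentile(pc_obs[bin_idx == b], 5) for b in range(n_bins)])
    obs_p50 = np.array([np.percentile(pc_obs[bin_idx == b], 50) for b in range(n_bins)])
    obs_p95 = np.array([np.percentile(pc_obs[bin_idx == b], 95) for b in range(n_bins)])

    rng = np.random.default_rng(seed)
    omega = np.sqrt(np.asarray(pop.omega2, dtype=float))
    sim_pct = np.empty((n_sim, 3, n_bins))
    for r in range(n_sim):
        eta = rng.standard_normal((S, model.n_eta)) * omega
        f = model.predict(theta, eta, arrays.dose, arrays.t)
        y = f * (1.0 + pop.sigma * rng.standard_normal(f.shape))
        for _ in range(100):  # redraw non-positive simulated concentrations
            bad = y <= 0.0
            if not bad.any():
                break
            y[bad] = f[bad] * (1.0 + pop.sigma * rng.standard_normal(int(bad.sum())))
        pc_sim = y[mask] * correction
        for b in range(n_bins):
            sel = pc_sim[bin_idx == b]
            sim_pct[r, :, b] = np.percentile(sel, [5, 50, 95])

    sim_ci = {}
    for k, name in enumerate(("p5", "p50", "p95")):
        lo = np.percentile(sim_pct[:, k, :], 2.5, axis=0)
        hi = np.percentile(sim_pct[:, k, :], 97.5, axis=0)
        sim_ci[name] = (lo, hi)

    return VPCResult(
        bins=bin_times,
        obs_p5=obs_p5,
        obs_p50=obs_p50,
        obs_p95=obs_p95,
        sim_ci=sim_ci,
        n_sim=n_sim,
        seed=seed,
        merged_bins=merged,
    )
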