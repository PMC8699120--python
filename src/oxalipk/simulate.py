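"""Synthetic study generator.

Emulates the rat study design behind the package: 30 animals in three
renal-function groups (normal, mild, severe — acute kidney injury induced
by 30 or 60 min renal ischemia-reperfusion), IV bolus oxaliplatin at 3 or
8 mg/kg (five rats per dose per group), plasma sampling at 3, 5, 10, 20,
30, 45 min and 1, 1.5, 2 h, and urine collection over 0-4 h in the
8 mg/kg arms.  Biochemical markers (BUN, plasma creatinine, creatinine
clearance) are drawn per group from the observed means and SDs, jointly
through a Gaussian copula so that the marker-clearance correlations are
non-trivial.  Concentrations come from the two-compartment model with
lognormal inter-individual variability and proportional residual error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .data import COLUMNS, PKDataset
from .foce import PopModel
from .model import PKParams, PKValidationError, auc_to_time, predict_conc
from .renal import CrCLRegression, anchor_regression

__all__ = [
    "StudyDesign",
    "MarkerModel",
    "RenalEffectModel",
    "default_pop_model",
    "draw_individual_params",
    "simulate_profile",
    "simulate_urine",
    "generate_markers",
    "generate_study",
]

#: nominal plasma sampling times in hours (3, 5, 10, 20, 30, 45 min, 1, 1.5, 2 h)
PLASMA_TIMES = (3 / 60, 5 / 60, 10 / 60, 20 / 60, 30 / 60, 45 / 60, 1.0, 1.5, 2.0)
URINE_INTERVAL_ENDS = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0)
RENAL_GROUPS = ("normal", "mild", "severe")
REFERENCE_BODY_WEIGHT = 0.3  # kg; converts per-kg doses to absolute urine amounts
DEFAULT_LLOQ = 0.01  # ug/mL


def default_pop_model() -> PopModel:
    """The final-model population parameters used as generator truth.

    Typical values V1 0.44 L/kg, V2 2.26 L/kg, CL 1.76 L/h/kg, CL2
    1.0 L/h/kg; inter-individual variability 37.5 / 30.5 / 31.5 % on
    V1 / CL / CL2; proportional residual SD 14.9 %.
    """
    return PopModel(
        theta=PKParams(v1=0.44, v2=2.26, cl=1.76, cl2=1.0),
        omega2=(0.375**2, 0.305**2, 0.315**2),
        sigma=0.149,
    )


@dataclass(frozen=True)
class StudyDesign:
    """Arms, sampling schedule and size of a generated study."""

    renal_groups: tuple[str, ...] = RENAL_GROUPS
    doses: tuple[float, ...] = (3.0, 8.0)  # mg/kg
    n_per_arm: int = 5
    plasma_times: tuple[float, ...] = PLASMA_TIMES  # h
    urine_interval_ends: tuple[float, ...] = URINE_INTERVAL_ENDS  # h, 8 mg/kg arms only
    urine_dose: float = 8.0  # mg/kg arm that gets urine collection
    lloq: float = DEFAULT_LLOQ  # ug/mL
    body_weight: float = REFERENCE_BODY_WEIGHT  # kg

    def __post_init__(self) -> None:
        pt = np.asarray(self.plasma_times, dtype=float)
        ut = np.asarray(self.urine_interval_ends, dtype=float)
        if np.any(pt <= 0) or np.any(np.diff(pt) <= 0):
            raise PKValidationError("plasma_times must be positive and strictly increasing")
        if len(ut) and (np.any(ut <= 0) or np.any(np.diff(ut) <= 0)):
            raise PKValidationError("urine_interval_ends must be positive and strictly increasing")
        if self.n_per_arm < 1:
            raise PKValidationError("n_per_arm must be >= 1")
        for g in self.renal_groups:
            if g not in RENAL_GROUPS:
                raise PKValidationError(f"unknown renal group {g!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.renal_groups) * len(self.doses) * self.n_per_arm


# Observed group means and SDs of the renal-function markers.
_MARKER_DEFAULTS = {
    #        BUN mg/dL       Cr mg/dL      CCr mL/min/kg
    "normal": ((18.3, 1.4), (0.27, 0.02), (4.2, 1.3)),
    "mild": ((27.9, 12.7), (0.54, 0.21), (2.2, 0.7)),
    "severe": ((62.0, 12.8), (0.95, 0.17), (1.6, 0.7)),
}


@dataclass(frozen=True)
class MarkerModel:
    """Group-wise distributions of BUN, plasma Cr and CCr.

    Marginals are normal truncated at zero.  BUN and CCr are drawn
    conditionally correlated with Cr through a Gaussian copula
    (``copula_r`` with Cr, positive for BUN, negative for CCr;
    conditional independence given Cr fixes the BUN-CCr entry).
    """

    means_sds: dict = field(default_factory=lambda: dict(_MARKER_DEFAULTS))
    copula_r: float = 0.8

    def __post_init__(self) -> None:
        for group, ((_, s1), (cr_m, s2), (_, s3)) in self.means_sds.items():
            if min(s1, s2, s3) < 0:
                raise PKValidationError(f"negative SD in marker model for {group!r}")
        crs = {g: v[1][0] for g, v in self.means_sds.items()}
        if not (crs.get("severe", 1) > crs.get("mild", 0.5) > crs.get("normal", 0.2)):
            raise PKValidationError("Cr means must increase with renal-failure severity")
        if not 0.0 <= self.copula_r < 1.0:
            raise PKValidationError("copula_r must be in [0, 1)")

    def correlation(self) -> np.ndarray:
        r = self.copula_r
        # order (Cr, BUN, CCr); BUN rises and CCr falls with Cr
        return np.array(
            [
                [1.0, r, -r],
                [r, 1.0, -r * r],
                [-r, -r * r, 1.0],
            ]
        )


@dataclass(frozen=True)
class RenalEffectModel:
    """How renal function enters the generator's truth.

    ``cr_to_cl`` maps plasma creatinine to the typical elimination
    clearance (creatinine outside the map's valid range is clipped to it);
    ``fe_normal`` is the fraction of the dose excreted intact in urine by
    4 h for normal renal function, scaled down in the dysfunction groups
    by ``urine_scaling``.
    """

    cr_to_cl: CrCLRegression = field(default_factory=anchor_regression)
    fe_normal: float = 5e-4
    urine_scaling: dict = field(
        default_factory=lambda: {"normal": 1.0, "mild": 0.635, "severe": 0.377}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.fe_normal < 1.0:
            raise PKValidationError("fe_normal must be in (0, 1)")
        for g, s in self.urine_scaling.items():
            if not 0.0 < s <= 1.0:
                raise PKValidationError(f"urine scaling for {g!r} must be in (0, 1]")

    def typical_cl(self, cr: float) -> float:
        lo, hi = self.cr_to_cl.cr_range
        return float(self.cr_to_cl(np.clip(cr, lo, hi)))

    def fe(self, group: str) -> float:
        return self.fe_normal * self.urine_scaling[group]


# ---------------------------------------------------------------------------
# Stochastic components
# ---------------------------------------------------------------------------


def _truncnorm_draw(u: float, mean: float, sd: float) -> float:
    """Inverse-CDF draw from N(mean, sd) truncated at zero, u in (0, 1)."""
    if sd == 0.0:
        return mean
    a = (0.0 - mean) / sd
    return float(scipy.stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd))


def generate_markers(group: str, markers: MarkerModel, rng: np.random.Generator):
    """One joint draw of (BUN, Cr, CCr) for a subject of ``group``."""
    if group not in markers.means_sds:
        raise PKValidationError(f"unknown renal group {group!r}")
    (bun_m, bun_s), (cr_m, cr_s), (ccr_m, ccr_s) = markers.means_sds[group]
    corr = markers.correlation()
    z = rng.multivariate_normal(np.zeros(3), corr, method="cholesky")
    u = scipy.stats.norm.cdf(z)
    cr = _truncnorm_draw(u[0], cr_m, cr_s)
    bun = _truncnorm_draw(u[1], bun_m, bun_s)
    ccr = _truncnorm_draw(u[2], ccr_m, ccr_s)
    return bun, cr, ccr


def draw_individual_params(
    pop: PopModel,
    cr: float | None = None,
    renal_effect: RenalEffectModel | None = None,
    rng: np.random.Generator | None = None,
):
    """Individual parameters ``P_i = theta_P * exp(eta_P)`` and their eta.

    Random effects are independent normals on (V1, CL, CL2); V2 carries
    none.  With an active ``renal_effect`` the typical clearance is
    replaced by ``cr_to_cl(Cr)`` before the random effect applies.
    """
    rng = np.random.default_rng() if rng is None else rng
    omega = np.sqrt(np.asarray(pop.omega2, dtype=float))
    eta = rng.standard_normal(3) * omega
    theta_cl = pop.theta.cl
    if renal_effect is not None:
        if cr is None:
            raise PKValidationError("renal effect requires a creatinine value")
        theta_cl = renal_effect.typical_cl(cr)
    params = PKParams(
        v1=pop.theta.v1 * float(np.exp(eta[0])),
        v2=pop.theta.v2,
        cl=theta_cl * float(np.exp(eta[1])),
        cl2=pop.theta.cl2 * float(np.exp(eta[2])),
    )
    return params, eta


def simulate_profile(
    ind: PKParams,
    dose: float,
    times,
    sigma: float,
    rng: np.random.Generator | None = None,
    lloq: float = DEFAULT_LLOQ,
):
    """Observed concentrations ``y = f(t) * (1 + eps)``, eps ~ N(0, sigma^2).

    Draws yielding non-positive concentrations are redrawn (truncating at
    zero would bias the mean).  Values below ``lloq`` are flagged, not
    dropped.  Returns ``(y, blq)`` arrays.
    """
    if sigma < 0.0:
        raise PKValidationError("sigma must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    times = np.asarray(times, dtype=float)
    f = predict_conc(ind, dose, times)
    if sigma == 0.0:
        y = f.copy()
    else:
        y = f * (1.0 + sigma * rng.standard_normal(times.shape))
        for _ in range(1000):
            bad = y <= 0.0
            if not bad.any():
                break
            y[bad] = f[bad] * (1.0 + sigma * rng.standard_normal(int(bad.sum())))
    blq = y < lloq
    return y, blq


def simulate_urine(
    ind: PKParams,
    dose: float,
    interval_ends,
    fe: float,
    rng: np.random.Generator | None = None,
    body_weight: float = REFERENCE_BODY_WEIGHT,
    noise_cv: float = 0.2 / 1.2,
    horizon: float = 4.0,
):
    """Cumulative urinary amounts (ug) at the interval ends.

    The excreted amount tracks the plasma exposure:
    ``Ae(t) = fe * dose_total * AUC(0,t) / AUC(0, horizon)``, so the
    cumulative amount at the horizon is exactly ``fe * dose_total``.  A
    single mean-one lognormal multiplier (CV ``noise_cv``) perturbs the
    whole curve, preserving monotonicity.
    """
    if not 0.0 <= fe < 1.0:
        raise PKValidationError("fe must be in [0, 1)")
    interval_ends = np.asarray(interval_ends, dtype=float)
    dose_total_ug = dose * body_weight * 1000.0
    if fe == 0.0:
        return np.zeros_like(interval_ends)
    auc_h = float(auc_to_time(ind, dose, horizon))
    ae = fe * dose_total_ug * np.asarray(auc_to_time(ind, dose, interval_ends)) / auc_h
    if noise_cv > 0.0:
        rng = np.random.default_rng() if rng is None else rng
        sdlog = float(np.sqrt(np.log1p(noise_cv**2)))
        ae = ae * float(np.exp(sdlog * rng.standard_normal() - 0.5 * sdlog**2))
    return ae


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------


def generate_study(
    design: StudyDesign | None = None,
    pop: PopModel | None = None,
    markers: MarkerModel | None = None,
    renal_effect: RenalEffectModel | None = None,
    seed: int = 0,
    return_truth: bool = False,
):
    """Generate a complete synthetic study as a validated event table.

    Deterministic for a fixed ``seed``: each subject consumes an
    independent substream keyed by ``(seed, subject_id)``, so regenerating
    any subject alone reproduces its data.  With the default design the
    table holds 30 subjects, 9 plasma observation rows each, plus dose
    rows and urine rows for the 8 mg/kg arms (when a renal effect is
    supplied; without one the urinary fraction of normal function is still
    used for every group).

    Returns the dataset, and with ``return_truth`` also a per-subject
    DataFrame of the true individual parameters and random effects.
    """
    design = design or StudyDesign()
    pop = pop or default_pop_model()
    markers = markers or MarkerModel()

    rows: list[dict] = []
    truth_rows: list[dict] = []
    sid = 0
    for group in design.renal_groups:
        for dose in design.doses:
            for _ in range(design.n_per_arm):
                sid += 1
                rng = np.random.default_rng(np.random.SeedSequence([int(seed), sid]))
                bun, cr, ccr = generate_markers(group, markers, rng)
                ind, eta = draw_individual_params(pop, cr, renal_effect, rng)
                common = {
                    "ID": sid,
                    "DOSEGRP": dose,
                    "RENGRP": group,
                    "CR": cr,
                    "BUN": bun,
                    "CCR": ccr,
                    "WT": design.body_weight,
                }
                rows.append(
                    {
                        **common,
                        "TIME": 0.0,
                        "EVID": 1,
                        "AMT": dose,
                        "DV": np.nan,
                        "MDV": 1,
                        "CMT": "plasma",
                        "BLQ": 0,
                    }
                )
                y, blq = simulate_profile(
                    ind, dose, design.plasma_times, pop.sigma, rng, design.lloq
                )
                for t, yy, bb in zip(design.plasma_times, y, blq):
                    rows.append(
                        {
                            **common,
                            "TIME": float(t),
                            "EVID": 0,
                            "AMT": np.nan,
                            "DV": float(yy),
                            "MDV": 0,
                            "CMT": "plasma",
                            "BLQ": int(bb),
                        }
                    )
                if dose == design.urine_dose and len(design.urine_interval_ends):
                    fe = (
                        renal_effect.fe(group)
                        if renal_effect is not None
                        else RenalEffectModel().fe("normal")
                    )
                    ae = simulate_urine(
                        ind,
                        dose,
                        design.urine_interval_ends,
                        fe,
                        rng,
                        body_weight=design.body_weight,
                    )
                    for t, a in zip(design.urine_interval_ends, ae):
                        rows.append(
                            {
                                **common,
                                "TIME": float(t),
                                "EVID": 0,
                                "AMT": np.nan,
                                "DV": float(a),
                                "MDV": 0,
                                "CMT": "urine",
                                "BLQ": 0,
                            }
                        )
                truth_rows.append(
                    {
                        "ID": sid,
                        "group": group,
                        "dose": dose,
                        "CR": cr,
                        "BUN": bun,
                        "CCR": ccr,
                        "V1_i": ind.v1,
                        "V2_i": ind.v2,
                        "CL_i": ind.cl,
                        "CL2_i": ind.cl2,
                        "CLtot_i": ind.cl_tot,
                        "eta_V1": eta[0],
                        "eta_CL": eta[1],
                        "eta_CL2": eta[2],
                    }
                )

    dataset = PKDataset(pd.DataFrame(rows, columns=COLUMNS))
    if return_truth:
        return dataset, pd.DataFrame(truth_rows)
    return dataset
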