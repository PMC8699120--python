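"""Non-compartmental analysis of individual concentration-time profiles.

AUC(0-inf) by the linear trapezoidal rule with terminal extrapolation,
terminal rate constant by log-linear regression over the terminal phase,
and the derived summaries: t1/2 = ln2/ke, CLtot = dose/AUC(0-inf),
Vd = CLtot/ke.  For an IV bolus the concentration at time zero is
back-extrapolated as the exponential of the intercept of a log-linear fit
through the first two sampled points, so the segment between dosing and
the first sample is not undercounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .data import PKDataset
from .model import PKValidationError

__all__ = [
    "ConcProfile",
    "NCAResult",
    "terminal_slope",
    "auc_0_inf",
    "nca_analyze",
    "nca_table",
    "urine_summary",
    "urinary_excretion_fraction",
]

EXTRAPOLATION_FLAG_FRACTION = 0.20


@dataclass(frozen=True)
class ConcProfile:
    """One subject's dose and sampled plasma concentrations."""

    subject: int
    dose: float  # mg/kg
    t: np.ndarray  # h, strictly increasing, > 0 for sampled points
    c: np.ndarray  # ug/mL, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        c = np.asarray(self.c, dtype=float)
        order = np.argsort(t)
        t, c = t[order], c[order]
        if np.any(t < 0.0):
            raise PKValidationError("profile times must be non-negative")
        if np.any(np.diff(t) <= 0.0):
            raise PKValidationError("profile times must be strictly increasing")
        if np.any(c < 0.0):
            raise PKValidationError("concentrations must be non-negative")
        if self.dose <= 0.0:
            raise PKValidationError("dose must be positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "c", c)


@dataclass(frozen=True)
class NCAResult:
    subject: int
    dose: float
    ke: float  # 1/h
    t_half: float  # h
    auc_last: float  # ug*h/mL
    auc_inf: float  # ug*h/mL
    cl_tot: float  # L/h/kg
    vd: float  # L/kg
    c0: float  # back-extrapolated ug/mL
    extrapolated_fraction: float
    flags: tuple[str, ...] = ()


def terminal_slope(profile: ConcProfile, n_terminal: int | str = 3) -> tuple[float, tuple[str, ...]]:
    """Terminal elimination rate constant ke (1/h).

    Ordinary least squares of ln C on t over the last ``n_terminal``
    positive concentrations; ``n_terminal='auto'`` picks the window (3 to
    5 points) with the best adjusted R^2.  A non-positive slope marks the
    profile unusable for extrapolation via the returned flags.
    """
    pos = profile.c > 0.0
    t = profile.t[pos]
    c = profile.c[pos]
    if n_terminal == "auto":
        best = (None, -np.inf)
        for n in (3, 4, 5):
            if len(t) < n:
                continue
            ke, r2adj = _ols_tail(t, c, n)
            if r2adj > best[1]:
                best = (ke, r2adj)
        if best[0] is None:
            raise PKValidationError("too few positive concentrations for terminal fit")
        ke = best[0]
    else:
        n = int(n_terminal)
        if len(t) < n or n < 2:
            raise PKValidationError(
                f"need at least {n} positive concentrations for the terminal fit"
            )
        ke, _ = _ols_tail(t, c, n)
    flags: tuple[str, ...] = ()
    if ke <= 0.0:
        flags = ("nonpositive_terminal_slope",)
    return ke, flags


def _ols_tail(t, c, n) -> tuple[float, float]:
    tt, cc = t[-n:], np.log(c[-n:])
    res = scipy.stats.linregress(tt, cc)
    r2 = float(res.rvalue) ** 2
    r2adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - 2, 1)
    return -float(res.slope), r2adj


def _back_extrapolated_c0(profile: ConcProfile) -> float:
    """C(0) from a log-linear fit through the first two positive points."""
    pos = profile.c > 0.0
    t = profile.t[pos]
    c = profile.c[pos]
    if len(t) < 2:
        return float(c[0]) if len(t) else 0.0
    t2, c2 = t[:2], np.log(c[:2])
    slope = (c2[1] - c2[0]) / (t2[1] - t2[0])
    if slope >= 0.0:  # rising start: fall back to the first observed value
        return float(c[0])
    return float(np.exp(c2[0] - slope * t2[0]))


def auc_0_inf(profile: ConcProfile, ke: float) -> tuple[float, float]:
    """(AUC to the last sample, AUC extrapolated to infinity), ug*h/mL.

    Linear trapezoids over the sampled points, with a leading segment from
    (0, back-extrapolated C0) when the first sample is after time zero;
    the tail adds C_last/ke.
    """
    if ke <= 0.0:
        raise PKValidationError("ke must be positive for extrapolation")
    t = profile.t
    c = profile.c
    if t[0] > 0.0:
        c0 = _back_extrapolated_c0(profile)
        t = np.r_[0.0, t]
        c = np.r_[c0, c]
    auc_last = float(np.trapezoid(c, t))
    auc_inf = auc_last + float(c[-1]) / ke
    return auc_last, auc_inf


def nca_analyze(profile: ConcProfile, n_terminal: int | str = 3) -> NCAResult:
    """Full non-compartmental summary of one profile."""
    if np.count_nonzero(profile.c > 0.0) < 3:
        raise PKValidationError("need at least 3 positive concentrations")
    ke, flags = terminal_slope(profile, n_terminal)
    if "nonpositive_terminal_slope" in flags:
        nan = float("nan")
        return NCAResult(
            subject=profile.subject, dose=profile.dose, ke=ke, t_half=nan,
            auc_last=nan, auc_inf=nan, cl_tot=nan, vd=nan, c0=nan,
            extrapolated_fraction=nan, flags=flags,
        )
    auc_last, auc_inf = auc_0_inf(profile, ke)
    extrap = (auc_inf - auc_last) / auc_inf
    if extrap > EXTRAPOLATION_FLAG_FRACTION:
        flags = flags + ("extrapolation_gt_20pct",)
    cl_tot = profile.dose / auc_inf
    vd = cl_tot / ke
    return NCAResult(
        subject=profile.subject,
        dose=profile.dose,
        ke=ke,
        t_half=float(np.log(2.0) / ke),
        auc_last=auc_last,
        auc_inf=auc_inf,
        cl_tot=cl_tot,
        vd=vd,
        c0=_back_extrapolated_c0(profile),
        extrapolated_fraction=float(extrap),
        flags=flags,
    )


def nca_table(data: PKDataset, n_terminal: int | str = 3) -> pd.DataFrame:
    """Per-subject NCA over a dataset's plasma observations."""
    obs = data.plasma_observations()
    doses = data.doses()
    rows = []
    for sid, sub in obs.groupby("ID"):
        keep = sub["BLQ"] == 0
        profile = ConcProfile(
            subject=int(sid),
            dose=float(doses.loc[sid]),
            t=sub.loc[keep, "TIME"].to_numpy(dtype=float),
            c=sub.loc[keep, "DV"].to_numpy(dtype=float),
        )
        try:
            r = nca_analyze(profile, n_terminal)
        except PKValidationError:
            continue
        rows.append(
            {
                "ID": r.subject,
                "dose": r.dose,
                "ke": r.ke,
                "t_half": r.t_half,
                "auc_last": r.auc_last,
                "auc_inf": r.auc_inf,
                "cl_tot": r.cl_tot,
                "vd": r.vd,
                "c0": r.c0,
                "extrapolated_fraction": r.extrapolated_fraction,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Urine summaries
# ---------------------------------------------------------------------------


def urinary_excretion_fraction(amount_excreted_ug: float, dose_total_ug: float) -> float:
    """Fraction (as a percentage) of the administered dose excreted intact."""
    if dose_total_ug <= 0.0:
        raise PKValidationError("total dose must be positive")
    if amount_excreted_ug < 0.0:
        raise PKValidationError("excreted amount cannot be negative")
    return 100.0 * amount_excreted_ug / dose_total_ug


def urine_summary(data: PKDataset, horizon: float = 4.0) -> pd.DataFrame:
    """Per-subject cumulative urinary excretion up to ``horizon`` hours.

    Returns the cumulative amount (ug) at the last collection interval
    ending at or before the horizon and the percentage of the absolute
    dose (dose per kg times body weight) it represents.
    """
    urine = data.urine_observations()
    doses = data.doses()
    cov = data.covariates()
    rows = []
    for sid, sub in urine.groupby("ID"):
        sub = sub[sub["TIME"] <= horizon + 1e-9]
        if len(sub) == 0:
            continue
        ae = float(sub["DV"].iloc[-1])
        wt = float(cov.loc[sid, "WT"])
        dose_total_ug = float(doses.loc[sid]) * wt * 1000.0  # mg/kg * kg -> mg -> ug
        rows.append(
            {
                "ID": int(sid),
                "ae_ug": ae,
                "dose_total_ug": dose_total_ug,
                "fe_percent": urinary_excretion_fraction(ae, dose_total_ug),
            }
        )
    return pd.DataFrame(rows)
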