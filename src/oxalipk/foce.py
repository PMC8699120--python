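"""First-order conditional estimation (FOCE-ELS) for the population model.

The population model places lognormal inter-individual variability on
V1, CL and CL2 (``P_i = theta_P * exp(eta_P)``, ``eta ~ N(0, omega^2)``,
diagonal) and a proportional residual error on the observations
(``y = f * (1 + eps)``, ``eps ~ N(0, sigma^2)``).

Estimation follows the classical FOCE linearisation with interaction
(residual variance evaluated at the individual prediction).  For each
subject the empirical Bayes mode ``eta_hat`` minimises

    sum_j [ (y_j - f_j(eta))^2 / (sigma^2 f_j(eta)^2) + ln(sigma^2 f_j(eta)^2) ]
        + eta' Omega^-1 eta

and the marginal -2 log-likelihood is approximated subject-wise by

    n_i ln(2 pi) + ln|V_i| + r_i' V_i^-1 r_i,
    V_i = G_i Omega G_i' + diag(sigma^2 f_i(eta_hat)^2),
    r_i = y_i - f_i(eta_hat) + G_i eta_hat,

with ``G_i`` the Jacobian of the prediction in ``eta`` at the mode
(central finite differences, step 1e-5).  The outer problem minimises
the summed objective over log-transformed (theta, omega, sigma).

The engine is generic over the structural model so that reduced models
(e.g. a one-compartment, single-random-effect model) run through exactly
the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .data import PKDataset
from .model import PKParams, PKValidationError, TwoCompartmentIVBolus

__all__ = [
    "PopModel",
    "FOCEResult",
    "FitOptions",
    "estimate_eta",
    "foce_objective",
    "fit_foce",
    "compute_cwres",
]

_FD_STEP_ETA = 1e-5  # central-difference step for d f / d eta
_LN2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PopModel:
    """Fixed effects, diagonal inter-individual variances, residual SD.

    ``omega2`` holds the variances of the random effects on (V1, CL, CL2);
    the reported inter-individual variability percentages are
    ``100 * sqrt(omega2)``.  ``sigma`` is the proportional residual SD as a
    fraction (0.149 for 14.9%).
    """

    theta: PKParams
    omega2: tuple[float, float, float]
    sigma: float

    def __post_init__(self) -> None:
        om = np.asarray(self.omega2, dtype=float)
        if om.shape != (3,) or np.any(om < 0.0) or not np.all(np.isfinite(om)):
            raise PKValidationError("omega2 must be 3 non-negative finite variances")
        object.__setattr__(self, "omega2", tuple(float(v) for v in om))
        if not np.isfinite(self.sigma) or self.sigma <= 0.0:
            raise PKValidationError("sigma must be strictly positive")

    @property
    def iiv_percent(self) -> tuple[float, float, float]:
        """Inter-individual variability on (V1, CL, CL2) as percentages."""
        return tuple(100.0 * float(np.sqrt(v)) for v in self.omega2)

    @property
    def sigma_percent(self) -> float:
        return 100.0 * self.sigma


@dataclass
class FitOptions:
    """Tunables of the outer optimisation and standard-error computation."""

    max_outer_iter: int = 200
    outer_fd_step: float = 1e-5  # absolute step on log-parameters
    inner_gtol: float = 1e-8
    inner_max_iter: int = 100
    se_method: str = "hessian"  # or "sandwich"
    compute_se: bool = True


@dataclass
class FOCEResult:
    """Everything the estimation stage reports."""

    pop_hat: PopModel
    minus2ll: float
    cv_percent: dict[str, float]
    se: dict[str, float]
    eta_hat: pd.DataFrame = field(repr=False)  # per-subject EBEs + post hoc params
    gof: pd.DataFrame = field(repr=False)  # OBS/PRED/IPRED/CWRES/TAD per observation
    converged: bool = True
    n_iter: int = 0
    n_obs: int = 0
    n_blq_excluded: int = 0
    message: str = ""

    def parameter_table(self) -> pd.DataFrame:
        """Estimate / CV% block in the layout of a population-PK report."""
        p = self.pop_hat
        rows = [
            ("V", "L/kg", p.theta.v1, self.cv_percent.get("V1", np.nan)),
            ("V2", "L/kg", p.theta.v2, self.cv_percent.get("V2", np.nan)),
            ("CL", "L/h/kg", p.theta.cl, self.cv_percent.get("CL", np.nan)),
            ("CL2", "L/h/kg", p.theta.cl2, self.cv_percent.get("CL2", np.nan)),
            ("omega_V", "%", p.iiv_percent[0], self.cv_percent.get("omega_V1", np.nan)),
            ("omega_CL", "%", p.iiv_percent[1], self.cv_percent.get("omega_CL", np.nan)),
            ("omega_CL2", "%", p.iiv_percent[2], self.cv_percent.get("omega_CL2", np.nan)),
            ("sigma", "%", p.sigma_percent, self.cv_percent.get("sigma", np.nan)),
        ]
        return pd.DataFrame(rows, columns=["parameter", "unit", "estimate", "cv_percent"])


# ---------------------------------------------------------------------------
# Array extraction
# ---------------------------------------------------------------------------


@dataclass
class _Arrays:
    """Padded per-subject arrays for the plasma observations."""

    ids: np.ndarray  # (S,)
    dose: np.ndarray  # (S,)
    t: np.ndarray  # (S, T)
    y: np.ndarray  # (S, T)
    mask: np.ndarray  # (S, T) 1.0 where the observation enters the likelihood
    n_blq: int = 0


def _extract_arrays(data: PKDataset) -> _Arrays:
    obs = data.plasma_observations()
    doses = data.doses()
    ids = np.unique(obs["ID"].to_numpy())
    if len(ids) == 0:
        raise PKValidationError("dataset has no plasma observations")
    groups = {sid: sub for sid, sub in obs.groupby("ID")}
    tmax = max(len(g) for g in groups.values())
    S = len(ids)
    t = np.zeros((S, tmax))
    y = np.zeros((S, tmax))
    mask = np.zeros((S, tmax))
    n_blq = 0
    for i, sid in enumerate(ids):
        g = groups[sid]
        n = len(g)
        t[i, :n] = g["TIME"].to_numpy(dtype=float)
        y[i, :n] = g["DV"].to_numpy(dtype=float)
        blq = g["BLQ"].to_numpy(dtype=int) == 1
        mask[i, :n] = (~blq).astype(float)
        n_blq += int(blq.sum())
    # padded slots keep t = 0, y = 0, mask = 0: they never enter any sum
    dose = np.array([float(doses.loc[sid]) for sid in ids])
    return _Arrays(ids=ids, dose=dose, t=t, y=y, mask=mask, n_blq=n_blq)


# ---------------------------------------------------------------------------
# Inner problem: batched empirical Bayes modes
# ---------------------------------------------------------------------------


def _jac_eta(model, theta, eta, dose, t, h: float = _FD_STEP_ETA) -> np.ndarray:
    """d predict / d eta by central differences, shape (S, T, n_eta)."""
    cols = []
    for k in range(eta.shape[1]):
        step = np.zeros_like(eta)
        step[:, k] = h
        fp = model.predict(theta, eta + step, dose, t)
        fm = model.predict(theta, eta - step, dose, t)
        cols.append((fp - fm) / (2.0 * h))
    return np.stack(cols, axis=-1)


_ETA_BOUND = 30.0  # |eta| beyond this is numerically meaningless
_STEP_BOUND = 5.0  # trust bound on a single Newton step component


def _inner_objective(model, theta, sigma2, w_inv, dose, t, y, mask, eta) -> np.ndarray:
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        f = np.maximum(model.predict(theta, eta, dose, t), 1e-12)
        f = np.where(np.isfinite(f), f, 1e-12)
        res = y - f
        var = sigma2 * f * f
        terms = res * res / var + np.log(var)
        return np.sum(terms * mask, axis=1) + np.sum(eta * eta * w_inv, axis=1)


def _inner_solve(
    model,
    theta,
    omega2,
    sigma,
    dose,
    t,
    y,
    mask,
    eta0=None,
    gtol: float = 1e-8,
    max_iter: int = 100,
):
    """Damped (Levenberg-style) Newton for all subjects' modes at once.

    The Gauss-Newton Hessian ``2 J' W J + 2 Omega^-1`` is positive
    definite, so the damped step is always a descent direction; per-subject
    damping factors adapt on rejection.  Returns (eta_hat, converged mask).
    """
    S = len(dose)
    p = model.n_eta
    sigma2 = float(sigma) ** 2
    w_inv = 1.0 / np.maximum(np.asarray(omega2, dtype=float), 1e-12)
    eta = np.zeros((S, p)) if eta0 is None else np.array(eta0, dtype=float)
    eye = np.eye(p)

    g = _inner_objective(model, theta, sigma2, w_inv, dose, t, y, mask, eta)
    lam = np.full(S, 1e-6)
    done = np.zeros(S, dtype=bool)
    for _ in range(max_iter):
        f = np.maximum(model.predict(theta, eta, dose, t), 1e-12)
        J = _jac_eta(model, theta, eta, dose, t)
        res = y - f
        inv_var = 1.0 / (sigma2 * f * f)
        dgdf = (-2.0 * res * inv_var - 2.0 * res * res * inv_var / f + 2.0 / f) * mask
        grad = np.einsum("st,stp->sp", dgdf, J) + 2.0 * eta * w_inv
        gn = np.max(np.abs(grad), axis=1)
        done = gn <= gtol * (1.0 + np.abs(g))
        if done.all():
            break
        W = 2.0 * inv_var * mask
        H = np.einsum("st,stp,stq->spq", W, J, J) + 2.0 * np.diag(w_inv)[None, :, :]
        active = ~done
        pending = active.copy()
        eta_try = eta.copy()
        for _attempt in range(30):
            idx = np.flatnonzero(pending)
            if len(idx) == 0:
                break
            Hd = H[idx] + lam[idx, None, None] * eye[None, :, :]
            step = -np.linalg.solve(Hd, grad[idx, :, None])[..., 0]
            step = np.clip(step, -_STEP_BOUND, _STEP_BOUND)
            cand = np.clip(eta[idx] + step, -_ETA_BOUND, _ETA_BOUND)
            g_cand = _inner_objective(
                model, theta, sigma2, w_inv, dose[idx], t[idx], y[idx], mask[idx], cand
            )
            improved = g_cand <= g[idx] + 1e-12
            good = idx[improved]
            eta_try[good] = cand[improved]
            g[good] = g_cand[improved]
            lam[good] = np.maximum(lam[good] * 0.3, 1e-10)
            bad = idx[~improved]
            lam[bad] *= 10.0
            pending[good] = False
        # subjects whose step never improved keep their eta (flat region)
        done[pending & active] = True
        eta = eta_try
    return eta, done


def estimate_eta(
    pop: PopModel,
    dose: float,
    t,
    y,
    model=TwoCompartmentIVBolus,
    gtol: float = 1e-8,
):
    """Empirical Bayes (post hoc) random-effect estimate for one subject.

    Parameters are the subject's dose (mg/kg), observation times (h) and
    observed concentrations (ug/mL).  Returns the 3-vector ``eta_hat``.
    """
    t = np.asarray(t, dtype=float).reshape(1, -1)
    y = np.asarray(y, dtype=float).reshape(1, -1)
    if y.size < 1:
        raise PKValidationError("subject needs at least one observation")
    mask = np.ones_like(y)
    eta, _ = _inner_solve(
        model,
        pop.theta.as_array(),
        np.asarray(pop.omega2),
        pop.sigma,
        np.array([dose], dtype=float),
        t,
        y,
        mask,
        gtol=gtol,
    )
    return eta[0]


# ---------------------------------------------------------------------------
# Outer objective
# ---------------------------------------------------------------------------


def _neg2ll_parts(model, theta, omega2, sigma, arrays: _Arrays, eta0=None,
                  inner_gtol: float = 1e-8, inner_max_iter: int = 100):
    """Per-subject FOCE -2LL contributions and the modes they used."""
    dose, t, y, mask = arrays.dose, arrays.t, arrays.y, arrays.mask
    eta_hat, _ = _inner_solve(
        model, theta, omega2, sigma, dose, t, y, mask,
        eta0=eta0, gtol=inner_gtol, max_iter=inner_max_iter,
    )
    f = np.maximum(model.predict(theta, eta_hat, dose, t), 1e-12)
    G = _jac_eta(model, theta, eta_hat, dose, t) * mask[:, :, None]
    sigma2 = float(sigma) ** 2
    om = np.asarray(omega2, dtype=float)

    GO = G * om[None, None, :]
    V = GO @ np.swapaxes(G, 1, 2)
    T = t.shape[1]
    diag = sigma2 * f * f * mask + (1.0 - mask)  # masked slots: unit diagonal
    V[:, np.arange(T), np.arange(T)] += diag
    # ridge stabilisation against numerically singular covariance
    sign, logdet = np.linalg.slogdet(V)
    if np.any(sign <= 0):
        V = V + 1e-10 * np.eye(T)[None, :, :]
        sign, logdet = np.linalg.slogdet(V)
    r = (y - f + np.einsum("stp,sp->st", G, eta_hat)) * mask
    sol = np.linalg.solve(V, r[:, :, None])[..., 0]
    quad = np.sum(r * sol, axis=1)
    n_i = mask.sum(axis=1)
    parts = n_i * _LN2PI + logdet + quad
    return parts, eta_hat, f, G, V


def foce_objective(pop: PopModel, data: PKDataset, model=TwoCompartmentIVBolus) -> float:
    """FOCE-ELS approximate -2 log-likelihood of the dataset under ``pop``."""
    arrays = _extract_arrays(data)
    parts, _, _, _, _ = _neg2ll_parts(
        model, pop.theta.as_array(), np.asarray(pop.omega2), pop.sigma, arrays
    )
    return float(np.sum(parts))


def foce_neg2ll_arrays(model, theta, omega2, sigma, dose, t, y, mask=None) -> float:
    """FOCE -2LL for raw arrays under any structural model.

    ``dose`` is (S,), ``t``/``y`` are (S, T) padded grids, ``mask`` marks
    the entries that enter the likelihood (all by default).  Useful for
    reduced models with a different number of random effects.
    """
    t = np.atleast_2d(np.asarray(t, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if mask is None:
        mask = np.ones_like(y)
    arrays = _Arrays(
        ids=np.arange(len(np.atleast_1d(dose))),
        dose=np.atleast_1d(np.asarray(dose, dtype=float)),
        t=t,
        y=y,
        mask=np.asarray(mask, dtype=float),
    )
    parts, _, _, _, _ = _neg2ll_parts(
        model, np.asarray(theta, dtype=float), np.asarray(omega2, dtype=float),
        float(sigma), arrays,
    )
    return float(np.sum(parts))


# ---------------------------------------------------------------------------
# Outer optimisation
# ---------------------------------------------------------------------------


def _nca_informed_init(data: PKDataset) -> PopModel:
    """Rough starting values from non-compartmental summaries.

    CL starts at the median dose/AUC(0-inf), V1 at the median dose/C(0);
    V2 and CL2 start at crude fractions of the NCA distribution volume and
    clearance.  Falls back to generic values if NCA fails.
    """
    from .nca import nca_table

    try:
        tab = nca_table(data)
        ok = tab[np.isfinite(tab["cl_tot"]) & np.isfinite(tab["vd"])]
        cl = float(np.median(ok["cl_tot"])) * 0.7
        vd = float(np.median(ok["vd"]))
        v1 = float(np.median(ok["dose"] / ok["c0"]))
        v2 = max(vd - v1, 0.5 * v1)
        cl2 = 0.5 * cl
        theta = PKParams(v1=v1, v2=v2, cl=cl, cl2=cl2)
    except Exception:
        theta = PKParams(v1=0.5, v2=2.0, cl=2.0, cl2=1.0)
    return PopModel(theta=theta, omega2=(0.09, 0.09, 0.09), sigma=0.2)


def _pack(pop: PopModel) -> np.ndarray:
    return np.log(
        np.r_[
            pop.theta.as_array(),
            np.sqrt(np.maximum(np.asarray(pop.omega2), 1e-8)),
            pop.sigma,
        ]
    )


def _unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    v = np.exp(x)
    return v[:4], v[4:7] ** 2, float(v[7])


_PARAM_KEYS = ["V1", "V2", "CL", "CL2", "omega_V1", "omega_CL", "omega_CL2", "sigma"]


def fit_foce(
    data: PKDataset,
    init: PopModel | None = None,
    options: FitOptions | None = None,
    model=TwoCompartmentIVBolus,
) -> FOCEResult:
    """Fit the population model by FOCE-ELS.

    The outer problem is a quasi-Newton (L-BFGS-B) minimisation of the
    FOCE objective over log-transformed (theta, omega, sigma); inner
    empirical Bayes modes are warm-started between objective evaluations.
    Deterministic for fixed data and initial values.
    """
    options = options or FitOptions()
    arrays = _extract_arrays(data)
    if len(arrays.ids) < 2:
        raise PKValidationError("population estimation needs at least 2 subjects")
    if init is None:
        init = _nca_informed_init(data)

    cache = {"eta": np.zeros((len(arrays.ids), model.n_eta))}
    n_eval = [0]

    def objective(x: np.ndarray) -> float:
        theta, omega2, sigma = _unpack(x)
        n_eval[0] += 1
        try:
            parts, eta_hat, _, _, _ = _neg2ll_parts(
                model, theta, omega2, sigma, arrays,
                eta0=cache["eta"], inner_gtol=options.inner_gtol,
                inner_max_iter=options.inner_max_iter,
            )
        except np.linalg.LinAlgError:
            return 1e12
        value = float(np.sum(parts))
        if not np.isfinite(value):
            return 1e12
        cache["eta"] = eta_hat
        return value

    x0 = _pack(init)
    res = scipy.optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={
            "maxiter": options.max_outer_iter,
            "eps": options.outer_fd_step,
            "ftol": 1e-11,
            "gtol": 1e-5,
        },
    )
    xhat = res.x
    theta, omega2, sigma = _unpack(xhat)
    pop_hat = PopModel(theta=PKParams.from_array(theta), omega2=tuple(omega2), sigma=sigma)

    parts, eta_hat, f, G, V = _neg2ll_parts(
        model, theta, omega2, sigma, arrays, eta0=cache["eta"],
        inner_gtol=options.inner_gtol, inner_max_iter=options.inner_max_iter,
    )
    minus2ll = float(np.sum(parts))

    se: dict[str, float] = {}
    cv: dict[str, float] = {}
    if options.compute_se:
        try:
            se_log = _standard_errors(objective, xhat, arrays, model, options)
            for key, s in zip(_PARAM_KEYS, se_log):
                se[key] = float(s)
                cv[key] = float(100.0 * s)  # delta method: CV of P = SE of log P
        except Exception as exc:  # SEs are reported, never allowed to kill a fit
            se = {}
            cv = {}

    gof = _gof_table(model, pop_hat, arrays, eta_hat, f, G, V)
    eta_df = _eta_table(model, pop_hat, arrays, eta_hat)

    converged = bool(res.success) or "CONVERGENCE" in str(res.message).upper()
    return FOCEResult(
        pop_hat=pop_hat,
        minus2ll=minus2ll,
        cv_percent=cv,
        se=se,
        eta_hat=eta_df,
        gof=gof,
        converged=converged,
        n_iter=int(res.nit),
        n_obs=int(arrays.mask.sum()),
        n_blq_excluded=arrays.n_blq,
        message=str(res.message),
    )


def _standard_errors(objective, xhat, arrays, model, options: FitOptions) -> np.ndarray:
    """SEs of the log-parameters from the outer objective's curvature.

    ``hessian``: inverse observed information, cov = 2 H^-1 of the -2LL.
    ``sandwich``: H^-1 B H^-1 form with B the per-subject score
    cross-products.
    """
    n = len(xhat)
    h = 1e-3
    H = np.zeros((n, n))
    f0 = objective(xhat)
    # central-difference Hessian on the log scale
    fp = np.zeros(n)
    fm = np.zeros(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        fp[i] = objective(xhat + e)
        fm[i] = objective(xhat - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            fpp = objective(xhat + ei + ej)
            fmm = objective(xhat - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
            ) / (2.0 * h**2)
    cov = 2.0 * np.linalg.pinv(H)
    if options.se_method == "sandwich":
        theta, omega2, sigma = _unpack(xhat)
        S = len(arrays.ids)
        scores = np.zeros((S, n))
        for i in range(n):
            e = np.zeros(n)
            e[i] = h
            pp, _, _, _, _ = _neg2ll_parts(model, *_unpack(xhat + e), arrays)
            pm, _, _, _, _ = _neg2ll_parts(model, *_unpack(xhat - e), arrays)
            scores[:, i] = -(pp - pm) / (2.0 * h) / 2.0  # per-subject LL score
        B = scores.T @ scores
        info = H / 2.0
        info_inv = np.linalg.pinv(info)
        cov = info_inv @ B @ info_inv
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def _gof_table(model, pop_hat: PopModel, arrays: _Arrays, eta_hat, f, G, V) -> pd.DataFrame:
    theta = pop_hat.theta.as_array()
    pred = model.predict(theta, np.zeros_like(eta_hat), arrays.dose, arrays.t)
    rows = []
    T = arrays.t.shape[1]
    for i, sid in enumerate(arrays.ids):
        m = arrays.mask[i].astype(bool)
        if not m.any():
            continue
        Vi = V[i][np.ix_(m, m)]
        ri = (arrays.y[i] - f[i] + G[i] @ eta_hat[i])[m]
        vals, vecs = np.linalg.eigh(Vi)
        inv_sqrt = vecs @ np.diag(1.0 / np.sqrt(np.maximum(vals, 1e-300))) @ vecs.T
        cw = inv_sqrt @ ri
        tt = arrays.t[i][m]
        for j in range(m.sum()):
            rows.append(
                {
                    "ID": int(sid),
                    "TIME": tt[j],
                    "TAD": tt[j],  # single bolus at time 0
                    "OBS": arrays.y[i][m][j],
                    "PRED": pred[i][m][j],
                    "IPRED": f[i][m][j],
                    "CWRES": cw[j],
                }
            )
    return pd.DataFrame(rows)


def _eta_table(model, pop_hat: PopModel, arrays: _Arrays, eta_hat) -> pd.DataFrame:
    th = pop_hat.theta
    df = pd.DataFrame(
        {
            "ID": arrays.ids.astype(int),
            "eta_V1": eta_hat[:, 0],
            "eta_CL": eta_hat[:, 1],
            "eta_CL2": eta_hat[:, 2],
        }
    )
    df["V1_i"] = th.v1 * np.exp(df["eta_V1"])
    df["CL_i"] = th.cl * np.exp(df["eta_CL"])
    df["CL2_i"] = th.cl2 * np.exp(df["eta_CL2"])
    df["CLtot_i"] = df["CL_i"] + df["CL2_i"]
    return df


def compute_cwres(pop: PopModel, data: PKDataset, model=TwoCompartmentIVBolus) -> pd.DataFrame:
    """CWRES / PRED / IPRED table for a dataset under a given population model.

    CWRES decorrelates the FOCE-linearised residual by the symmetric
    inverse square root of the subject covariance; under a correct model
    it is approximately standard normal.
    """
    arrays = _extract_arrays(data)
    theta = pop.theta.as_array()
    parts, eta_hat, f, G, V = _neg2ll_parts(
        model, theta, np.asarray(pop.omega2), pop.sigma, arrays
    )
    return _gof_table(model, pop, arrays, eta_hat, f, G, V)
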