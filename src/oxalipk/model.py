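"""Closed-form two-compartment IV-bolus pharmacokinetic model.

The structural model shared by every other stage of the package.  An
intravenous bolus enters a central compartment of volume ``V1`` (L/kg),
distributes to a peripheral compartment of volume ``V2`` (L/kg) via the
inter-compartmental clearance ``CL2`` (L/h/kg), and is eliminated from
the central compartment with clearance ``CL`` (L/h/kg).  The plasma
concentration is the familiar bi-exponential

    C(t) = A * exp(-alpha * t) + B * exp(-beta * t)

with ``alpha > beta > 0`` the roots of the characteristic polynomial of
the micro rate constants.  All parameters are expressed per kilogram of
body weight, so a dose given in mg/kg yields concentrations directly in
ug/mL without a body-weight field.  Time is in hours throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParams",
    "MacroParams",
    "PKValidationError",
    "DegenerateEliminationError",
    "micro_constants",
    "macro_constants",
    "predict_conc",
    "auc_closed_form",
    "auc_to_time",
    "TwoCompartmentIVBolus",
    "OneCompartmentIVBolus",
]


class PKValidationError(ValueError):
    """Raised when a parameter set or input violates its domain."""


class DegenerateEliminationError(ValueError):
    """Raised when alpha == beta (repeated root of the disposition polynomial).

    The bi-exponential form is then undefined; the case has probability
    zero under continuous parameters and is rejected rather than handled
    with the ``t*exp(-alpha*t)`` limiting form.
    """


@dataclass(frozen=True)
class PKParams:
    """Structural parameters of the two-compartment model (per-kg basis).

    Attributes
    ----------
    v1 : float
        Central volume of distribution, L/kg.
    v2 : float
        Peripheral volume of distribution, L/kg.
    cl : float
        Elimination clearance from the central compartment, L/h/kg.
    cl2 : float
        Inter-compartmental clearance, L/h/kg.
    """

    v1: float
    v2: float
    cl: float
    cl2: float

    def __post_init__(self) -> None:
        for name in ("v1", "v2", "cl", "cl2"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise PKValidationError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )

    @property
    def cl_tot(self) -> float:
        """Total clearance CL + CL2, L/h/kg (the reported composite)."""
        return self.cl + self.cl2

    @property
    def vd(self) -> float:
        """Total distribution volume V1 + V2, L/kg (the reported composite)."""
        return self.v1 + self.v2

    def as_array(self) -> np.ndarray:
        return np.array([self.v1, self.v2, self.cl, self.cl2], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "PKParams":
        return cls(float(x[0]), float(x[1]), float(x[2]), float(x[3]))


@dataclass(frozen=True)
class MacroParams:
    """Macro (bi-exponential) constants of the IV-bolus solution.

    ``a`` and ``b`` are intercepts in ug/mL, ``alpha`` and ``beta``
    hybrid rate constants in 1/h with ``alpha > beta > 0``.
    """

    a: float
    b: float
    alpha: float
    beta: float


def micro_constants(params: PKParams) -> tuple[float, float, float]:
    """Micro rate constants (k10, k12, k21), all 1/h.

    k10 = CL/V1 (elimination), k12 = CL2/V1 (central -> peripheral),
    k21 = CL2/V2 (peripheral -> central).
    """
    return params.cl / params.v1, params.cl2 / params.v1, params.cl2 / params.v2


def macro_constants(params: PKParams, dose: float) -> MacroParams:
    """Bi-exponential constants for an IV bolus of `dose` mg/kg.

    alpha and beta are the roots of ``s^2 - (k10+k12+k21) s + k10*k21``;
    the intercepts satisfy ``A + B = dose/V1`` (concentration at t = 0)
    and ``A/alpha + B/beta = dose/CL`` (the AUC identity).
    """
    if not np.isfinite(dose) or dose <= 0.0:
        raise PKValidationError(f"dose must be strictly positive, got {dose!r}")
    k10, k12, k21 = micro_constants(params)
    ksum = k10 + k12 + k21
    disc = ksum * ksum - 4.0 * k10 * k21
    if disc <= 1e-12 * ksum * ksum:
        raise DegenerateEliminationError(
            "alpha == beta: repeated disposition root is not supported"
        )
    root = float(np.sqrt(disc))
    alpha = 0.5 * (ksum + root)
    beta = 0.5 * (ksum - root)
    c0 = dose / params.v1
    a = c0 * (alpha - k21) / (alpha - beta)
    b = c0 * (k21 - beta) / (alpha - beta)
    return MacroParams(a=a, b=b, alpha=alpha, beta=beta)


def predict_conc(params: PKParams, dose: float, t: np.ndarray | float) -> np.ndarray:
    """Plasma concentration (ug/mL) at time(s) `t` hours after an IV bolus."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise PKValidationError("time must be non-negative")
    m = macro_constants(params, dose)
    return m.a * np.exp(-m.alpha * t) + m.b * np.exp(-m.beta * t)


def auc_closed_form(params: PKParams, dose: float) -> float:
    """AUC from zero to infinity, ug*h/mL: exactly dose/CL for a linear model."""
    if not np.isfinite(dose) or dose <= 0.0:
        raise PKValidationError(f"dose must be strictly positive, got {dose!r}")
    return dose / params.cl


def auc_to_time(params: PKParams, dose: float, t: np.ndarray | float) -> np.ndarray:
    """Partial AUC from 0 to `t` hours (analytic integral of the bi-exponential)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise PKValidationError("time must be non-negative")
    m = macro_constants(params, dose)
    return m.a / m.alpha * (1.0 - np.exp(-m.alpha * t)) + m.b / m.beta * (
        1.0 - np.exp(-m.beta * t)
    )


# ---------------------------------------------------------------------------
# Vectorised structural-model adapters used by the mixed-effects machinery.
# A structural model maps a fixed-effect vector theta and a per-subject
# random-effect matrix eta (S, n_eta) to predicted concentrations on a
# padded time grid (S, T).  Random effects act multiplicatively:
# P_i = theta_P * exp(eta_P).
# ---------------------------------------------------------------------------


def _biexp_batch(v1, v2, cl, cl2, dose, t):
    """Batched two-compartment bolus concentration; inputs broadcast to (S, T)."""
    k10 = cl / v1
    k12 = cl2 / v1
    k21 = cl2 / v2
    ksum = k10 + k12 + k21
    root = np.sqrt(ksum * ksum - 4.0 * k10 * k21)
    alpha = 0.5 * (ksum + root)
    beta = 0.5 * (ksum - root)
    c0 = dose / v1
    a = c0 * (alpha - k21) / root
    b = c0 * (k21 - beta) / root
    return a * np.exp(-alpha * t) + b * np.exp(-beta * t)


class TwoCompartmentIVBolus:
    """Two-compartment bolus model with lognormal variability on V1, CL, CL2.

    theta order: (V1, V2, CL, CL2); eta order: (V1, CL, CL2).  V2 carries
    no random effect.
    """

    n_theta = 4
    n_eta = 3
    theta_names = ("V1", "V2", "CL", "CL2")
    eta_names = ("V1", "CL", "CL2")

    @staticmethod
    def predict(theta: np.ndarray, eta: np.ndarray, dose: np.ndarray, t: np.ndarray) -> np.ndarray:
        eta = np.atleast_2d(eta)
        v1 = theta[0] * np.exp(eta[:, 0:1])
        cl = theta[2] * np.exp(eta[:, 1:2])
        cl2 = theta[3] * np.exp(eta[:, 2:3])
        v2 = np.broadcast_to(theta[1], v1.shape)
        dose = np.asarray(dose, dtype=float).reshape(-1, 1)
        return _biexp_batch(v1, v2, cl, cl2, dose, np.atleast_2d(t))


class OneCompartmentIVBolus:
    """Mono-exponential bolus model with a single random effect on CL.

    theta order: (V, CL); eta order: (CL,).  Used for reduced problems and
    cross-checks where a one-dimensional random effect is wanted.
    """

    n_theta = 2
    n_eta = 1
    theta_names = ("V", "CL")
    eta_names = ("CL",)

    @staticmethod
    def predict(theta: np.ndarray, eta: np.ndarray, dose: np.ndarray, t: np.ndarray) -> np.ndarray:
        eta = np.atleast_2d(eta)
        v = theta[0]
        cl = theta[1] * np.exp(eta[:, 0:1])
        dose = np.asarray(dose, dtype=float).reshape(-1, 1)
        return dose / v * np.exp(-(cl / v) * np.atleast_2d(t))
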