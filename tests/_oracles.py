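"""Independent oracles used by the tests.

These deliberately avoid the package's closed-form/linearised code paths:
the concentration oracle integrates the compartmental mass-balance ODEs
numerically, and the marginal likelihood oracle integrates the single
random effect out by adaptive Gauss-Hermite quadrature centred at the
conditional mode.
"""

from __future__ import annotations

import numpy as np
import scipy.integrate
import scipy.optimize


def conc_ode_oracle(v1, v2, cl, cl2, dose, times):
    """Two-compartment bolus concentrations by stiff ODE integration.

    dA1/dt = -(k10 + k12) A1 + k21 A2,  dA2/dt = k12 A1 - k21 A2,
    A1(0) = dose (per kg), C = A1 / V1.
    """
    k10, k12, k21 = cl / v1, cl2 / v1, cl2 / v2

    def rhs(_t, a):
        return [-(k10 + k12) * a[0] + k21 * a[1], k12 * a[0] - k21 * a[1]]

    times = np.asarray(times, dtype=float)
    sol = scipy.integrate.solve_ivp(
        rhs,
        (0.0, float(times.max()) if times.max() > 0 else 1.0),
        [dose, 0.0],
        t_eval=times,
        method="LSODA",
        rtol=1e-11,
        atol=1e-14,
    )
    return sol.y[0] / v1


def marginal_m2ll_gh(pred_1d, omega2, sigma, y, n_nodes=80):
    """Exact (to quadrature accuracy) -2 log marginal likelihood, single eta.

    ``pred_1d(eta)`` maps a scalar random effect to the prediction vector
    for one subject; the residual is proportional normal with SD
    ``sigma * f`` and ``eta ~ N(0, omega2)``.  Adaptive Gauss-Hermite:
    nodes are centred at the conditional mode and scaled by the local
    curvature.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    def nll_joint(e):
        f = pred_1d(e)
        var = sigma**2 * f**2
        return (
            0.5 * np.sum((y - f) ** 2 / var + np.log(2.0 * np.pi * var))
            + 0.5 * e * e / omega2
            + 0.5 * np.log(2.0 * np.pi * omega2)
        )

    res = scipy.optimize.minimize_scalar(
        nll_joint, bounds=(-6.0, 6.0), method="bounded", options={"xatol": 1e-12}
    )
    mode, nll0 = res.x, res.fun
    h = 1e-4
    curv = (nll_joint(mode + h) - 2.0 * nll0 + nll_joint(mode - h)) / h**2
    scale = 1.0 / np.sqrt(max(curv, 1e-12))
    x = mode + np.sqrt(2.0) * scale * nodes
    g = np.array([np.exp(-(nll_joint(xi) - nll0) + ni**2) for xi, ni in zip(x, nodes)])
    integral = np.sqrt(2.0) * scale * np.sum(weights * g)
    return -2.0 * (np.log(integral) - nll0)
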