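"""FOCE-ELS estimation: empirical Bayes modes, the linearised marginal
likelihood against an adaptive Gauss-Hermite oracle, invariances, and
parameter recovery on simulated studies."""

import numpy as np
import pytest

from oxalipk import (
    PKParams,
    PopModel,
    compute_cwres,
    estimate_eta,
    fit_foce,
    foce_objective,
    generate_study,
    predict_conc,
)
from oxalipk.foce import FitOptions, foce_neg2ll_arrays
from oxalipk.model import OneCompartmentIVBolus, TwoCompartmentIVBolus

from _oracles import marginal_m2ll_gh

RICH_TIMES = np.linspace(0.05, 12.0, 40)


class TestEstimateEta:
    def test_noise_free_typical_subject_has_zero_modes_as_sigma_vanishes(self, pop_truth):
        # the interaction term ln(sigma^2 f^2) shifts the joint mode by
        # O(sigma^2), so eta_hat -> 0 only in the small-sigma limit
        y = predict_conc(pop_truth.theta, 8.0, RICH_TIMES)
        shift = []
        for sigma in (0.149, 0.01):
            pop = PopModel(theta=pop_truth.theta, omega2=pop_truth.omega2, sigma=sigma)
            shift.append(np.abs(estimate_eta(pop, 8.0, RICH_TIMES, y)).max())
        assert shift[1] < 1e-4
        assert shift[1] < shift[0]

    def test_vanishing_prior_variance_pins_modes_to_zero(self, pop_truth):
        rng = np.random.default_rng(0)
        f = predict_conc(pop_truth.theta, 8.0, RICH_TIMES)
        y = f * (1 + 0.149 * rng.standard_normal(f.shape))
        tight = PopModel(theta=pop_truth.theta, omega2=(1e-10, 1e-10, 1e-10), sigma=0.149)
        eta = estimate_eta(tight, 8.0, RICH_TIMES, y)
        np.testing.assert_allclose(eta, 0.0, atol=1e-4)

    def test_rich_noise_free_data_recover_true_effects(self, pop_truth):
        eta_true = np.array([0.25, -0.35, 0.15])
        ind = PKParams(
            v1=0.44 * np.exp(eta_true[0]),
            v2=2.26,
            cl=1.76 * np.exp(eta_true[1]),
            cl2=1.0 * np.exp(eta_true[2]),
        )
        y = predict_conc(ind, 8.0, RICH_TIMES)
        # small sigma: the likelihood dominates the prior shrinkage
        pop = PopModel(theta=pop_truth.theta, omega2=pop_truth.omega2, sigma=0.01)
        eta = estimate_eta(pop, 8.0, RICH_TIMES, y)
        np.testing.assert_allclose(eta, eta_true, atol=0.02)


class TestObjectiveOracle:
    def _toy(self, seed, sigma=0.1, omega=0.3, n_subj=4):
        rng = np.random.default_rng(seed)
        theta = np.array([rng.uniform(0.3, 1.0), rng.uniform(0.8, 3.0)])
        t = np.tile(np.linspace(0.1, 2.0, 8), (n_subj, 1))
        dose = np.full(n_subj, 8.0)
        eta = rng.standard_normal((n_subj, 1)) * omega
        f = OneCompartmentIVBolus.predict(theta, eta, dose, t)
        y = f * (1 + sigma * rng.standard_normal(f.shape))
        return theta, omega**2, sigma, dose, t, y

    @pytest.mark.parametrize("seed", range(20))
    def test_single_eta_matches_adaptive_quadrature(self, seed):
        # one random single-subject toy model per parameter set
        theta, omega2, sigma, dose, t, y = self._toy(seed, n_subj=1)
        m2ll = foce_neg2ll_arrays(
            OneCompartmentIVBolus, theta, [omega2], sigma, dose, t, y
        )
        oracle = marginal_m2ll_gh(
            lambda e: OneCompartmentIVBolus.predict(theta, np.array([[e]]), dose[:1], t[:1])[0],
            omega2,
            sigma,
            y[0],
        )
        assert m2ll == pytest.approx(oracle, abs=0.5)

    def test_small_sigma_tightens_agreement(self):
        theta, omega2, sigma, dose, t, y = self._toy(99, sigma=0.03, n_subj=1)
        m2ll = foce_neg2ll_arrays(
            OneCompartmentIVBolus, theta, [omega2], sigma, dose, t, y
        )
        oracle = marginal_m2ll_gh(
            lambda e: OneCompartmentIVBolus.predict(theta, np.array([[e]]), dose[:1], t[:1])[0],
            omega2,
            sigma,
            y[0],
        )
        assert m2ll == pytest.approx(oracle, abs=0.1)

    def test_zero_omega_reduces_to_extended_least_squares(self, pop_truth):
        rng = np.random.default_rng(4)
        t = np.tile(np.linspace(0.05, 2.0, 9), (6, 1))
        dose = np.full(6, 8.0)
        f = TwoCompartmentIVBolus.predict(pop_truth.theta.as_array(), np.zeros((6, 3)), dose, t)
        y = f * (1 + 0.149 * rng.standard_normal(f.shape))
        sigma = 0.149
        m2ll = foce_neg2ll_arrays(
            TwoCompartmentIVBolus, pop_truth.theta.as_array(), [0.0, 0.0, 0.0], sigma, dose, t, y
        )
        # analytic ELS objective for a pure fixed-effects proportional model
        var = sigma**2 * f**2
        els = float(np.sum((y - f) ** 2 / var + np.log(2 * np.pi * var)))
        assert m2ll == pytest.approx(els, abs=1e-4)

    def test_relabeling_subjects_leaves_objective_unchanged(self, default_study, pop_truth):
        base = foce_objective(pop_truth, default_study)
        ids = list(default_study.subjects)
        rng = np.random.default_rng(8)
        shuffled = default_study.subset(rng.permutation(ids), relabel=True)
        assert foce_objective(pop_truth, shuffled) == pytest.approx(base, rel=1e-12)


class TestFit:
    def test_low_variability_recovers_theta_closely(self, pop_truth):
        pop = PopModel(theta=pop_truth.theta, omega2=(1e-6, 1e-6, 1e-6), sigma=0.01)
        data = generate_study(pop=pop, seed=5)
        fit = fit_foce(data, options=FitOptions(compute_se=False))
        est = fit.pop_hat.theta
        assert est.cl == pytest.approx(1.76, rel=0.02)
        assert est.v1 == pytest.approx(0.44, rel=0.02)
        assert est.v2 == pytest.approx(2.26, rel=0.02)
        assert est.cl2 == pytest.approx(1.0, rel=0.02)

    def test_refit_from_estimate_is_a_fixed_point(self, default_study, default_fit):
        refit = fit_foce(
            default_study, init=default_fit.pop_hat, options=FitOptions(compute_se=False)
        )
        assert refit.minus2ll == pytest.approx(default_fit.minus2ll, abs=0.01)

    def test_fit_reports_standard_errors(self, default_study):
        fit = fit_foce(default_study, options=FitOptions(se_method="hessian"))
        assert set(fit.cv_percent) == {
            "V1", "V2", "CL", "CL2", "omega_V1", "omega_CL", "omega_CL2", "sigma",
        }
        assert all(0 < v < 100 for v in fit.cv_percent.values())

    def test_deterministic_given_data_and_init(self, default_study):
        a = fit_foce(default_study, options=FitOptions(compute_se=False))
        b = fit_foce(default_study, options=FitOptions(compute_se=False))
        assert a.minus2ll == b.minus2ll
        assert a.pop_hat.theta == b.pop_hat.theta


class TestCWRES:
    def test_standard_normal_under_true_model(self, pop_truth):
        data = generate_study(pop=pop_truth, seed=31)
        gof = compute_cwres(pop_truth, data)
        cw = gof["CWRES"].to_numpy()
        assert len(cw) == 270
        assert abs(cw.mean()) < 0.2
        assert 0.7 < cw.var() < 1.35

    def test_no_extreme_residuals_across_many_studies(self, pop_truth):
        worst = 0.0
        for seed in range(40):
            data = generate_study(pop=pop_truth, seed=1000 + seed)
            cw = compute_cwres(pop_truth, data)["CWRES"].to_numpy()
            worst = max(worst, np.abs(cw).max())
        assert worst < 6.0

    def test_pred_and_ipred_columns(self, pop_truth, default_study):
        gof = compute_cwres(pop_truth, default_study)
        # PRED uses eta = 0, IPRED the subject modes: they differ subject-wise
        assert (gof["PRED"] != gof["IPRED"]).any()
        assert np.all(gof["IPRED"] > 0)
        assert np.all(gof["TAD"] == gof["TIME"])
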