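"""Synthetic-study generator: stochastic components match their nominal
distributions, study assembly matches the design, and fixed seeds are
fully reproducible."""

import numpy as np
import pandas as pd
import pytest

from oxalipk import (
    MarkerModel,
    PKParams,
    PKValidationError,
    PopModel,
    RenalEffectModel,
    StudyDesign,
    default_pop_model,
    draw_individual_params,
    generate_markers,
    generate_study,
    predict_conc,
    simulate_profile,
    simulate_urine,
)


class TestDrawIndividualParams:
    def test_zero_variability_returns_typical_values(self, pop_truth):
        pop = PopModel(theta=pop_truth.theta, omega2=(0.0, 0.0, 0.0), sigma=0.149)
        ind, eta = draw_individual_params(pop, rng=np.random.default_rng(0))
        assert ind.cl == pop.theta.cl
        assert ind.v1 == pop.theta.v1
        np.testing.assert_array_equal(eta, 0.0)

    def test_log_clearance_sd_matches_omega(self, pop_truth):
        rng = np.random.default_rng(42)
        draws = np.array(
            [draw_individual_params(pop_truth, rng=rng)[0].cl for _ in range(100_000)]
        )
        sd_log = np.std(np.log(draws))
        assert sd_log == pytest.approx(0.305, abs=0.003)
        # the median of a lognormal is the typical value
        assert np.median(draws) == pytest.approx(1.76, rel=0.01)

    def test_v2_carries_no_random_effect(self, pop_truth):
        rng = np.random.default_rng(3)
        for _ in range(5):
            ind, _ = draw_individual_params(pop_truth, rng=rng)
            assert ind.v2 == pop_truth.theta.v2

    def test_renal_effect_replaces_typical_clearance(self, pop_truth):
        renal = RenalEffectModel()
        rng = np.random.default_rng(5)
        draws = np.array(
            [
                draw_individual_params(pop_truth, cr=2.0, renal_effect=renal, rng=rng)[0].cl
                for _ in range(20_000)
            ]
        )
        assert np.median(draws) == pytest.approx(renal.typical_cl(2.0), rel=0.02)


class TestSimulateProfile:
    def test_zero_sigma_reproduces_model_exactly(self, table3_params):
        t = np.array([0.05, 0.5, 2.0])
        y, blq = simulate_profile(table3_params, 8.0, t, sigma=0.0)
        np.testing.assert_array_equal(y, predict_conc(table3_params, 8.0, t))
        assert not blq.any()

    def test_proportional_error_cv(self, table3_params):
        rng = np.random.default_rng(7)
        t = np.full(10_000, 0.5)
        y, _ = simulate_profile(table3_params, 8.0, t, sigma=0.149, rng=rng)
        assert np.std(y) / np.mean(y) == pytest.approx(0.149, abs=0.005)

    def test_outputs_finite_positive_and_blq_flagged(self, table3_params):
        rng = np.random.default_rng(11)
        t = np.linspace(0.05, 2.0, 500)
        y, blq = simulate_profile(table3_params, 3.0, t, sigma=0.8, rng=rng, lloq=0.05)
        assert np.all(np.isfinite(y))
        assert np.all(y > 0)  # redraw rule forbids non-positive observations
        np.testing.assert_array_equal(blq, y < 0.05)


class TestSimulateUrine:
    def test_terminal_amount_matches_excreted_fraction(self, table3_params):
        ae = simulate_urine(
            table3_params, 8.0, [0.5, 1, 1.5, 2, 3, 4], fe=5e-4, noise_cv=0.0
        )
        # 5e-4 of the 2400 ug absolute dose for a 0.3 kg rat
        assert ae[-1] == pytest.approx(1.2, rel=1e-9)

    def test_zero_fraction_gives_zeros(self, table3_params):
        ae = simulate_urine(table3_params, 8.0, [1, 2, 4], fe=0.0)
        np.testing.assert_array_equal(ae, 0.0)

    def test_cumulative_monotone_nondecreasing(self, table3_params):
        rng = np.random.default_rng(13)
        ae = simulate_urine(table3_params, 8.0, [0.5, 1, 1.5, 2, 3, 4], fe=5e-4, rng=rng)
        assert np.all(np.diff(ae) >= 0)

    def test_noise_is_mean_one(self, table3_params):
        rng = np.random.default_rng(17)
        totals = [
            simulate_urine(table3_params, 8.0, [4.0], fe=5e-4, rng=rng)[-1]
            for _ in range(20_000)
        ]
        assert np.mean(totals) == pytest.approx(1.2, rel=0.01)
        assert np.std(totals) == pytest.approx(0.2, rel=0.1)


class TestGenerateMarkers:
    def test_zero_sd_returns_group_means(self):
        mm = MarkerModel(
            means_sds={
                "normal": ((18.3, 0.0), (0.27, 0.0), (4.2, 0.0)),
                "mild": ((27.9, 0.0), (0.54, 0.0), (2.2, 0.0)),
                "severe": ((62.0, 0.0), (0.95, 0.0), (1.6, 0.0)),
            }
        )
        bun, cr, ccr = generate_markers("normal", mm, np.random.default_rng(0))
        assert (bun, cr, ccr) == (18.3, 0.27, 4.2)

    def test_severe_group_bun_mean(self):
        mm = MarkerModel()
        rng = np.random.default_rng(23)
        draws = np.array([generate_markers("severe", mm, rng) for _ in range(10_000)])
        assert draws[:, 0].mean() == pytest.approx(62.0, rel=0.01)
        assert np.all(draws > 0)

    def test_copula_correlates_markers_with_creatinine(self):
        mm = MarkerModel()
        rng = np.random.default_rng(29)
        draws = np.array([generate_markers("mild", mm, rng) for _ in range(5_000)])
        bun, cr, ccr = draws[:, 0], draws[:, 1], draws[:, 2]
        assert np.corrcoef(cr, bun)[0, 1] > 0.5
        assert np.corrcoef(cr, ccr)[0, 1] < -0.5


class TestGenerateStudy:
    def test_default_design_counts(self, default_study):
        assert default_study.n_subjects == 30
        assert len(default_study.plasma_observations()) == 270
        urine = default_study.urine_observations()
        doses = default_study.doses()
        assert set(doses.loc[urine["ID"].unique()]) == {8.0}
        assert len(urine) == 15 * 6  # 15 high-dose rats x 6 intervals

    def test_same_seed_identical(self):
        a = generate_study(seed=123)
        b = generate_study(seed=123)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_different_seed_differs(self):
        a = generate_study(seed=123)
        b = generate_study(seed=124)
        assert not a.df.equals(b.df)

    def test_renal_effect_builds_in_negative_cr_clearance_correlation(self, pop_truth):
        # pooled over a few studies so the small-sample correlation is stable
        rs = []
        for seed in (0, 1, 2):
            _, truth = generate_study(
                pop=pop_truth,
                renal_effect=RenalEffectModel(),
                seed=seed,
                return_truth=True,
            )
            rs.append(np.corrcoef(truth["CR"], truth["CLtot_i"])[0, 1])
        assert np.mean(rs) < -0.2

    def test_group_marker_means_converge_to_defaults(self, pop_truth):
        design = StudyDesign(n_per_arm=60)
        _, truth = generate_study(design, pop_truth, seed=7, return_truth=True)
        sev = truth[truth["group"] == "severe"]
        assert sev["CR"].mean() == pytest.approx(0.95, abs=0.04)
        assert sev["BUN"].mean() == pytest.approx(62.0, rel=0.05)
        nrm = truth[truth["group"] == "normal"]
        assert nrm["CCR"].mean() == pytest.approx(4.2, rel=0.05)

    def test_invalid_design_rejected(self):
        with pytest.raises(PKValidationError):
            StudyDesign(n_per_arm=0)
        with pytest.raises(PKValidationError):
            StudyDesign(plasma_times=(0.5, 0.4))
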