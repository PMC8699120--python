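"""Non-compartmental analysis: terminal slope, trapezoidal AUC, and the
derived clearance/volume summaries against closed-form oracles."""

import numpy as np
import pytest

from oxalipk import (
    ConcProfile,
    PKParams,
    PKValidationError,
    auc_0_inf,
    auc_closed_form,
    macro_constants,
    nca_analyze,
    nca_table,
    predict_conc,
    terminal_slope,
    urinary_excretion_fraction,
    urine_summary,
)
from oxalipk.simulate import PLASMA_TIMES


def _profile_from_model(params, dose, times, subject=1):
    return ConcProfile(
        subject=subject, dose=dose, t=np.asarray(times), c=predict_conc(params, dose, times)
    )


class TestTerminalSlope:
    def test_monoexponential_recovers_rate(self):
        t = np.linspace(0.25, 4.0, 10)
        prof = ConcProfile(subject=1, dose=1.0, t=t, c=10.0 * np.exp(-0.693 * t))
        ke, flags = terminal_slope(prof)
        assert ke == pytest.approx(0.693, rel=1e-9)
        assert not flags
        res = nca_analyze(prof)
        assert res.t_half == pytest.approx(np.log(2) / 0.693, rel=1e-9)

    def test_beta_phase_of_two_compartment_profile(self, table3_params):
        m = macro_constants(table3_params, 8.0)
        # late samples lie deep in the beta phase
        t = np.r_[np.linspace(0.05, 2.0, 9), [6.0, 9.0, 12.0]]
        prof = _profile_from_model(table3_params, 8.0, t)
        ke, _ = terminal_slope(prof, n_terminal=3)
        assert ke == pytest.approx(m.beta, rel=1e-3)

    def test_noisy_replicates_recover_beta_in_median(self, table3_params):
        m = macro_constants(table3_params, 8.0)
        rng = np.random.default_rng(19)
        t = np.r_[np.linspace(0.05, 2.0, 9), [6.0, 9.0, 12.0]]
        f = predict_conc(table3_params, 8.0, t)
        kes = []
        for _ in range(500):
            y = np.abs(f * (1.0 + 0.149 * rng.standard_normal(t.shape)))
            prof = ConcProfile(subject=1, dose=8.0, t=t, c=y)
            ke, flags = terminal_slope(prof)
            if not flags:
                kes.append(ke)
        assert np.median(kes) == pytest.approx(m.beta, rel=0.05)

    def test_rising_tail_flagged(self):
        prof = ConcProfile(subject=1, dose=1.0, t=[1.0, 2.0, 3.0], c=[1.0, 2.0, 4.0])
        ke, flags = terminal_slope(prof)
        assert ke < 0
        assert "nonpositive_terminal_slope" in flags

    def test_auto_window_selects_good_fit(self, table3_params):
        m = macro_constants(table3_params, 8.0)
        t = np.r_[np.linspace(0.05, 2.0, 9), [5.0, 7.0, 9.0, 11.0, 13.0]]
        prof = _profile_from_model(table3_params, 8.0, t)
        ke, _ = terminal_slope(prof, n_terminal="auto")
        assert ke == pytest.approx(m.beta, rel=1e-2)


class TestAUC:
    def test_two_point_trapezoid(self):
        prof = ConcProfile(subject=1, dose=1.0, t=[0.0, 1.0], c=[10.0, 6.0])
        auc_last, _ = auc_0_inf(prof, ke=1.0)
        assert auc_last == pytest.approx(8.0)

    def test_constant_profile_rectangle(self):
        prof = ConcProfile(subject=1, dose=1.0, t=[0.0, 1.0, 2.0, 3.0], c=[2.0] * 4)
        auc_last, auc_inf = auc_0_inf(prof, ke=0.5)
        assert auc_last == pytest.approx(2.0 * 3.0)
        assert auc_inf == pytest.approx(6.0 + 2.0 / 0.5)

    def test_dense_profile_recovers_closed_form(self, table3_params):
        t = np.linspace(0.01, 12.0, 400)
        prof = _profile_from_model(table3_params, 8.0, t)
        res = nca_analyze(prof)
        assert res.auc_inf == pytest.approx(auc_closed_form(table3_params, 8.0), rel=0.01)
        assert res.cl_tot == pytest.approx(1.76, rel=0.01)

    def test_redundant_interpolated_points_leave_auc_unchanged(self, table3_params):
        # start at t = 0 so the leading segment needs no back-extrapolation
        t = np.linspace(0.0, 2.0, 9)
        prof = _profile_from_model(table3_params, 8.0, t)
        ke, _ = terminal_slope(prof)
        base_last, base_inf = auc_0_inf(prof, ke)
        # insert linear interpolants halfway between each pair of samples
        t2 = np.sort(np.r_[t, (t[:-1] + t[1:]) / 2])
        c2 = np.interp(t2, t, prof.c)
        prof2 = ConcProfile(subject=1, dose=8.0, t=t2, c=c2)
        last2, inf2 = auc_0_inf(prof2, ke)
        assert last2 == pytest.approx(base_last, rel=1e-9)
        assert inf2 == pytest.approx(base_inf, rel=1e-9)

    def test_shuffled_input_sorted_internally(self, table3_params):
        t = np.linspace(0.05, 2.0, 9)
        c = predict_conc(table3_params, 8.0, t)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(t))
        a = nca_analyze(ConcProfile(subject=1, dose=8.0, t=t, c=c))
        b = nca_analyze(ConcProfile(subject=1, dose=8.0, t=t[order], c=c[order]))
        assert a.auc_inf == b.auc_inf
        assert a.ke == b.ke


class TestNCASummaries:
    def test_monoexponential_closed_form(self):
        v1, k = 0.5, 1.2
        t = np.linspace(0.01, 8.0, 300)
        prof = ConcProfile(subject=1, dose=4.0, t=t, c=4.0 / v1 * np.exp(-k * t))
        res = nca_analyze(prof)
        assert res.cl_tot == pytest.approx(k * v1, rel=0.01)
        assert res.vd == pytest.approx(v1, rel=0.01)

    def test_short_sampling_biases_clearance_high(self, table3_params):
        # the 2-h schedule truncates the terminal phase: ke over-estimates
        # beta, the extrapolated tail shrinks, and CLtot lands above the
        # model value
        prof = _profile_from_model(table3_params, 8.0, np.array(PLASMA_TIMES))
        res = nca_analyze(prof)
        assert res.cl_tot > 1.76

    def test_batch_returns_one_row_per_subject(self, default_study):
        tab = nca_table(default_study)
        assert len(tab) == 30
        assert set(tab.columns) >= {"ke", "t_half", "auc_inf", "cl_tot", "vd"}

    def test_too_few_points_rejected(self):
        with pytest.raises(PKValidationError):
            nca_analyze(ConcProfile(subject=1, dose=1.0, t=[0.5, 1.0], c=[2.0, 1.0]))


class TestUrineSummaries:
    def test_printed_study_values_satisfy_bound(self):
        # 1.2 ug excreted of a 2400 ug absolute dose -> 0.05%, below 0.1%
        fe = urinary_excretion_fraction(1.2, 2400.0)
        assert fe == pytest.approx(0.05)
        assert fe < 0.1

    def test_summary_over_generated_study(self, default_study):
        tab = urine_summary(default_study)
        assert len(tab) == 15  # high-dose rats only
        assert (tab["fe_percent"] < 0.1).all()
        assert tab["dose_total_ug"].unique() == pytest.approx([2400.0])
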