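"""Isoeffect alpha/beta estimation, Fe plot, LQ fit, isoeffect curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rilfkit import (IsoeffectPair, Schedule, alpha_beta_from_pair,
                     alpha_beta_profile, fe_plot, fit_exp_decay, fit_lq,
                     isoeffect_curve)
from rilfkit.errors import DomainError, ValidationError


def _lq_isoeffective_pairs(alpha_beta, ref_total, n_list):
    """Independent oracle: schedules with the same BED as a single dose
    of ``ref_total`` Gy, built directly from the quadratic identity."""
    bed_ref = ref_total * (1.0 + ref_total / alpha_beta)
    out = []
    for n in n_list:
        d = 0.5 * alpha_beta * (np.sqrt(1 + 4 * bed_ref / (n * alpha_beta)) - 1)
        out.append((n, d, n * d))
    return out


class TestAlphaBetaFromPair:
    def test_printed_ed50_pair(self):
        pair = IsoeffectPair(14.55, 14.55, 27.7, 27.7 / 5)
        assert alpha_beta_from_pair(pair) == pytest.approx(4.429, abs=5e-4)

    def test_exact_recovery_from_constructed_pair(self):
        (_, d2, total2), = _lq_isoeffective_pairs(3.0, 10.0, [5])
        pair = IsoeffectPair(10.0, 10.0, total2, d2)
        assert alpha_beta_from_pair(pair) == pytest.approx(3.0, abs=1e-9)

    def test_equal_fraction_sizes_return_negative_d(self):
        # d1 = d2 = d makes the identity collapse to -d (outside model
        # assumptions but algebraically exact)
        pair = IsoeffectPair(10.0, 2.0, 20.0, 2.0)
        assert alpha_beta_from_pair(pair) == pytest.approx(-2.0)

    def test_equal_totals_degenerate(self):
        with pytest.raises(DomainError):
            alpha_beta_from_pair(IsoeffectPair(10.0, 10.0, 10.0, 2.0))


class TestAlphaBetaProfile:
    def test_printed_fit_values_at_severity_landmarks(self, fit_1fx, fit_5fx):
        table, _ = alpha_beta_profile(
            fit_1fx, fit_5fx, 5, fi_grid=[3.60, 5.40, 6.48])
        ab = dict(zip(table.fi, table.alpha_beta_gy))
        assert ab[3.60] == pytest.approx(4.429, abs=5e-4)   # FI = A/2
        assert ab[5.40] == pytest.approx(4.314, abs=5e-3)   # FI = 0.75 A
        assert ab[6.48] == pytest.approx(4.253, abs=5e-3)   # FI = 0.90 A

    def test_midpoint_doses_are_the_ed50s(self, fit_1fx, fit_5fx):
        table, _ = alpha_beta_profile(fit_1fx, fit_5fx, 5, fi_grid=[3.60])
        assert table.d1_gy.iloc[0] == pytest.approx(14.55, abs=1e-9)
        assert table.d2_gy.iloc[0] == pytest.approx(27.7, abs=1e-9)

    def test_profile_monotone_decreasing_over_effective_range(self, fit_1fx,
                                                              fit_5fx):
        grid = np.linspace(0.5, 7.0, 131)
        table, _ = alpha_beta_profile(fit_1fx, fit_5fx, 5, fi_grid=grid)
        assert np.all(np.diff(table.alpha_beta_gy) < 0)

    def test_summary_reports_mean_and_sd(self, fit_1fx, fit_5fx):
        table, summary = alpha_beta_profile(fit_1fx, fit_5fx, 5)
        assert summary["n_levels"] == len(table)
        assert summary["alpha_beta_mean_gy"] == pytest.approx(
            float(table.alpha_beta_gy.mean()))

    def test_grid_outside_domain_rejected(self, fit_1fx, fit_5fx):
        with pytest.raises(DomainError):
            alpha_beta_profile(fit_1fx, fit_5fx, 5, fi_grid=[7.3])


class TestFePlot:
    def test_two_point_line_equals_pair_identity(self):
        points = [(14.55, 14.55), (27.7 / 5, 27.7)]
        fe = fe_plot(points)
        pair = IsoeffectPair(14.55, 14.55, 27.7, 27.7 / 5)
        assert fe.alpha_beta == pytest.approx(alpha_beta_from_pair(pair),
                                              abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(ab=st.floats(1.0, 15.0), ref=st.floats(8.0, 25.0))
    def test_exact_recovery_from_lq_isoeffective_schedules(self, ab, ref):
        pts = [(d, total)
               for _, d, total in _lq_isoeffective_pairs(ab, ref, [1, 2, 5, 10])]
        fe = fe_plot(pts)
        assert fe.alpha_beta == pytest.approx(ab, abs=1e-9)
        assert fe.residual_ss == pytest.approx(0.0, abs=1e-15)

    def test_identical_fraction_sizes_rank_deficient(self):
        with pytest.raises(ValidationError):
            fe_plot([(2.0, 10.0), (2.0, 20.0)])


class TestFitLq:
    SCHEDULES = [(d, d) for d in (10.5, 12.5, 14.5, 17.5, 20.0)] + \
                [(5 * d, d) for d in (2.0, 4.0, 6.0, 7.0, 8.5)]

    def test_exact_recovery_on_noise_free_data(self):
        alpha, beta, c = 0.0480, 0.0107, 0.9
        sched = np.array(self.SCHEDULES)
        y = c - (alpha * sched[:, 0] + beta * sched[:, 1] * sched[:, 0])
        fit = fit_lq(sched, 10.0 ** (-y))  # -log10 undoes this exactly
        assert fit.alpha == pytest.approx(alpha, abs=1e-9)
        assert fit.beta == pytest.approx(beta, abs=1e-9)
        assert fit.alpha_beta == pytest.approx(alpha / beta, rel=1e-9)

    def test_printed_parameter_ratios(self):
        assert 0.0150 / 0.0038 == pytest.approx(3.9474, abs=5e-5)
        assert 0.0480 / 0.0107 == pytest.approx(4.4879, rel=1e-3)

    def test_ratio_invariant_to_log_base(self):
        sched = np.array(self.SCHEDULES)
        rng = np.random.default_rng(0)
        fis = np.clip(rng.uniform(0.1, 7.0, len(sched)), 0.05, None)
        fit10 = fit_lq(sched, fis)
        fit_e = fit_lq(sched, fis,
                       transform=lambda f: -np.log(np.maximum(f, 0.05)))
        assert fit_e.alpha == pytest.approx(fit10.alpha * np.log(10), rel=1e-9)
        assert fit_e.alpha_beta == pytest.approx(fit10.alpha_beta, rel=1e-9)

    def test_single_fraction_size_unidentifiable(self):
        with pytest.raises(ValidationError):
            fit_lq([(10.0, 2.0), (20.0, 2.0), (30.0, 2.0)], [1.0, 2.0, 3.0])

    def test_too_few_schedules(self):
        with pytest.raises(ValidationError):
            fit_lq([(10.0, 10.0)], [1.0])


class TestIsoeffectCurve:
    def test_reference_fraction_number_returns_reference(self):
        ref = Schedule.from_nd(1, 14.55)
        (n, d, total), = isoeffect_curve(4.49, ref, [1])
        assert (n, d, total) == (1, pytest.approx(14.55), pytest.approx(14.55))

    def test_five_fraction_equivalent_of_single_ed50(self):
        ref = Schedule.from_nd(1, 14.55)
        (_, d, total), = isoeffect_curve(4.49, ref, [5])
        # positive root of 5d(1 + d/4.49) = 14.55(1 + 14.55/4.49)
        assert d == pytest.approx(5.5297, abs=1e-3)
        # cross-check: BED equality
        assert total * (1 + d / 4.49) == pytest.approx(
            14.55 * (1 + 14.55 / 4.49), abs=1e-9)

    def test_lq_sparing_monotonicity(self):
        ref = Schedule.from_nd(1, 14.55)
        curve = isoeffect_curve(4.49, ref, range(1, 11))
        d = [row[1] for row in curve]
        total = [row[2] for row in curve]
        assert np.all(np.diff(d) < 0)
        assert np.all(np.diff(total) > 0)

    def test_invalid_alpha_beta(self):
        with pytest.raises(ValidationError):
            isoeffect_curve(0.0, Schedule.from_nd(1, 10.0), [2])


class TestFitExpDecay:
    def test_exact_recovery(self):
        x = np.linspace(0.0, 20.0, 21)
        y = 2.0 * np.exp(-x / 5.0) + 1.0
        a, b, c = fit_exp_decay(x, y)
        assert (a, b, c) == (pytest.approx(2.0, abs=1e-6),
                             pytest.approx(5.0, abs=1e-6),
                             pytest.approx(1.0, abs=1e-6))

    def test_constant_data_gives_flat_fit(self):
        x = np.linspace(0.0, 10.0, 11)
        a, b, c = fit_exp_decay(x, np.full(11, 3.0))
        assert abs(a) < 1e-6
        assert c == pytest.approx(3.0, abs=1e-6)

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0.0, 20.0, 40)
        sigma = 0.05
        y = 2.0 * np.exp(-x / 5.0) + 1.0 + rng.normal(0, sigma, len(x))
        a, b, c = fit_exp_decay(x, y)
        # loose 3-sigma-style envelope from the known noise level
        assert a == pytest.approx(2.0, abs=0.15)
        assert b == pytest.approx(5.0, abs=0.8)
        assert c == pytest.approx(1.0, abs=0.1)


class TestSchedule:
    def test_consistency_enforced(self):
        with pytest.raises(ValidationError):
            Schedule(5, 6.0, 29.0)

    def test_from_nd(self):
        s = Schedule.from_nd(5, 5.54)
        assert s.total_dose == pytest.approx(27.7)
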