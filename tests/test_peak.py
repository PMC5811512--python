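"""Peak existence criteria, closed-form peak time/height, and the numeric
argmax oracle."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from openblock import (
    NoPeakError,
    RateSet,
    analyze_peak,
    build_generator,
    peak_exists_3state,
    peak_exists_4state,
    peak_exists_spectral,
    peak_numeric,
    peak_time_3state,
    psi_3state,
    psi_limit,
    psi_simplified,
    slowest_preexponential,
)
from conftest import random_rates


class TestExistenceCriteria:
    def test_spectral_criterion_examples(self, worked_example):
        assert peak_exists_spectral(worked_example)
        # delta + r_slow = 2 - 1 > 0: monotone waveform
        assert not peak_exists_spectral(RateSet(1, 0, 1, 2))

    def test_spectral_criterion_independent_of_gamma(self):
        assert peak_exists_spectral(RateSet(2, 1, 0.1, 1))
        assert peak_exists_spectral(RateSet(2, 1, 10, 1))

    def test_gamma_zero_means_no_peak(self):
        assert not peak_exists_spectral(RateSet(3, 0, 0, 1))
        assert not peak_exists_3state(RateSet(3, 0, 0, 1))

    def test_three_state_rule_is_alpha_exceeds_delta(self):
        assert peak_exists_3state(RateSet(2, 1, 1, 1))
        assert not peak_exists_3state(RateSet(1, 1, 1, 1))  # boundary excluded
        with pytest.raises(ValueError):
            peak_exists_3state(RateSet(2, 1, 1, 1, m=2))

    def test_four_state_rule_reduces_to_alpha_exceeds_delta_at_beta_zero(self):
        assert peak_exists_4state(RateSet(1.01, 0, 1, 1, m=2))
        assert not peak_exists_4state(RateSet(0.99, 0, 1, 1, m=2))
        with pytest.raises(ValueError):
            peak_exists_4state(RateSet(2, 1, 1, 1, m=1))

    def test_four_state_boundary_at_unit_rates(self):
        # boundary delta solves delta^2 - 4 delta + 2 = 0 -> 2 - sqrt(2)
        dstar = 2.0 - math.sqrt(2.0)
        assert peak_exists_4state(RateSet(1, 1, 1, dstar - 1e-6, m=2))
        assert not peak_exists_4state(RateSet(1, 1, 1, dstar + 1e-6, m=2))
        # confirm by bisection on the spectral criterion
        f = lambda d: 1.0 if peak_exists_spectral(RateSet(1, 1, 1, d, m=2)) else -1.0
        root = brentq(f, 0.1, 1.5, xtol=1e-9)
        assert root == pytest.approx(dstar, abs=1e-6)

    @pytest.mark.parametrize("m,closed_form", [
        (1, peak_exists_3state), (2, peak_exists_4state)])
    def test_closed_form_matches_spectral_criterion(self, m, closed_form, rng):
        agree = 0
        total = 300
        for _ in range(total):
            rs = random_rates(rng, m=m)
            # skip the epsilon-band around the existence boundary
            evals_slow = None
            try:
                pre = slowest_preexponential(rs)
            except Exception:
                continue
            if abs(pre) < 1e-8:
                continue
            assert closed_form(rs) == peak_exists_spectral(rs)
            agree += 1
        assert agree > total // 2


class TestPeakTime:
    def test_worked_example_is_ln_two(self, worked_example):
        assert peak_time_3state(worked_example) == pytest.approx(math.log(2),
                                                                 rel=1e-12)

    def test_no_peak_raises(self):
        with pytest.raises(NoPeakError):
            peak_time_3state(RateSet(1, 0, 1, 2))

    def test_matches_numeric_argmax(self, rng):
        checked = 0
        while checked < 100:
            rs = random_rates(rng)
            if not peak_exists_3state(rs):
                continue
            try:
                tp = peak_time_3state(rs)
            except Exception:
                continue
            gen = build_generator(rs)
            tp_num, _ = peak_numeric(gen)
            assert tp == pytest.approx(tp_num, rel=1e-8)
            checked += 1

    def test_degenerate_spectrum_falls_back_to_numeric(self):
        # (2, 0, 1, 1): double eigenvalue -2; O(t) = 0.5 + (t - 0.5) e^{-2t}...
        tp = peak_time_3state(RateSet(2, 0, 1, 1))
        assert tp == pytest.approx(1.0, rel=1e-6)


class TestPsi:
    def test_worked_example(self, worked_example):
        assert psi_3state(worked_example) == pytest.approx(0.25, rel=1e-12)

    def test_simplified_formula_values(self):
        assert psi_simplified(3.0, 1.0) == pytest.approx(0.25, rel=1e-12)
        assert psi_simplified(4.0, 1.0) == pytest.approx(1.0 / 3.0, rel=1e-12)
        with pytest.raises(ValueError):
            psi_simplified(2.0, 1.0)
        with pytest.raises(ValueError):
            psi_simplified(3.0, 0.0)

    def test_simplified_equals_full_closed_form(self, rng):
        checked = 0
        while checked < 100:
            d = float(10.0 ** rng.uniform(-1, 1))
            a = d * float(10.0 ** rng.uniform(0.35, 1.5))  # alpha > 2 delta
            rs = RateSet(a, 0.0, d, d)
            try:
                full = psi_3state(rs)
            except Exception:
                continue
            assert psi_simplified(a, d) == pytest.approx(full, rel=1e-10)
            checked += 1

    def test_consistent_with_numeric_peak_height(self, rng):
        checked = 0
        while checked < 100:
            rs = random_rates(rng)
            if not peak_exists_3state(rs):
                continue
            try:
                psi = psi_3state(rs)
            except Exception:
                continue
            gen = build_generator(rs)
            from openblock import steady_state
            _, op = peak_numeric(gen)
            oss = steady_state(gen)[gen.open_index]
            assert psi == pytest.approx(op / oss - 1.0, rel=1e-6)
            checked += 1


class TestPsiLimits:
    def test_tabulated_limits(self):
        rs = RateSet(3.0, 0.5, 2.0, 1.0)
        assert psi_limit("alpha", "to_infinity", rs) == pytest.approx(2.0)
        assert psi_limit("alpha", "to_zero", rs) == 0.0
        assert psi_limit("beta", "to_infinity", rs) == 0.0
        assert psi_limit("gamma", "to_infinity", rs) == pytest.approx(2.0)
        assert psi_limit("gamma", "to_zero", rs) == 0.0
        assert psi_limit("delta", "to_infinity", rs) == 0.0
        assert psi_limit("delta", "to_zero", rs) == math.inf

    def test_beta_to_zero_is_numeric_value_at_zero(self):
        rs = RateSet(3.0, 0.5, 1.0, 1.0)
        assert psi_limit("beta", "to_zero", rs) == pytest.approx(
            psi_3state(rs.with_(beta=0.0)), rel=1e-12)
        # no peak at beta = 0 when alpha <= delta
        assert psi_limit("beta", "to_zero", RateSet(1.0, 0.5, 1.0, 2.0)) == 0.0

    def test_unknown_selector_rejected(self):
        rs = RateSet(1, 1, 1, 1)
        with pytest.raises(ValueError):
            psi_limit("epsilon", "to_zero", rs)
        with pytest.raises(ValueError):
            psi_limit("alpha", "sideways", rs)
        with pytest.raises(ValueError):
            psi_limit("alpha", "to_zero", RateSet(1, 1, 1, 1, m=2))

    def test_numeric_psi_approaches_alpha_to_infinity_limit(self):
        base = RateSet(1.0, 0.5, 2.0, 1.0)
        limit = psi_limit("alpha", "to_infinity", base)
        psis = [psi_3state(base.with_(alpha=a)) for a in 10.0 ** np.arange(1, 7)]
        errs = np.abs(np.array(psis) - limit)
        assert np.all(np.diff(errs) < 0)
        assert errs[-1] < 1e-4


class TestPeakNumeric:
    def test_worked_example(self, worked_example):
        gen = build_generator(worked_example)
        tp, op = peak_numeric(gen)
        assert tp == pytest.approx(math.log(2), abs=1e-8)
        assert op == pytest.approx(0.625, abs=1e-10)

    def test_monotone_waveform_has_no_interior_peak(self):
        with pytest.raises(NoPeakError):
            peak_numeric(build_generator(RateSet(1, 0, 1, 2)))

    def test_result_stable_under_refinement(self, worked_example):
        gen = build_generator(worked_example)
        tp1, op1 = peak_numeric(gen)
        tp2, op2 = peak_numeric(gen)  # deterministic: identical
        assert tp1 == tp2 and op1 == op2


class TestAnalyzePeak:
    def test_worked_example_report(self, worked_example):
        rep = analyze_peak(worked_example)
        assert rep.exists
        assert rep.t_p == pytest.approx(math.log(2), rel=1e-12)
        assert rep.O_p == pytest.approx(0.625, rel=1e-10)
        assert rep.psi == pytest.approx(0.25, rel=1e-10)
        assert rep.O_ss == pytest.approx(0.5, rel=1e-10)
        assert rep.r_slow == pytest.approx(-2.0, abs=1e-10)

    def test_monotone_case(self):
        rep = analyze_peak(RateSet(1, 0, 1, 2))
        assert not rep.exists
        assert rep.t_p is None and rep.psi is None
        assert rep.r_slow == pytest.approx(-1.0, abs=1e-10)

    def test_peak_height_identity_holds(self, rng):
        checked = 0
        while checked < 60:
            m = int(rng.integers(1, 4))
            rs = random_rates(rng, m=m)
            rep = analyze_peak(rs)
            if not rep.exists:
                continue
            assert rep.O_p == pytest.approx((1 + rep.psi) * rep.O_ss, rel=1e-9)
            assert rep.t_p > 0
            assert rep.O_p > rep.O_ss
            checked += 1

    def test_gamma_zero_rejected(self):
        with pytest.raises(ValueError):
            analyze_peak(RateSet(3, 0, 0, 1))

    def test_report_serialization(self, worked_example):
        import json

        rep = analyze_peak(worked_example)
        d = json.loads(rep.to_json())
        assert d["exists"] is True and d["alpha"] == 3
        row = rep.to_csv_row()
        assert row.startswith("3,0,1,1,1,true,")
        assert len(row.split(",")) == len(rep.csv_header().split(","))


class TestGammaInvariance:
    """The existence decision never depends on the association rate."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    rate = st.floats(min_value=1e-2, max_value=1e2, allow_nan=False)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(alpha=rate, beta=rate, delta=rate, gamma_exp=st.integers(-3, 3),
           m=st.integers(min_value=1, max_value=4))
    def test_existence_unchanged_by_gamma(self, alpha, beta, delta,
                                          gamma_exp, m):
        base = peak_exists_spectral(RateSet(alpha, beta, 1.0, delta, m))
        moved = peak_exists_spectral(
            RateSet(alpha, beta, 10.0 ** gamma_exp, delta, m))
        assert base == moved


class TestBoundaryTrendWithGateCount:
    def test_boundary_delta_shrinks_as_m_grows(self):
        """With beta > 0, adding closed states shrinks the region of
        dissociation rates that still yields a peak."""
        alpha, beta, gamma = 1.0, 0.5, 1.0

        def boundary(m):
            f = lambda d: 1.0 if peak_exists_spectral(
                RateSet(alpha, beta, gamma, d, m)) else -1.0
            return brentq(f, 1e-3, 2.0, xtol=1e-9)

        bounds = [boundary(m) for m in (1, 2, 3, 4)]
        assert all(b1 > b2 for b1, b2 in zip(bounds, bounds[1:]))
        assert bounds[0] == pytest.approx(1.0, abs=1e-6)
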