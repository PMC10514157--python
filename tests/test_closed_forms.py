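"""Closed-form quantities, cross-checked symbolically and numerically."""

import math

import numpy as np
import pytest
import sympy as sp

from twopatch import (
    ParameterError,
    PatchParams,
    continuous_limits,
    delta_max,
    delta_tilde,
    equilibrium_continuous,
    equilibrium_discrete,
    equilibrium_full_exchange,
    h_prime_zero,
    kappa_continuous,
    kappa_discrete,
    max_population_summary,
    numeric_argmax_H,
    numeric_zero_H,
    quadratic_and_nbar,
    response_curve,
    summarize,
)


def _sympy_delta_tilde(rA, rB, KA, KB):
    """Independent symbolic evaluation of the nontrivial-zero expression."""
    rA, rB, KA, KB = map(sp.Rational, (rA, rB, KA, KB))
    num = KA * KB * (rA - 1) * (rB - 1) * (rA - rB)
    den = (KA * (rB - 1) + KB * (rA - 1)) * (KA * rA * (rB - 1) - KB * rB * (rA - 1))
    return sp.nsimplify(num / den)


class TestDeltaTilde:
    def test_worked_value(self, turning_discrete):
        # 26.23824 / 69.997824 for this parameter set
        assert delta_tilde(turning_discrete) == pytest.approx(0.3748438, abs=1e-6)

    def test_matches_symbolic_evaluation(self, turning_discrete):
        p = turning_discrete
        exact = float(_sympy_delta_tilde("3.4", "1.5", "8.4", "1.37"))
        assert delta_tilde(p) == pytest.approx(exact, rel=1e-14)

    def test_matches_numeric_bisection(self, turning_discrete):
        assert delta_tilde(turning_discrete) == pytest.approx(
            numeric_zero_H(turning_discrete), abs=1e-6
        )

    def test_simplifies_to_half_on_special_ray(self):
        """K_B/K_A = (r_B-1)/(r_A-1) collapses the expression to 1/2."""
        p = PatchParams(3.0, 1.5, 2.0, 0.5)
        assert delta_tilde(p) == pytest.approx(0.5, rel=1e-14)
        exact = _sympy_delta_tilde(3, sp.Rational(3, 2), 2, sp.Rational(1, 2))
        assert exact == sp.Rational(1, 2)

    def test_equal_growth_rates_have_no_second_zero(self):
        assert delta_tilde(PatchParams(2.0, 2.0, 1.0, 2.0)) is None

    def test_out_of_range_values_return_none(self, mono_beneficial_discrete):
        assert delta_tilde(mono_beneficial_discrete) is None

    def test_equal_capacities_rejected(self):
        with pytest.raises(ParameterError):
            delta_tilde(PatchParams(3.0, 1.5, 2.0, 2.0))

    def test_swap_invariance(self, turning_discrete):
        assert delta_tilde(turning_discrete.swapped()) == pytest.approx(
            delta_tilde(turning_discrete), rel=1e-12
        )


class TestQuadraticAndNbar:
    def test_equal_growth_rates_give_capacity(self):
        p = PatchParams(2.0, 2.0, 1.0, 2.5)
        *_, nbar_B, nbar_A = quadratic_and_nbar(p)
        assert nbar_B == pytest.approx(2.5, rel=1e-12)
        assert nbar_A == pytest.approx(1.0, rel=1e-12)

    def test_coefficient_signs_give_one_positive_root(self, unimodal_discrete):
        a, _, c, nbar_B, _ = quadratic_and_nbar(unimodal_discrete)
        assert a > 0 and c < 0
        assert nbar_B > 0

    def test_nbar_total_matches_numeric_maximum(self, unimodal_discrete):
        *_, nbar_B, nbar_A = quadratic_and_nbar(unimodal_discrete)
        _, h_max = numeric_argmax_H(unimodal_discrete, (0.0, 1.0))
        K_sum = unimodal_discrete.K_A + unimodal_discrete.K_B
        assert nbar_A + nbar_B == pytest.approx(h_max + K_sum, abs=1e-6)

    def test_matches_symbolic_quadratic(self):
        """The implemented coefficients agree with an independent symbolic
        build of the same quadratic on a rational parameter set."""
        rA, rB, KA, KB = sp.Rational(16, 5), sp.Rational(3, 2), sp.Rational(77, 20), sp.Rational(137, 100)
        sA, sB = sp.sqrt(rA), sp.sqrt(rB)
        a_sym = (rB - 1) * (KA * sA * (rB - 1) + KB * sB * (rA - 1))
        b_sym = KB * (rB - 1) * (2 * KA * sA - (KA - KB + (KA + KB) * rA) * sB)
        c_sym = -KA * KB**2 * (sA - sB) * (sA * sB - 1)
        p = PatchParams(3.2, 1.5, 3.85, 1.37)
        a, b, c, *_ = quadratic_and_nbar(p)
        assert a == pytest.approx(float(a_sym), rel=1e-12)
        assert b == pytest.approx(float(b_sym), rel=1e-12)
        assert c == pytest.approx(float(c_sym), rel=1e-12)


class TestDeltaMax:
    def test_interior_maximum_below_mixing(self, unimodal_discrete):
        dm = delta_max(unimodal_discrete)
        assert 0.0 < dm < 0.5
        d_star, _ = numeric_argmax_H(unimodal_discrete, (0.0, 1.0))
        assert dm == pytest.approx(d_star, abs=1e-4)

    def test_interior_maximum_beyond_mixing(self, beyond_mixing_discrete):
        dm = delta_max(beyond_mixing_discrete)
        assert 0.5 < dm < 1.0
        d_star, _ = numeric_argmax_H(beyond_mixing_discrete, (0.0, 1.0))
        assert dm == pytest.approx(d_star, abs=1e-4)

    def test_equal_growth_rates_pin_maximum_at_zero(self):
        assert delta_max(PatchParams(2.0, 2.0, 1.0, 2.0)) == pytest.approx(0.0, abs=1e-12)

    def test_crosses_half_exactly_at_kappa_rho_boundary(self):
        """delta_max = 0.5 when K_B/K_A sits exactly on kappa*(r_B-1)/(r_A-1),
        validating the >1 orientation of the threshold constant."""
        p_ref = PatchParams(3.0, 1.5, 2.0, 1.5)
        rho = 0.5 / 2.0
        boundary_ratio = kappa_discrete(p_ref) * rho
        p = PatchParams(3.0, 1.5, 2.0, 2.0 * boundary_ratio)
        assert delta_max(p) == pytest.approx(0.5, abs=1e-10)


class TestHPrimeZero:
    def test_worked_value(self, mono_beneficial_discrete):
        assert h_prime_zero(mono_beneficial_discrete) == pytest.approx(0.75)

    @pytest.mark.parametrize(
        "params",
        [PatchParams(3.0, 1.5, 2.0, 2.0), PatchParams(2.0, 2.0, 1.0, 3.0)],
    )
    def test_vanishes_on_degenerate_rays(self, params):
        assert h_prime_zero(params) == 0.0

    def test_matches_finite_difference_on_random_draws(self):
        from twopatch import H_discrete

        rng = np.random.default_rng(13)
        for _ in range(10):
            rA, rB = rng.uniform(1.3, 4.0, 2)
            KA, KB = rng.uniform(0.3, 4.0, 2)
            p = PatchParams(rA, rB, KA, KB)
            h = 1e-6
            fd = H_discrete(p, h) / h
            assert fd == pytest.approx(h_prime_zero(p), abs=1e-4)


class TestMaxPopulationSummary:
    def test_full_exchange_case(self, mono_beneficial_discrete):
        mx, amx, NA1, NB1 = max_population_summary(mono_beneficial_discrete)
        assert amx == 1.0
        assert NA1 == pytest.approx(1.75, rel=1e-12)
        assert NB1 == pytest.approx(21.0 / 11.0, rel=1e-12)
        eq = equilibrium_discrete(mono_beneficial_discrete, 1.0)
        assert (NA1, NB1) == pytest.approx(eq.as_tuple(), abs=1e-8)
        assert mx == pytest.approx(NA1 + NB1, rel=1e-12)

    def test_disconnected_case(self, mono_detrimental_discrete):
        mx, amx, *_ = max_population_summary(mono_detrimental_discrete)
        assert amx == 0.0
        assert mx == pytest.approx(2.25)

    def test_interior_case(self, unimodal_discrete):
        mx, amx, *_ = max_population_summary(unimodal_discrete)
        assert 0.0 < amx < 1.0
        *_, nbar_B, nbar_A = quadratic_and_nbar(unimodal_discrete)
        assert mx == pytest.approx(nbar_A + nbar_B, rel=1e-12)

    @pytest.mark.parametrize(
        "fixture",
        ["mono_beneficial_discrete", "unimodal_discrete", "turning_discrete",
         "mono_detrimental_discrete", "beyond_mixing_discrete"],
    )
    def test_numeric_curve_never_beats_closed_form(self, fixture, request):
        """The 201-point numeric maximum stays below max_total and reaches
        it to within discretization error."""
        p = request.getfixturevalue(fixture)
        mx, *_ = max_population_summary(p)
        curve = response_curve(p)
        totals = curve.N_A + curve.N_B
        assert totals.max() <= mx + 1e-6
        d_star, h_star = numeric_argmax_H(p, (0.0, 1.0))
        assert h_star + p.K_A + p.K_B == pytest.approx(mx, abs=1e-4)

    def test_eq8_matches_symbolic_fixed_point(self):
        """Full-exchange equilibrium agrees with solving N_A = f_B(N_B),
        N_B = f_A(N_A) symbolically."""
        rA, rB, KA, KB = sp.Rational(3), sp.Rational(3, 2), sp.Rational(2), sp.Rational(3, 2)
        NA, NB = sp.symbols("NA NB", positive=True)
        xiA, xiB = (rA - 1) / KA, (rB - 1) / KB
        sols = sp.solve(
            [sp.Eq(NA, rB * NB / (1 + xiB * NB)), sp.Eq(NB, rA * NA / (1 + xiA * NA))],
            [NA, NB],
            dict=True,
        )
        positive = [s for s in sols if s[NA] > 0 and s[NB] > 0]
        assert len(positive) == 1
        NA1, NB1 = equilibrium_full_exchange(PatchParams(3.0, 1.5, 2.0, 1.5))
        assert NA1 == pytest.approx(float(positive[0][NA]), rel=1e-12)
        assert NB1 == pytest.approx(float(positive[0][NB]), rel=1e-12)


class TestThresholdConstants:
    def test_kappa_discrete_worked_values(self):
        assert kappa_discrete(PatchParams(3.0, 1.5, 2.0, 1.5)) == pytest.approx(
            (3.0 + math.sqrt(4.5) - 2.0) / (1.5 + math.sqrt(4.5) - 2.0)
        )
        assert kappa_discrete(PatchParams(3.2, 1.5, 1.0, 2.0)) == pytest.approx(
            2.0054, abs=1e-4
        )

    def test_kappa_tends_to_one_for_similar_rates(self):
        assert kappa_discrete(PatchParams(2.0, 1.999, 1.0, 2.0)) == pytest.approx(
            1.0, abs=1e-2
        )

    def test_kappa_rejects_equal_rates(self):
        with pytest.raises(ParameterError):
            kappa_discrete(PatchParams(2.0, 2.0, 1.0, 2.0))

    def test_kappa_continuous_worked_value(self):
        assert kappa_continuous(0.5, 2.0) == pytest.approx(6.5 / 3.5)

    def test_kappa_continuous_exceeds_one(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            rA, rB = rng.uniform(0.05, 5.0, 2)
            if rA == rB:
                continue
            assert kappa_continuous(rA, rB) > 1.0


class TestContinuousLimits:
    def test_worked_mixing_limit(self, turning_continuous):
        lim = continuous_limits(turning_continuous)
        assert lim.H_inf == pytest.approx(-0.2, rel=1e-12)
        eq = equilibrium_continuous(turning_continuous, 1e4)
        K_sum = turning_continuous.K_A + turning_continuous.K_B
        assert eq.total - K_sum == pytest.approx(lim.H_inf, rel=1e-3)

    def test_requires_canonical_order(self, mono_detrimental_continuous):
        with pytest.raises(ParameterError):
            continuous_limits(mono_detrimental_continuous)  # K_A > K_B

    def test_equal_capacity_limits_vanish(self):
        s = summarize(PatchParams(1.0, 2.0, 1.5, 1.5, "continuous"))
        assert s.H_inf == 0.0 and s.H_prime_zero == 0.0 and s.Hprime_inf_criterion == 0.0


class TestSignEquivalences:
    def test_delta_tilde_window_matches_capacity_ratio_bands(self):
        """The nontrivial zero lies in (0,1] exactly when the capacity
        ratio falls below sqrt(r_A)(r_B-1)/(sqrt(r_B)(r_A-1)); between that
        and r_A(r_B-1)/(r_B(r_A-1)) the raw expression is >= 1."""
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 40:
            rA = rng.uniform(1.5, 4.0)
            rB = rng.uniform(1.2, rA - 0.1)
            KA = rng.uniform(0.5, 4.0)
            ratio = rng.uniform(0.02, 1.5)
            if abs(ratio - 1.0) < 1e-3:
                continue
            p = PatchParams(rA, rB, KA, KA * ratio)
            upper = rA * (rB - 1.0) / (rB * (rA - 1.0))
            lower = math.sqrt(rA) * (rB - 1.0) / (math.sqrt(rB) * (rA - 1.0))
            if abs(ratio - upper) < 1e-6 or abs(ratio - lower) < 1e-6:
                continue
            dt = delta_tilde(p)
            if ratio < lower:
                assert dt is not None and 0.0 < dt < 1.0
            else:
                assert dt is None  # raw expression negative or >= 1
            checked += 1


class TestSummarize:
    def test_discrete_summary_fields(self, turning_discrete):
        s = summarize(turning_discrete)
        assert s.mode == "discrete"
        assert s.delta_tilde == pytest.approx(0.3748438, abs=1e-6)
        assert s.kappa is not None and s.kappa > 1.0
        assert s.max_total is not None

    def test_continuous_summary_fields(self, mono_beneficial_continuous):
        s = summarize(mono_beneficial_continuous)
        assert s.mode == "continuous"
        assert s.kappa_c == pytest.approx(6.5 / 3.5)
        assert s.H_inf is not None and s.H_inf > 0
        d = s.to_dict()
        assert d["kappa_c"] == s.kappa_c
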