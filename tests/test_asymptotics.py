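"""Periodic attractors, invasion quantities and the outcome classifier."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from phenofluct import (BOTH_EXTINCT, H_WINS, L_WINS, FitnessModel,
                        NutrientSignal, PopulationSpec, classify_outcome,
                        competition_map, invasion_lambda,
                        invasion_lambda_lag_form, periodic_mean_trait,
                        periodic_size, survival_threshold)
from phenofluct.errors import (AnalyticPreconditionError,
                               SurvivalHypothesisError)


class TestPeriodicMeanTrait:
    def test_constant_environment_gives_fittest_state(self, model, pair,
                                                      constant_signal):
        u = periodic_mean_trait(pair[1], model, constant_signal)
        assert u.time_average == pytest.approx(model.phi(1.0))

    def test_flat_periodic_signal_reproduced_exactly(self, model, pair):
        sig = NutrientSignal("sinusoidal", M=1.0, A=0.0, T=5.0)
        u = periodic_mean_trait(pair[1], model, sig)
        np.testing.assert_allclose(u.values, model.phi(1.0), rtol=1e-13)

    def test_periodicity_and_bounds(self, model, pair, high_variability_signal):
        for spec in pair:
            u = periodic_mean_trait(spec, model, high_variability_signal)
            assert abs(u.values[0] - u.values[-1]) < 1e-8 * abs(u.values[0])
            phi = model.phi(high_variability_signal(u.t))
            assert u.values.min() >= phi.min() - 1e-9
            assert u.values.max() <= phi.max() + 1e-9

    def test_satisfies_relaxation_ode(self, model, pair, high_variability_signal):
        # residual of u' = 2 sqrt(gamma beta) (phi - u) below 1e-4 sup norm
        u = periodic_mean_trait(pair[0], model, high_variability_signal)
        a = np.sqrt(model.gamma * pair[0].beta)
        du = np.gradient(u.values, u.t)
        res = du - 2.0 * a * (model.phi(high_variability_signal(u.t)) - u.values)
        assert np.abs(res[1:-1]).max() < 1e-4

    def test_mean_value_identity(self, model, pair, signals):
        # time average of u equals time average of phi on every fixture
        for sig in (signals["low"], signals["high"]):
            for spec in pair:
                u = periodic_mean_trait(spec, model, sig)
                phi_avg = np.trapezoid(model.phi(sig(u.t)), u.t) / sig.T
                assert u.time_average == pytest.approx(phi_avg, abs=1e-9)

    def test_requires_equal_proliferation_rates(self, pair, high_variability_signal):
        skew = FitnessModel(gamma=100.0, zeta=50.0, d=0.01)
        with pytest.raises(AnalyticPreconditionError):
            periodic_mean_trait(pair[0], skew, high_variability_signal)


class TestInvasionLambda:
    def test_constant_signal_reduces_to_sqrt_beta(self, model, pair,
                                                  constant_signal):
        assert invasion_lambda(pair[1], model, constant_signal) == 0.1
        assert invasion_lambda(pair[0], model, constant_signal) == \
            pytest.approx(np.sqrt(0.025))

    def test_flat_periodic_signal_reduces_to_sqrt_beta(self, model, pair):
        sig = NutrientSignal("sinusoidal", M=1.0, A=0.0, T=5.0)
        assert invasion_lambda(pair[1], model, sig) == pytest.approx(0.1, abs=1e-12)

    def test_dual_formulas_agree(self, model, pair, high_variability_signal):
        # quadratic-lag and lag-velocity forms of Lambda agree to 1e-6 relative
        for spec in pair:
            l_quad = invasion_lambda(spec, model, high_variability_signal)
            l_lag = invasion_lambda_lag_form(spec, model, high_variability_signal)
            assert abs(l_quad - l_lag) / l_quad < 1e-6

    @given(M=st.floats(0.1, 50.0), frac=st.floats(0.0, 1.0),
           T=st.floats(1.0, 20.0), beta=st.floats(0.005, 0.1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_dual_formulas_agree_randomized(self, model, M, frac, T, beta):
        # agreement is limited by the O(n_quad^-2) period quadrature; the
        # sharpest admissible fixtures (A = M with large M) sit near 2e-5
        sig = NutrientSignal("sinusoidal", M=M, A=frac * M, T=T)
        spec = PopulationSpec("L", beta)
        l_quad = invasion_lambda(spec, model, sig)
        l_lag = invasion_lambda_lag_form(spec, model, sig)
        assert abs(l_quad - l_lag) / l_quad < 5e-5

    def test_high_variability_favours_fast_variation(self, model, pair,
                                                     high_variability_signal):
        lam_H = invasion_lambda(pair[0], model, high_variability_signal)
        lam_L = invasion_lambda(pair[1], model, high_variability_signal)
        assert lam_H < lam_L

    def test_low_variability_favours_slow_variation(self, model, pair,
                                                    low_variability_signal):
        lam_H = invasion_lambda(pair[0], model, low_variability_signal)
        lam_L = invasion_lambda(pair[1], model, low_variability_signal)
        assert lam_L < lam_H


class TestPeriodicSize:
    def test_constant_environment_logistic_plateau(self, model, pair,
                                                   constant_signal):
        w = periodic_size(pair[1], model, constant_signal)
        assert w.time_average == pytest.approx(7400.0)

    def test_flat_periodic_signal_exact_plateau(self, model, pair):
        sig = NutrientSignal("sinusoidal", M=1.0, A=0.0, T=5.0)
        w = periodic_size(pair[1], model, sig)
        np.testing.assert_allclose(w.values, 7400.0, rtol=1e-10)

    def test_periodicity_and_nonnegativity(self, model, pair, signals):
        for sig in (signals["low"], signals["high"]):
            for spec in pair:
                w = periodic_size(spec, model, sig)
                assert abs(w.values[0] - w.values[-1]) < 1e-8 * w.values[0]
                assert np.all(w.values >= 0.0)

    def test_mean_value_identity(self, model, pair, signals):
        # (1/T) int w = (sqrt(gamma)/d)(threshold - Lambda) on every fixture
        for sig in (signals["low"], signals["high"]):
            for spec in pair:
                w = periodic_size(spec, model, sig)
                lam = invasion_lambda(spec, model, sig)
                theta = survival_threshold(model, sig)
                rhs = np.sqrt(model.gamma) / model.d * (theta - lam)
                assert w.time_average == pytest.approx(rhs, rel=1e-6)

    def test_period_map_fixed_point(self, model, pair, high_variability_signal):
        # integrating the periodic logistic ODE over one period from w(0)
        # returns to w(0): the closed form is the attractor of the period map
        spec = pair[0]
        w = periodic_size(spec, model, high_variability_signal)
        u = periodic_mean_trait(spec, model, high_variability_signal)
        sqgb = np.sqrt(model.gamma * spec.beta)

        def rhs(t, y):
            S = high_variability_signal(t)
            Q = (model.gamma * model.g(S) - sqgb
                 - model.gamma * (u(t) - model.phi(S)) ** 2)
            return (Q - model.d * y) * y

        sol = solve_ivp(rhs, (0.0, high_variability_signal.T), [w.values[0]],
                        rtol=1e-10, atol=1e-8)
        assert sol.y[0, -1] == pytest.approx(w.values[0], rel=1e-4)

    def test_refuses_subthreshold_population(self, model, constant_signal):
        doomed = PopulationSpec("L", 60.0)  # sqrt(60) > sqrt(gamma) g(1)
        with pytest.raises(SurvivalHypothesisError):
            periodic_size(doomed, model, constant_signal)


class TestClassifyOutcome:
    def test_constant_environment_low_variation_wins(self, model, pair,
                                                     constant_signal):
        out = classify_outcome(pair, model, constant_signal)
        assert out.outcome == L_WINS
        assert out.Lambda_H == pytest.approx(np.sqrt(0.025))
        assert out.Lambda_L == pytest.approx(0.1)
        assert out.threshold == pytest.approx(7.5)
        assert out.mean_size == pytest.approx(7400.0)
        assert out.mean_trait == pytest.approx(0.5)
        assert out.sigma2_inf == pytest.approx(0.01)

    def test_low_and_high_variability_outcomes(self, model, pair,
                                               low_variability_signal,
                                               high_variability_signal):
        assert classify_outcome(pair, model, low_variability_signal).outcome == L_WINS
        assert classify_outcome(pair, model, high_variability_signal).outcome == H_WINS

    def test_joint_extinction_condition(self, model, constant_signal):
        # beta_L = 60 > gamma g(1)^2 = 56.25: weak inequality branch fires
        specs = (PopulationSpec("H", 70.0), PopulationSpec("L", 60.0))
        out = classify_outcome(specs, model, constant_signal)
        assert out.outcome == BOTH_EXTINCT
        assert out.winner is None and out.u is None and out.w is None

    def test_periodic_branch_with_flat_signal_matches_constant_branch(
            self, model, pair, constant_signal):
        # A = 0 sinusoidal and truly constant classification coincide exactly
        flat = NutrientSignal("sinusoidal", M=1.0, A=0.0, T=5.0)
        a = classify_outcome(pair, model, constant_signal)
        b = classify_outcome(pair, model, flat)
        assert a.outcome == b.outcome == L_WINS
        assert b.Lambda_L == pytest.approx(a.Lambda_L, abs=1e-12)
        assert b.threshold == pytest.approx(a.threshold, rel=1e-12)
        assert b.mean_size == pytest.approx(a.mean_size, rel=1e-9)

    def test_winner_attractors_populated(self, model, pair,
                                         high_variability_signal):
        out = classify_outcome(pair, model, high_variability_signal)
        assert out.winner == "H"
        assert out.u is not None and out.w is not None
        assert out.sigma2_inf == pytest.approx(np.sqrt(0.025 / 100.0))
        assert out.mean_size == pytest.approx(
            np.sqrt(model.gamma) / model.d * (out.threshold - out.Lambda_H))


class TestCompetitionMap:
    def test_abundant_low_amplitude_nutrient_all_plus_one(self, model):
        # M=60, A=10: slow variation wins everywhere on the (T, beta_H) grid
        signs, _ = competition_map(model, M=60.0, A=10.0,
                                   beta_H_grid=np.linspace(0.012, 0.1, 8),
                                   T_grid=np.linspace(1.0, 20.0, 8),
                                   n_quad=1001)
        assert np.all(signs == 1.0)

    def test_large_relative_fluctuations_flip_some_entries(self, model):
        # M = A: starvation/abundance cycling opens a fast-variation region
        signs, diffs = competition_map(model, M=10.0, A=10.0,
                                       beta_H_grid=np.linspace(0.012, 0.1, 10),
                                       T_grid=np.linspace(1.0, 20.0, 10),
                                       n_quad=1001)
        assert np.any(signs == -1.0)
        assert np.any(signs == 1.0)
        assert signs.shape == diffs.shape == (10, 10)

    def test_equal_variation_rates_tie(self, model):
        signs, _ = competition_map(model, M=10.0, A=10.0,
                                   beta_H_grid=np.array([0.01 + 1e-12]),
                                   T_grid=np.array([5.0]),
                                   beta_L=0.01, n_quad=501)
        assert signs[0, 0] == 0.0
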