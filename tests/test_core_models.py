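"""Unit and property tests for the utility equations and SD transforms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tppunish import (
    ModelParams,
    TrialDesign,
    choice_probabilities,
    get_model,
    hyperbolic_inequity,
    hyperbolic_punishment,
    option_utilities,
    power_inequity,
    power_punishment,
    tpia_utility,
)


class TestTpiaUtility:
    @pytest.mark.parametrize("p,gamma,expected", [
        (0, 0.0, 50.0),      # no punishment, no inequity weight: keep x3
        (30, 1.0, 10.0),     # dictator zeroed out: 20 - |0 - 10|
        (15, 0.5, 17.5),     # 35 - 0.5 * |45 - 10|
    ])
    def test_costly_examples(self, p, gamma, expected):
        assert tpia_utility(90, 10, 50, p, gamma, 3.0, costly=True) == pytest.approx(expected)

    def test_free_condition_keeps_endowment(self):
        # the control condition removes only the cost; the dictator is
        # still punished
        u = tpia_utility(90, 10, 50, 15, 0.5, 3.0, costly=False)
        assert u == pytest.approx(50 - 0.5 * abs(45 - 10))

    def test_dictator_payoff_clamped_at_zero(self):
        # with x1=90 and multiplier 3 the 7 options give payoffs 90..0
        p = np.array([0, 5, 10, 15, 20, 25, 30], float)
        payoffs = np.maximum(90 - 3 * p, 0.0)
        assert payoffs.tolist() == [90, 75, 60, 45, 30, 15, 0]
        # p=30 triples to 90 and cannot push the dictator below zero
        u30 = tpia_utility(90, 10, 50, 30, 1.0)
        u_unclamped = (50 - 30) - 1.0 * abs((90 - 90) - 10)
        assert u30 == pytest.approx(u_unclamped)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            tpia_utility(90, 10, 50, -1, 0.5)
        with pytest.raises(ValueError):
            tpia_utility(90, 10, 50, 5, 1.5)

    @given(gamma=st.floats(0, 1), p=st.sampled_from([0, 5, 10, 15, 20, 25, 30]))
    def test_costly_utility_bounded_by_endowment(self, gamma, p):
        assert tpia_utility(90, 10, 50, p, gamma) <= 50.0


class TestTransforms:
    @pytest.mark.parametrize("p_sd,sd,k,expected", [
        (10, 1, 1.0, 20.0),
        (0, 5, 0.3, 0.0),
        (10, 100, 1.0, 10.1),
    ])
    def test_hyperbolic_punishment_examples(self, p_sd, sd, k, expected):
        assert hyperbolic_punishment(p_sd, sd, k) == pytest.approx(expected)

    @given(k=st.floats(0.01, 10), p_sd=st.floats(0.1, 30),
           sd=st.sampled_from([1, 2, 3, 5, 10, 20, 50]))
    def test_hyperbolic_punishment_decreasing_in_sd(self, k, p_sd, sd):
        assert hyperbolic_punishment(p_sd, sd, k) > hyperbolic_punishment(p_sd, sd + 1, k)

    def test_hyperbolic_punishment_limit_is_nominal(self):
        assert hyperbolic_punishment(10, 10 ** 9, 1.0) == pytest.approx(10.0, rel=1e-8)

    def test_hyperbolic_inequity_examples(self):
        assert hyperbolic_inequity(0.0, 7, 0.4) == pytest.approx(0.5)
        assert hyperbolic_inequity(1.0, 1, 1.0) == pytest.approx(0.8808, abs=1e-4)
        assert hyperbolic_inequity(50.0, 1, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("p_sd,sd,k,w,expected", [
        (10, 1, 2.0, 3.0, 12.0),
        (10, 4, 0.0, 1.0, 10.0),
        (5, 10, 0.5, 2.0, 55.0),
    ])
    def test_power_punishment_examples(self, p_sd, sd, k, w, expected):
        assert power_punishment(p_sd, sd, k, w) == pytest.approx(expected)

    def test_power_inequity_examples(self):
        assert power_inequity(0.0, 1, 0.0, 1.0) == pytest.approx(0.5)
        assert power_inequity(-3.0, 1, 3.0, 1.0) == pytest.approx(0.5)
        assert power_inequity(0.0, 2, 1.0, 1.0) == pytest.approx(0.8808, abs=1e-4)

    @pytest.mark.parametrize("fn,args", [
        (hyperbolic_punishment, (10, 0, 1.0)),
        (hyperbolic_punishment, (10, 5, -1.0)),
        (hyperbolic_inequity, (0.5, 0, 1.0)),
        (power_punishment, (10, 0, 1.0, 1.0)),
        (power_inequity, (0.5, -2, 1.0, 1.0)),
    ])
    def test_domain_errors(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


class TestOptionUtilities:
    def test_gamma_zero_costly_is_decreasing(self):
        trial = TrialDesign("costly", 5, 90, 10)
        model = get_model("hyperbolic_punishment")
        u = option_utilities(trial, ModelParams(0.0, 0.5, 1.0), model)
        assert len(u) == 7
        assert np.all(np.diff(u) < 0)
        assert np.argmax(u) == 0

    def test_gamma_zero_free_is_flat_at_endowment(self):
        trial = TrialDesign("free", 5, 90, 10)
        model = get_model("hyperbolic_inequity")
        # gamma_sd = -12: sigmoid maps to ~0, so only the (absent) cost varies
        u = option_utilities(trial, ModelParams(-12.0, 0.5, 1.0), model)
        assert u == pytest.approx(np.full(7, 50.0), abs=1e-3)

    def test_matches_exhaustive_hand_evaluation(self):
        # hyperbolic punishment, gamma=0.5, k=0.1, sd=10: impact factor = 2;
        # the observer pays the nominal amount, the dictator feels double
        trial = TrialDesign("costly", 10, 90, 10)
        model = get_model("hyperbolic_punishment")
        u = option_utilities(trial, ModelParams(0.5, 0.1, 1.0), model)
        expected = []
        for p in trial.options:
            ps = 2.0 * p  # subjective punishment impact
            expected.append(max(50 - p, 0) - 0.5 * abs(max(90 - 3 * ps, 0) - 10))
        assert u == pytest.approx(expected)
        assert np.argmax(u) == 2

    def test_degenerate_hyperbolic_k_large_recovers_plain_tpia(self):
        # k -> infinity: the transform is the identity and the model is
        # the plain inequity-aversion account
        trial = TrialDesign("costly", 3, 85, 15)
        model = get_model("hyperbolic_punishment")
        u = option_utilities(trial, ModelParams(0.4, 1e9, 1.0), model)
        plain = [tpia_utility(85, 15, 50, p, 0.4) for p in trial.options]
        assert u == pytest.approx(plain, rel=1e-6)

    def test_trial_validation(self):
        with pytest.raises(ValueError):
            TrialDesign("banana", 5, 90, 10)
        with pytest.raises(ValueError):
            TrialDesign("costly", 0, 90, 10)
        with pytest.raises(ValueError):
            TrialDesign("costly", 5, 90, 10, options=(5, 10))


class TestChoiceProbabilities:
    def test_uniform_under_equal_utilities(self):
        p = choice_probabilities(np.zeros(7), beta=2.3)
        assert p == pytest.approx(np.full(7, 1 / 7))

    def test_two_option_logistic(self):
        p = choice_probabilities([0.0, 1.0], beta=1.0)
        assert p == pytest.approx([0.26894, 0.73106], abs=1e-5)

    def test_large_beta_approaches_argmax(self):
        p = choice_probabilities([1.0, 3.0, 2.0], beta=500.0)
        assert np.argmax(p) == 1
        assert p[1] == pytest.approx(1.0, abs=1e-6)

    @given(u=arrays(np.float64, 7, elements=st.floats(-50, 50)),
           beta=st.floats(0.01, 10), shift=st.floats(-100, 100))
    def test_normalised_and_translation_invariant(self, u, beta, shift):
        p = choice_probabilities(u, beta)
        assert np.all(p > 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert choice_probabilities(u + shift, beta) == pytest.approx(p, abs=1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            choice_probabilities([np.inf, 0.0], 1.0)
        with pytest.raises(ValueError):
            choice_probabilities([0.0, 1.0], 0.0)
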