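"""Stochastic two-choice / four-outcome simulator: determinism, state
containment, martingale calibration, and cross-validation with the solver."""

from fractions import Fraction

import numpy as np
import pytest

import operanteq as oq
from operanteq import (
    compare_to_solution,
    estimate_fixation_probability,
    simulate_four_outcome,
    simulate_two_choice,
)
from operanteq.model import make_affine_operator, preset_model


class TestTwoChoicePaths:
    def test_identical_seeds_reproduce_paths_bitwise(self, martingale_model):
        p1 = simulate_two_choice(martingale_model, 0.5, seed=42)
        p2 = simulate_two_choice(martingale_model, 0.5, seed=42)
        assert np.array_equal(p1.states, p2.states)
        assert p1.outcome == p2.outcome and p1.steps == p2.steps

    def test_states_stay_in_unit_interval(self, asymmetric_model):
        for seed in range(20):
            path = simulate_two_choice(asymmetric_model, 0.5, seed=seed)
            assert path.states.min() >= 0.0 and path.states.max() <= 1.0

    def test_identity_operators_censor_with_constant_state(self):
        gid = make_affine_operator(1, 0)
        model = oq.DiscreteModel(g1=gid, g2=gid)
        path = simulate_two_choice(model, 0.5, seed=0, max_steps=50)
        assert path.outcome == "censored"
        assert np.all(path.states == 0.5)

    def test_one_step_bernoulli_fixation(self):
        # g1 == 1, g2 == 0: a single trial decides fixation
        model = oq.DiscreteModel(
            g1=make_affine_operator(0, 1), g2=make_affine_operator(0, 0)
        )
        highs = sum(
            simulate_two_choice(model, 0.7, seed=s).outcome == "fixated_high"
            for s in range(2000)
        )
        assert all(
            simulate_two_choice(model, 0.7, seed=s).steps == 1 for s in range(10)
        )
        p = highs / 2000
        assert abs(p - 0.7) <= 3 * np.sqrt(0.7 * 0.3 / 2000)

    @pytest.mark.parametrize("x0,eps", [(1.5, 1e-6), (-0.1, 1e-6), (0.5, 0.7), (0.5, 0.0)])
    def test_invalid_arguments_rejected(self, martingale_model, x0, eps):
        with pytest.raises(ValueError):
            simulate_two_choice(martingale_model, x0, seed=0, eps=eps)


class TestFixationEstimates:
    def test_martingale_estimate_matches_start_state(self, martingale_model):
        s = estimate_fixation_probability(martingale_model, 0.5, 4000, seed=11)
        assert s.censored_count == 0
        assert abs(s.p_hat - 0.5) <= 3 * s.se

    def test_absorbing_starts_are_exact(self, martingale_model):
        assert estimate_fixation_probability(martingale_model, 0.0, 50, seed=0).p_hat == 0.0
        assert estimate_fixation_probability(martingale_model, 1.0, 50, seed=0).p_hat == 1.0

    def test_martingale_calibration_across_rates_and_starts(self):
        """For a1 = a2 = a the closed form is f(x) = x; at least 95% of
        (x0, a) cells agree within 3 SE."""
        cells = ok = 0
        for a in ("1/10", "3/10", "1/2"):
            model = preset_model("lyubich_shapiro", {"a1": Fraction(a)})
            for x0 in (0.25, 0.5, 0.75):
                s = estimate_fixation_probability(model, x0, 1500, seed=101 + cells)
                cells += 1
                ok += abs(s.p_hat - x0) <= 3 * s.se
        assert ok / cells >= 0.95

    def test_standard_error_shrinks_with_replicates(self, martingale_model):
        s1 = estimate_fixation_probability(martingale_model, 0.5, 500, seed=5)
        s2 = estimate_fixation_probability(martingale_model, 0.5, 4000, seed=5)
        assert s2.se < s1.se


class TestFourOutcome:
    def test_outcome_probabilities_sum_to_one_identically(self):
        for p in (0.0, 0.3, 1.0):
            for x in (0.0, 0.4, 1.0):
                probs = (p * x, (1 - p) * x, p * (1 - x), (1 - p) * (1 - x))
                assert sum(probs) == pytest.approx(1.0)

    def test_predictable_only_outcomes_when_p_is_one(self):
        # with p = 1 the unpredictable outcomes (1-p)x and (1-p)(1-x) vanish,
        # so only operators 1 and 3 are ever applied
        marker = []
        ops = [
            oq.model.make_generic_operator(lambda t, i=i: marker.append(i) or 0.5 * t + 0.25)
            for i in range(4)
        ]
        simulate_four_outcome(1.0, ops, x0=0.5, seed=3, max_steps=200)
        assert set(marker) <= {0, 2}

    def test_one_step_outcome_frequencies_match_table(self):
        """Multinomial check at x0 = 0.5, p = 0.3 against (0.15, 0.35, 0.15, 0.35)."""
        # operators chosen so the applied index is recoverable from the new state
        targets = (0.1, 0.3, 0.6, 0.9)
        ops = [oq.model.make_generic_operator(lambda t, v=v: v) for v in targets]
        counts = dict.fromkeys(targets, 0)
        n = 20_000
        for s in range(n):
            path = simulate_four_outcome(0.3, ops, x0=0.5, seed=s, max_steps=1)
            counts[round(path.states[1], 10)] += 1
        expected = (0.15, 0.35, 0.15, 0.35)
        for v, e in zip(targets, expected):
            se = np.sqrt(e * (1 - e) / n)
            assert abs(counts[v] / n - e) <= 3 * se

    def test_invalid_p_rejected(self):
        ops = [make_affine_operator("1/5", "1/5")] * 4
        with pytest.raises(ValueError):
            simulate_four_outcome(1.5, ops, x0=0.5, seed=0)


class TestSolverCrossValidation:
    def test_martingale_grid_agrees_with_closed_form(self, martingale_model):
        df = compare_to_solution(martingale_model, [0.25, 0.5, 0.75], 2000, seed=17)
        assert not df["flagged"].any()
        assert np.abs(df["f_solved"] - df["x0"]).max() <= 1e-6

    def test_asymmetric_model_agrees_with_numeric_solution(self, asymmetric_model):
        df = compare_to_solution(asymmetric_model, [0.25, 0.5, 0.75], 2000, seed=23)
        assert not df["flagged"].any()

    def test_zero_replicates_give_empty_report(self, martingale_model):
        df = compare_to_solution(martingale_model, [0.5], 0, seed=0)
        assert df.empty
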