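"""Learning rules: single-step arithmetic, Kalman closed forms, composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ubandit.deciders import choice_probability
from ubandit.learners import (
    alphabet_stats,
    attach_uncertainty_tracker,
    dual_rate_update,
    init_beliefs,
    kalman_update,
    make_learner,
    qlearn_update,
    range_update,
    relative_update,
    select_reject_update,
)


class TestInitialization:
    def test_main_alphabet(self, main_design):
        state = init_beliefs("kalman:qu", main_design)
        assert state.q0 == 0.0
        assert state.sigma0 == pytest.approx(np.sqrt(2.0 / 3.0))
        assert all(o.q == 0.0 and o.sigma == state.sigma0 for o in state.options.values())

    def test_validation_alphabet(self, validation_design):
        q0, sigma0 = alphabet_stats(validation_design.outcome_alphabet)
        assert q0 == pytest.approx(11.0 / 3.0)
        assert sigma0 == pytest.approx(np.sqrt(101.0 / 3.0 - (11.0 / 3.0) ** 2))
        assert sigma0 == pytest.approx(4.497, abs=1e-3)

    def test_unknown_model_rejected(self, main_design):
        with pytest.raises(ValueError):
            init_beliefs("bayes_optimal:qu", main_design)


class TestSingleStepUpdates:
    def test_qlearn(self):
        q, trace = qlearn_update(0.0, 0.5, 1.0)
        assert (q, trace.delta) == (0.5, 1.0)
        assert qlearn_update(0.5, 1.0, 0.0)[0] == 0.0
        assert qlearn_update(0.5, 0.5, 0.0)[0] == 0.25

    def test_dual_rate(self):
        assert dual_rate_update(0.0, 0.8, 0.2, 1.0)[0] == pytest.approx(0.8)
        assert dual_rate_update(0.5, 0.8, 0.2, 0.0)[0] == pytest.approx(0.4)
        # zero prediction error: neither branch applies, no update
        q, trace = dual_rate_update(0.5, 0.8, 0.2, 0.5)
        assert q == 0.5 and trace.alpha_used == 0.0

    @given(
        alpha=st.floats(0, 1),
        outcomes=st.lists(st.sampled_from([-1.0, 0.0, 1.0]), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=50)
    def test_dual_rate_collapses_to_qlearn(self, alpha, outcomes):
        q1 = q2 = 0.0
        for r in outcomes:
            q1, _ = qlearn_update(q1, alpha, r)
            q2, _ = dual_rate_update(q2, alpha, alpha, r)
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_select_reject(self):
        s, r, _ = select_reject_update(0.0, 0.0, 0.5, 0.5, 1.0)
        assert (s, r) == (0.5, -0.5)
        s, r, _ = select_reject_update(0.2, 0.1, 0.5, 0.5, 0.0)
        assert s == pytest.approx(0.1) and r == pytest.approx(0.2)
        _, r, _ = select_reject_update(0.3, 0.7, 0.5, 0.0, 1.0)
        assert r == 0.7  # alpha_rejected = 0 leaves the rejected option alone

    def test_relative(self):
        q, v, trace = relative_update(0.0, 0.0, 0.0, 0.5, 0.5, 1.0)
        assert (q, v) == (0.5, 0.25)
        assert trace.delta == 1.0
        # outcome equal to V_c + q_selected elicits no value update
        q, _, trace = relative_update(0.3, 0.0, 0.2, 0.9, 0.5, 0.5)
        assert q == pytest.approx(0.3) and trace.delta == pytest.approx(0.0)

    def test_range(self):
        q, rmax, rmin, trace = range_update(0.0, 10.0, 0.0, 1.0, 0.1, 10.0)
        assert trace.r_effective == pytest.approx(10.0 / 11.0)
        assert range_update(0.0, 10.0, 0.0, 1.0, 0.1, 0.0)[3].r_effective == 0.0
        q, rmax, rmin, _ = range_update(0.0, 0.0, 0.0, 0.5, 1.0, 10.0)
        assert rmax == 10.0 and rmin == 0.0

    def test_range_normalized_within_trackers(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            rmin = rng.uniform(-5, 0)
            rmax = rng.uniform(0, 5)
            r = rng.uniform(rmin, rmax)
            eff = range_update(0.0, rmax, rmin, 0.5, 0.5, r)[3].r_effective
            assert 0.0 <= eff <= 1.0


class TestKalman:
    def test_first_observation_gain_half(self):
        _, sigma, trace = kalman_update(0.0, 1.0, 1.0, 1.0)
        assert trace.alpha_used == 0.5

    @pytest.mark.parametrize("seed", [0, 1])
    def test_closed_forms(self, seed):
        """sigma_k^2 = sigma0^2/(k+1), alpha_k = 1/(k+1), q = pseudo-count mean."""
        rng = np.random.default_rng(seed)
        sigma0 = np.sqrt(2.0 / 3.0)
        q, sigma = 0.0, sigma0
        outcomes = rng.choice([-1.0, 0.0, 1.0], size=10)
        for k, r in enumerate(outcomes, start=1):
            q, sigma, trace = kalman_update(q, sigma, sigma0, r)
            assert trace.alpha_used == pytest.approx(1.0 / (k + 1), abs=1e-12)
            assert sigma**2 == pytest.approx(sigma0**2 / (k + 1), abs=1e-12)
            assert q == pytest.approx((0.0 + outcomes[:k].sum()) / (k + 1), abs=1e-12)

    def test_sigma_strictly_decreasing_to_zero(self):
        sigma0 = 1.0
        sigma = sigma0
        prev = sigma
        for _ in range(500):
            _, sigma, _ = kalman_update(0.0, sigma, sigma0, 0.0)
            assert sigma < prev
            prev = sigma
        assert sigma < 0.05


class TestStatefulLearners:
    def _run(self, learner_id, design, n=16, seed=0, track=False):
        rng = np.random.default_rng(seed)
        learner = make_learner(learner_id, track_uncertainty=track)
        state = init_beliefs(learner_id + ":q", design)
        pair = design.learning_pairs[0]
        params = {
            "alpha": 0.4,
            "alpha_plus": 0.6,
            "alpha_minus": 0.2,
            "alpha_selected": 0.4,
            "alpha_rejected": 0.3,
            "alpha_c": 0.3,
            "alpha_r": 0.5,
        }
        choices = []
        for _ in range(n):
            chosen, unchosen = (
                (pair.good_id, pair.bad_id) if rng.random() < 0.5 else (pair.bad_id, pair.good_id)
            )
            from ubandit.designs import sample_outcome

            r = sample_outcome(design.conditions[pair.condition_id], design.option_role(chosen), rng)
            learner.step(state, pair.pair_id, chosen, unchosen, r, params)
            choices.append(chosen)
        return state, choices

    @pytest.mark.parametrize(
        "learner_id", ["1alpha", "2alpha", "select_reject", "relative", "range", "kalman"]
    )
    def test_uninvolved_options_untouched(self, main_design, learner_id):
        state, _ = self._run(learner_id, main_design)
        untouched = main_design.learning_pairs[5]
        assert state.options[untouched.good_id].q == state.q0
        assert state.options[untouched.good_id].sigma == state.sigma0

    def test_unsampled_option_keeps_sigma0(self, main_design):
        state, choices = self._run("kalman", main_design, seed=3)
        pair = main_design.learning_pairs[0]
        for oid in (pair.good_id, pair.bad_id):
            k = choices.count(oid)
            expected = state.sigma0 / np.sqrt(k + 1)
            assert state.options[oid].sigma == pytest.approx(expected, abs=1e-12)

    def test_attached_tracker_matches_kalman_sigma(self, main_design):
        # sigma depends only on the choice sequence, not the value rule
        s_base, c_base = self._run("1alpha", main_design, seed=9, track=True)
        s_kal, c_kal = self._run("kalman", main_design, seed=9)
        assert c_base == c_kal  # same rng stream drives the choices
        pair = main_design.learning_pairs[0]
        for oid in (pair.good_id, pair.bad_id):
            assert s_base.options[oid].sigma == pytest.approx(
                s_kal.options[oid].sigma, abs=1e-12
            )

    def test_attach_to_range_bounded_values_decaying_sigma(self, main_design):
        state, choices = self._run("range", main_design, seed=4, track=True)
        pair = main_design.learning_pairs[0]
        for oid in (pair.good_id, pair.bad_id):
            assert 0.0 <= state.options[oid].q <= 1.0
            if choices.count(oid):
                assert state.options[oid].sigma < state.sigma0

    def test_attach_with_zero_beta_u_is_base_model(self, main_design):
        state, _ = self._run("1alpha", main_design, seed=2, track=True)
        pair = main_design.learning_pairs[0]
        a, b = state.options[pair.good_id], state.options[pair.bad_id]
        p_qu = choice_probability("qu", a, b, {"beta_q": 3.0, "beta_u": 0.0}).p_i
        p_q = choice_probability("q", a, b, {"beta_q": 3.0}).p_i
        assert p_qu == pytest.approx(p_q, abs=1e-15)

    def test_attach_accepts_instance_or_id(self):
        learner = attach_uncertainty_tracker("range")
        assert learner.track_uncertainty
        learner2 = attach_uncertainty_tracker(make_learner("2alpha"))
        assert learner2.learner_id == "2alpha" and learner2.track_uncertainty
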