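"""Likelihood replay, MAP fitting, Laplace evidence, pseudo-R^2."""

import math

import numpy as np
import pandas as pd
import pytest

from ubandit.cohort import BehaviorDataset, generate_cohort
from ubandit.deciders import choice_probability
from ubandit.fitting import (
    TruncGaussPrior,
    fit_dataset,
    fit_map,
    laplace_log_evidence,
    phase_log_likelihood,
    pseudo_r2,
    subject_arrays,
)
from ubandit.learners import init_beliefs, make_learner
from ubandit.models import MODEL_IDS, model_param_names, split_model_id

LOG_HALF = math.log(0.5)


def replay_python(model_id, params, dataset, subject, phase):
    """Reference replay via the stateful object API (independent of the kernel)."""
    learner_id, decider_id = split_model_id(model_id)
    learner = make_learner(learner_id, track_uncertainty=True)
    state = init_beliefs(model_id, dataset.design)
    ll = 0.0
    for rec in dataset.subject_trials(subject).itertuples(index=False):
        chosen = rec.choice
        unchosen = rec.option_right if chosen == rec.option_left else rec.option_left
        if rec.phase == phase:
            trace = choice_probability(
                decider_id, state.options[chosen], state.options[unchosen], params
            )
            ll += math.log(trace.p_i)
        if rec.phase == "learning":
            learner.step(state, rec.pair_id, chosen, unchosen, rec.outcome, params)
    return ll


class TestLikelihood:
    def test_indifference_gives_coinflip_ll(self, small_cohort):
        arrays = subject_arrays(small_cohort, "s000")
        ll = phase_log_likelihood(
            "kalman:qu", {"beta_q": 0.0, "beta_u": 0.0}, arrays, "learning"
        )
        assert ll == pytest.approx(240 * LOG_HALF)
        ll = phase_log_likelihood("kalman:qu", {"beta_q": 0.0, "beta_u": 0.0}, arrays, "test")
        assert ll == pytest.approx(180 * LOG_HALF)

    def test_three_trial_hand_unrolled_oracle(self, main_design):
        """Q-learning + softmax on a 3-trial toy history, unrolled by hand."""
        g, b = "1_p1.00_G", "1_p1.00_B"
        rows = []
        for t, (choice, outcome) in enumerate([(g, 1.0), (g, 0.0), (b, -1.0)]):
            rows.append(
                dict(
                    subject="s0",
                    phase="learning",
                    block=1,
                    trial=t,
                    pair_id="1_p1.00",
                    pair_type="learning",
                    condition="p1.00",
                    option_left=g,
                    option_right=b,
                    choice=choice,
                    outcome=outcome,
                )
            )
        dataset = BehaviorDataset(trials=pd.DataFrame(rows), design=main_design)
        alpha, beta_q = 0.5, 2.0

        def logistic(x):
            return 1.0 / (1.0 + math.exp(-x))

        # trial 1: q_G = q_B = 0 -> p = 0.5; then q_G <- 0 + 0.5*(1-0) = 0.5
        # trial 2: p = logistic((0.5-0)*2); then q_G <- 0.5 + 0.5*(0-0.5) = 0.25
        # trial 3 (B chosen): p = logistic((0-0.25)*2)
        expected = (
            math.log(0.5) + math.log(logistic(1.0)) + math.log(logistic(-0.5))
        )
        ll = phase_log_likelihood(
            "1alpha:q",
            {"alpha": alpha, "beta_q": beta_q},
            subject_arrays(dataset, "s0"),
            "learning",
        )
        assert ll == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    @pytest.mark.parametrize("phase", ["learning", "test"])
    def test_kernel_matches_object_replay(self, main_design, model_id, phase):
        cohort = generate_cohort(1, model_id, main_design, seed=5)
        params = dict.fromkeys(model_param_names(model_id), 0.0)
        params.update({"alpha": 0.35, "alpha_plus": 0.6, "alpha_minus": 0.2,
                       "alpha_selected": 0.5, "alpha_rejected": 0.25,
                       "alpha_c": 0.3, "alpha_r": 0.7, "beta_q": 2.5})
        if "beta_u" in params:
            params["beta_u"] = -1.5
        params = {k: params[k] for k in model_param_names(model_id)}
        arrays = subject_arrays(cohort, "s000")
        assert phase_log_likelihood(model_id, params, arrays, phase) == pytest.approx(
            replay_python(model_id, params, cohort, "s000", phase), abs=1e-9
        )

    def test_wrong_parameter_count_rejected(self, small_cohort):
        arrays = subject_arrays(small_cohort, "s000")
        with pytest.raises(ValueError):
            phase_log_likelihood("kalman:qu", [1.0], arrays, "learning")


def test_model_free_parameters_per_model():
    expected = {
        "1alpha": ("alpha",),
        "2alpha": ("alpha_plus", "alpha_minus"),
        "select_reject": ("alpha_selected", "alpha_rejected"),
        "relative": ("alpha", "alpha_c"),
        "range": ("alpha", "alpha_r"),
        "kalman": (),
    }
    for learner, alphas in expected.items():
        assert model_param_names(f"{learner}:q") == alphas + ("beta_q",)
        assert model_param_names(f"{learner}:qu") == alphas + ("beta_q", "beta_u")


class TestPseudoR2:
    def test_worked_examples(self):
        assert pseudo_r2(240 * LOG_HALF, 240) == pytest.approx(0.0)
        assert pseudo_r2(0.0, 240) == pytest.approx(1.0)
        assert pseudo_r2(-120.0, 240) == pytest.approx(1.0 - 120.0 / (240 * -LOG_HALF))
        assert pseudo_r2(-120.0, 240) == pytest.approx(0.2787, abs=2e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pseudo_r2(-1.0, 0)


class TestMAP:
    def test_recovers_generating_betas(self, main_design):
        sampler_params = {"beta_q": 3.0, "beta_u": -1.0}
        from ubandit.cohort import simulate_learning_phase, subject_rng
        from ubandit.designs import build_learning_schedule

        sched = build_learning_schedule(main_design, seed=3)
        rows, _ = simulate_learning_phase(
            "kalman:qu", sampler_params, main_design, sched, subject_rng(8, 0)
        )
        dataset = BehaviorDataset(trials=pd.DataFrame(rows), design=main_design)
        fit = fit_map("kalman:qu", subject_arrays(dataset, "s0"), seed=1)
        assert fit.converged
        assert fit.map_params["beta_q"] == pytest.approx(3.0, abs=1.5)
        assert fit.map_params["beta_u"] == pytest.approx(-1.0, abs=1.5)
        assert fit.log_likelihood <= 0
        assert fit.pseudo_r2 <= 1

    def test_flat_data_shrinks_to_prior_mean(self, main_design):
        # a coin-flipping subject: both decision weights pinned at 0
        from ubandit.cohort import ParameterSampler

        flat = generate_cohort(
            1,
            "kalman:qu",
            main_design,
            seed=2,
            sampler=ParameterSampler({"beta_q": ("uniform", 0, 0), "beta_u": ("uniform", 0, 0)}),
        )
        fit = fit_map("kalman:qu", subject_arrays(flat, "s000"), seed=0)
        assert abs(fit.map_params["beta_q"]) < 1.5
        assert abs(fit.map_params["beta_u"]) < 1.5

    def test_prior_variance_barely_matters_with_informative_data(self, main_design):
        cohort = generate_cohort(1, "kalman:qu", main_design, seed=9)
        arrays = subject_arrays(cohort, "s000")
        fit1 = fit_map("kalman:qu", arrays, prior=TruncGaussPrior.for_model("kalman:qu", 1.0), seed=0)
        fit2 = fit_map("kalman:qu", arrays, prior=TruncGaussPrior.for_model("kalman:qu", 2.0), seed=0)
        for name in fit1.map_params:
            assert fit1.map_params[name] == pytest.approx(fit2.map_params[name], abs=0.2)


class TestEvidence:
    def test_laplace_matches_grid_integration(self, main_design):
        """Independent oracle: 2-D trapezoid integration of the posterior."""
        cohort = generate_cohort(1, "kalman:qu", main_design, seed=4)
        arrays = subject_arrays(cohort, "s000")
        prior = TruncGaussPrior.for_model("kalman:qu")
        fit = fit_map("kalman:qu", arrays, prior=prior, seed=0)

        grid = np.linspace(-20, 20, 481)
        log_post = np.empty((grid.size, grid.size))
        for i, bq in enumerate(grid):
            for j, bu in enumerate(grid):
                x = np.array([bq, bu])
                log_post[i, j] = phase_log_likelihood(
                    "kalman:qu", x, arrays, "learning"
                ) + prior.log_norm_const() - prior.quad_penalty(x)
        m = log_post.max()
        integral = np.trapezoid(
            np.trapezoid(np.exp(log_post - m), grid, axis=1), grid
        )
        log_ev_grid = m + np.log(integral)
        assert fit.log_evidence == pytest.approx(log_ev_grid, abs=0.2)

    def test_nested_model_penalized_on_average(self, main_design):
        cohort = generate_cohort(6, "1alpha:q", main_design, seed=6, include_test=False)
        fits = fit_dataset(cohort, ["1alpha:q", "2alpha:q"], n_restarts=6, seed=0)
        ev = fits.groupby("model_id")["log_evidence"].mean()
        assert ev["1alpha:q"] > ev["2alpha:q"]
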