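"""Synthetic cohorts: simulate virtual participants through both phases.

Each virtual participant is a (learner, decider, parameter set) triple run
through a learning schedule with partial feedback and then through a
feedback-free test schedule with frozen beliefs. Outcomes are drawn fresh
per trial from the condition's generative tree. One RNG stream is derived
per subject from (master seed, subject index), so cohorts are reproducible
regardless of iteration order.

By default, test-phase decision weights are sampled independently of the
learning-phase ones, mirroring the separate per-phase model fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import designs as dsg
from .deciders import DECIDER_PARAMS, choice_probability
from .designs import ExperimentDesign, build_learning_schedule, build_test_schedule
from .learners import BeliefState, init_beliefs, make_learner
from .models import model_param_names, split_model_id

TRIAL_COLUMNS = [
    "subject",
    "phase",
    "block",
    "trial",
    "pair_id",
    "pair_type",
    "condition",
    "option_left",
    "option_right",
    "choice",
    "outcome",
]


@dataclass
class BehaviorDataset:
    """Trial-level records for one or many subjects, plus provenance."""

    trials: pd.DataFrame
    design: ExperimentDesign
    manifest: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list:
        return sorted(self.trials["subject"].unique())

    def subject_trials(self, subject) -> pd.DataFrame:
        df = self.trials[self.trials["subject"] == subject]
        return df.sort_values("trial").reset_index(drop=True)

    def validate(self) -> None:
        df = self.trials
        test = df[df["phase"] == "test"]
        if test["outcome"].notna().any():
            raise ValueError("test-phase records must carry no outcome")
        ok = (df["choice"] == df["option_left"]) | (df["choice"] == df["option_right"])
        if not ok.all():
            raise ValueError("choice must be one of the two shown options")
        for subject in self.subjects:
            sub = self.subject_trials(subject)
            phases = sub["phase"].to_numpy()
            if (phases == "test").any():
                first_test = int(np.argmax(phases == "test"))
                if (phases[first_test:] == "learning").any():
                    raise ValueError(f"subject {subject}: learning after test")


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

# Fitted-range defaults for recovery studies: rates span their full [0, 1]
# support; decision weights span the range of fitted subject-level values.
DEFAULT_RANGES = {
    "alpha": (0.0, 1.0),
    "beta_q": (0.5, 6.0),
    "beta_u": (-8.0, 0.0),
}

# Group-level fitted means/SDs of the winning Kalman:QU model, per phase.
FITTED_KALMAN_QU = {
    "learning": {"beta_q": (2.9, 1.47), "beta_u": (-1.1, 2.07)},
    "test": {"beta_q": (1.2, 0.74), "beta_u": (-5.5, 2.14)},
}


@dataclass
class ParameterSampler:
    """Per-parameter distributions: name -> ("uniform", lo, hi) or
    ("truncnorm", mean, sd, lo, hi)."""

    specs: dict

    def sample(self, rng: np.random.Generator) -> dict:
        out = {}
        for name, spec in self.specs.items():
            kind = spec[0]
            if kind == "uniform":
                _, lo, hi = spec
                out[name] = float(rng.uniform(lo, hi))
            elif kind == "truncnorm":
                _, mean, sd, lo, hi = spec
                while True:
                    x = rng.normal(mean, sd)
                    if lo <= x <= hi:
                        out[name] = float(x)
                        break
            else:
                raise ValueError(f"unknown sampler kind {kind!r}")
        return out

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.specs.items()}


def default_sampler(model_id: str) -> ParameterSampler:
    """Uniform sampler over each parameter's fitted range (rates: [0, 1])."""
    specs = {}
    for name in model_param_names(model_id):
        key = name if name in DEFAULT_RANGES else ("alpha" if name.startswith("alpha") else name)
        lo, hi = DEFAULT_RANGES[key]
        specs[name] = ("uniform", lo, hi)
    return ParameterSampler(specs)


def fitted_sampler(model_id: str = "kalman:qu", phase: str = "learning") -> ParameterSampler:
    """Decision weights near the group-level fitted Kalman:QU means
    (truncated normals within the fitted range); rates uniform."""
    fitted = FITTED_KALMAN_QU[phase]
    specs = {}
    for name in model_param_names(model_id):
        if name in fitted:
            mean, sd = fitted[name]
            lo, hi = DEFAULT_RANGES[name]
            specs[name] = ("truncnorm", mean, sd, lo, hi)
        else:
            specs[name] = ("uniform", 0.0, 1.0)
    return ParameterSampler(specs)


def decider_sampler(base: ParameterSampler, model_id: str) -> ParameterSampler:
    """Restrict a sampler to the model's decision weights (test phase)."""
    _, decider_id = split_model_id(model_id)
    return ParameterSampler({n: base.specs[n] for n in DECIDER_PARAMS[decider_id]})


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_learning_phase(
    model_id: str,
    params: dict,
    design: ExperimentDesign,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    subject="s0",
):
    """Run one agent through a learning schedule.

    Per trial: softmax choice from current beliefs, outcome drawn from the
    chosen option's contingencies (partial feedback), then the learner's
    update. Returns (trial rows, final belief state).
    """
    learner_id, decider_id = split_model_id(model_id)
    learner = make_learner(learner_id, track_uncertainty=True)
    state = init_beliefs(model_id, design)
    rows = []
    for rec in schedule.itertuples(index=False):
        left, right = rec.option_left, rec.option_right
        trace = choice_probability(
            decider_id, state.options[left], state.options[right], params
        )
        chosen, unchosen = (left, right) if rng.random() < trace.p_i else (right, left)
        cond = design.option_condition(chosen)
        outcome = dsg.sample_outcome(cond, design.option_role(chosen), rng)
        learner.step(state, rec.pair_id, chosen, unchosen, outcome, params)
        rows.append(
            {
                "subject": subject,
                "phase": "learning",
                "block": rec.block,
                "trial": rec.trial,
                "pair_id": rec.pair_id,
                "pair_type": rec.pair_type,
                "condition": rec.condition,
                "option_left": left,
                "option_right": right,
                "choice": chosen,
                "outcome": outcome,
            }
        )
    return rows, state


def simulate_test_phase(
    model_id: str,
    params_test: dict,
    state: BeliefState,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    subject="s0",
):
    """Feedback-free choices from frozen beliefs; beliefs are not updated."""
    _, decider_id = split_model_id(model_id)
    rows = []
    for rec in schedule.itertuples(index=False):
        left, right = rec.option_left, rec.option_right
        if left not in state.options or right not in state.options:
            raise KeyError(f"unknown option in test schedule: {left!r}/{right!r}")
        trace = choice_probability(
            decider_id, state.options[left], state.options[right], params_test
        )
        chosen = left if rng.random() < trace.p_i else right
        rows.append(
            {
                "subject": subject,
                "phase": "test",
                "block": rec.block,
                "trial": rec.trial,
                "pair_id": rec.pair_id,
                "pair_type": rec.pair_type,
                "condition": rec.condition,
                "option_left": left,
                "option_right": right,
                "choice": chosen,
                "outcome": np.nan,
            }
        )
    return rows


def subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(index)])


def generate_cohort(
    n_subjects: int,
    model_id: str,
    design: ExperimentDesign,
    seed: int,
    sampler: ParameterSampler | None = None,
    test_sampler: ParameterSampler | None = None,
    include_test: bool = True,
    test_model_id: str | None = None,
) -> BehaviorDataset:
    """Simulate a cohort of virtual participants.

    Learning-phase parameters come from ``sampler`` (default: uniform over
    the fitted ranges); test-phase decision weights are an independent draw
    from ``test_sampler`` (default: the decision-weight part of ``sampler``).
    ``test_model_id`` lets test choices follow a different decision rule
    than the one used during learning (default: same model). Each subject
    gets their own schedule randomization and RNG stream.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    test_model_id = test_model_id or model_id
    sampler = sampler or default_sampler(model_id)
    test_sampler = test_sampler or decider_sampler(sampler, test_model_id)

    all_rows = []
    true_params = {}
    for i in range(n_subjects):
        rng = subject_rng(seed, i)
        subject = f"s{i:03d}"
        sched_seed = int(rng.integers(2**31))
        learn_sched = build_learning_schedule(design, sched_seed)
        params = sampler.sample(rng)
        rows, state = simulate_learning_phase(
            model_id, params, design, learn_sched, rng, subject=subject
        )
        all_rows.extend(rows)
        params_test = test_sampler.sample(rng)
        if include_test:
            test_sched = build_test_schedule(design, learn_sched, int(rng.integers(2**31)))
            all_rows.extend(
                simulate_test_phase(
                    test_model_id, params_test, state, test_sched, rng, subject=subject
                )
            )
        true_params[subject] = {"learning": params, "test": params_test}

    trials = pd.DataFrame(all_rows, columns=TRIAL_COLUMNS)
    manifest = {
        "model_id": model_id,
        "test_model_id": test_model_id,
        "design": design.name,
        "seed": int(seed),
        "n_subjects": int(n_subjects),
        "sampler": sampler.to_dict(),
        "test_sampler": test_sampler.to_dict(),
        "true_params": true_params,
    }
    return BehaviorDataset(trials=trials, design=design, manifest=manifest)
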