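"""Model registry: learner x decider combinations and their free parameters.

A model id is "<learner>:<decider>", e.g. "kalman:qu". Parameter vectors
are ordered [learner params..., decider params...]. Learning rates are
bounded to [0, 1] and decision weights to [-20, 20]; fitting priors are
independent Gaussians with mean 0.5 (rates) or 0 (weights) and variance
16.25, truncated by the bounds.
"""

from __future__ import annotations

import numpy as np

from .deciders import DECIDER_IDS, DECIDER_PARAMS
from .learners import ALPHA_BOUNDS, BETA_BOUNDS, LEARNER_IDS, LEARNER_PARAMS

#: all twelve learner x decider combinations, learners major
MODEL_IDS = tuple(f"{lrn}:{dec}" for lrn in LEARNER_IDS for dec in DECIDER_IDS)

PRIOR_VARIANCE = 16.25
PRIOR_MEAN_ALPHA = 0.5
PRIOR_MEAN_BETA = 0.0


def split_model_id(model_id: str) -> tuple:
    try:
        learner_id, decider_id = model_id.split(":", 1)
    except ValueError:
        raise ValueError(f"model id must be '<learner>:<decider>', got {model_id!r}") from None
    if learner_id not in LEARNER_IDS:
        raise ValueError(f"unknown learner {learner_id!r}")
    if decider_id not in DECIDER_IDS:
        raise ValueError(f"unknown decider {decider_id!r}")
    return learner_id, decider_id


def model_param_names(model_id: str, phase: str = "learning") -> tuple:
    """Free parameters of a model fit. Identical for both phases: test-phase
    fits replay learning with the same learner parameters, then score test
    choices with the decision weights."""
    learner_id, decider_id = split_model_id(model_id)
    return LEARNER_PARAMS[learner_id] + DECIDER_PARAMS[decider_id]


def n_learner_params(model_id: str) -> int:
    learner_id, _ = split_model_id(model_id)
    return len(LEARNER_PARAMS[learner_id])


def is_rate(name: str) -> bool:
    return name.startswith("alpha")


def model_bounds(model_id: str) -> list:
    return [ALPHA_BOUNDS if is_rate(n) else BETA_BOUNDS for n in model_param_names(model_id)]


def default_prior(model_id: str) -> tuple:
    """(means, variances) of the independent Gaussian priors."""
    names = model_param_names(model_id)
    means = np.array([PRIOR_MEAN_ALPHA if is_rate(n) else PRIOR_MEAN_BETA for n in names])
    variances = np.full(len(names), PRIOR_VARIANCE)
    return means, variances
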