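"""Learning models: belief initialization and per-trial update rules.

Six learners are implemented, all updating an expected value ``q`` per
option from the chosen option's outcome (partial feedback):

* ``1alpha`` — Q-learning with one learning rate.
* ``2alpha`` — separate learning rates for positive/negative prediction errors.
* ``select_reject`` — also updates the rejected option with the
  reverse-signed prediction error of the selected option.
* ``relative`` — centers outcomes on a learned context value V_c.
* ``range`` — normalizes outcomes by learned context range trackers
  (R_MAX, R_MIN), so values live in [0, 1].
* ``kalman`` — Kalman-filter learning: a per-option estimation-uncertainty
  sigma yields a dynamic learning rate alpha = sigma^2/(sigma^2 + sigma0^2)
  and shrinks with every observation; no free learning-rate parameter.

Any non-Kalman learner can be composed with the Kalman sigma-recursion
(:func:`attach_uncertainty_tracker`) so that an uncertainty-sensitive
decision rule can be used on top of it: sigma depends only on which option
was sampled, not on how its value is learned.

Values and uncertainties are initialized from the experiment-wide outcome
alphabet with equal probabilities: q0 is its mean and sigma0 its standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .designs import ExperimentDesign

ALPHA_BOUNDS = (0.0, 1.0)
BETA_BOUNDS = (-20.0, 20.0)

LEARNER_IDS = ("1alpha", "2alpha", "select_reject", "relative", "range", "kalman")

#: free parameters of each learner, in canonical order
LEARNER_PARAMS = {
    "1alpha": ("alpha",),
    "2alpha": ("alpha_plus", "alpha_minus"),
    "select_reject": ("alpha_selected", "alpha_rejected"),
    "relative": ("alpha", "alpha_c"),
    "range": ("alpha", "alpha_r"),
    "kalman": (),
}


@dataclass
class OptionBelief:
    q: float
    sigma: float
    n_obs: int = 0


@dataclass
class ContextBelief:
    v: float = 0.0
    r_max: float = 0.0
    r_min: float = 0.0


@dataclass
class UpdateTrace:
    delta: float = 0.0
    alpha_used: float = 0.0
    r_effective: float = 0.0


@dataclass
class BeliefState:
    options: dict = field(default_factory=dict)
    contexts: dict = field(default_factory=dict)
    q0: float = 0.0
    sigma0: float = 1.0


def alphabet_stats(alphabet) -> tuple:
    """(q0, sigma0) of the categorical distribution with p(r) = 1/|alphabet|."""
    r = np.asarray(alphabet, dtype=float)
    q0 = float(r.mean())
    sigma0 = float(np.sqrt(np.mean(r**2) - q0**2))
    return q0, sigma0


def init_beliefs(model_id: str, design: ExperimentDesign) -> BeliefState:
    """Fresh beliefs for a learner on a design.

    Every option starts at (q0, sigma0); context trackers start at
    V_c = 0 and R_MAX = R_MIN = 0 (zero is the omnipresent non-reward
    outcome in all supported designs).
    """
    learner = model_id.split(":", 1)[0]
    if learner not in LEARNER_IDS:
        raise ValueError(f"unknown learner {learner!r}")
    q0, sigma0 = alphabet_stats(design.outcome_alphabet)
    state = BeliefState(q0=q0, sigma0=sigma0)
    for oid in design.option_ids():
        state.options[oid] = OptionBelief(q=q0, sigma=sigma0)
    for pair in design.learning_pairs:
        state.contexts[pair.pair_id] = ContextBelief()
    return state


# ---------------------------------------------------------------------------
# single-step update rules (pure arithmetic, used by the Learner classes)
# ---------------------------------------------------------------------------

def qlearn_update(q: float, alpha: float, outcome: float) -> tuple:
    delta = outcome - q
    return q + alpha * delta, UpdateTrace(delta=delta, alpha_used=alpha, r_effective=outcome)


def dual_rate_update(q: float, alpha_plus: float, alpha_minus: float, outcome: float) -> tuple:
    delta = outcome - q
    if delta > 0:
        alpha = alpha_plus
    elif delta < 0:
        alpha = alpha_minus
    else:
        alpha = 0.0  # neither branch applies at delta == 0
    return q + alpha * delta, UpdateTrace(delta=delta, alpha_used=alpha, r_effective=outcome)


def select_reject_update(
    q_selected: float,
    q_rejected: float,
    alpha_selected: float,
    alpha_rejected: float,
    outcome: float,
) -> tuple:
    delta = outcome - q_selected
    new_sel = q_selected + alpha_selected * delta
    new_rej = q_rejected + alpha_rejected * (-delta)
    return new_sel, new_rej, UpdateTrace(delta=delta, alpha_used=alpha_selected, r_effective=outcome)


def relative_update(
    q_selected: float,
    q_rejected: float,
    v_context: float,
    alpha: float,
    alpha_c: float,
    outcome: float,
) -> tuple:
    delta = outcome - v_context - q_selected
    new_q = q_selected + alpha * delta
    delta_c = (outcome + q_rejected) / 2.0 - v_context
    new_v = v_context + alpha_c * delta_c
    return new_q, new_v, UpdateTrace(delta=delta, alpha_used=alpha, r_effective=outcome - v_context)


def range_update(
    q_selected: float,
    r_max: float,
    r_min: float,
    alpha: float,
    alpha_r: float,
    outcome: float,
) -> tuple:
    r_ran = (outcome - r_min) / (1.0 + r_max - r_min)
    delta = r_ran - q_selected
    new_q = q_selected + alpha * delta
    if outcome > r_max:
        r_max = r_max + alpha_r * (outcome - r_max)
    if outcome < r_min:
        r_min = r_min + alpha_r * (outcome - r_min)
    return new_q, r_max, r_min, UpdateTrace(delta=delta, alpha_used=alpha, r_effective=r_ran)


def kalman_gain(sigma: float, sigma0: float) -> float:
    var = sigma * sigma
    return var / (var + sigma0 * sigma0)


def kalman_update(q: float, sigma: float, sigma0: float, outcome: float) -> tuple:
    """Kalman value-and-uncertainty update for the observed option."""
    alpha = kalman_gain(sigma, sigma0)
    delta = outcome - q
    new_q = q + alpha * delta
    new_var = sigma * sigma - alpha * sigma * sigma
    return new_q, float(np.sqrt(new_var)), UpdateTrace(
        delta=delta, alpha_used=alpha, r_effective=outcome
    )


def sigma_recursion(sigma: float, sigma0: float) -> float:
    """One step of the uncertainty shrinkage for an observed option."""
    alpha = kalman_gain(sigma, sigma0)
    var = sigma * sigma - alpha * sigma * sigma
    return float(np.sqrt(var))


# ---------------------------------------------------------------------------
# stateful learners
# ---------------------------------------------------------------------------

class Learner:
    """A learning rule applied to a :class:`BeliefState` trial by trial.

    ``track_uncertainty`` runs the Kalman sigma-recursion on the chosen
    option alongside the value update, which lets an uncertainty-sensitive
    decider (QU) be used with any value-learning rule.
    """

    learner_id: str = ""

    def __init__(self, track_uncertainty: bool = False):
        self.track_uncertainty = track_uncertainty or self.learner_id == "kalman"

    @property
    def param_names(self) -> tuple:
        return LEARNER_PARAMS[self.learner_id]

    def step(
        self,
        state: BeliefState,
        pair_id: str,
        chosen: str,
        unchosen: str,
        outcome: float,
        params: dict,
    ) -> UpdateTrace:
        trace = self._update_values(state, pair_id, chosen, unchosen, outcome, params)
        opt = state.options[chosen]
        if self.track_uncertainty and self.learner_id != "kalman":
            opt.sigma = sigma_recursion(opt.sigma, state.sigma0)
        opt.n_obs += 1
        return trace

    def _update_values(self, state, pair_id, chosen, unchosen, outcome, params):
        raise NotImplementedError


class OneAlpha(Learner):
    learner_id = "1alpha"

    def _update_values(self, state, pair_id, chosen, unchosen, outcome, params):
        opt = state.options[chosen]
        opt.q, trace = qlearn_update(opt.q, params["alpha"], outcome)
        return trace


class TwoAlpha(Learner):
    learner_id = "2alpha"

    def _update_values(self, state, pair_id, chosen, unchosen, outcome, params):
        opt = state.options[chosen]
        opt.q, trace = dual_rate_update(
            opt.q, params["alpha_plus"], params["alpha_minus"], outcome
        )
        return trace


class SelectReject(Learner):
    learner_id = "select_reject"

    def _update_values(self, state, pair_id, chosen, unchosen, outcome, params):
        sel, rej = state.options[chosen], state.options[unchosen]
        sel.q, rej.q, trace = select_reject_update(
            sel.q, rej.q, params["alpha_selected"], params["alpha_rejected"], outcome
        )
        return trace


class Relative(Learner):
    learner_id = "relative"

    def _update_values(self, state, pair_id, chosen, unchosen, outcome, params):
        sel, rej = state.options[chosen], state.options[unchosen]
        ctx = state.contexts[pair_id]
        sel.q, ctx.v, trace = relative_update(
            sel.q, rej.q, ctx.v, params["alpha"], params["alpha_c"], outcome
        )
        return trace


class Range(Learner):
    learner_id = "range"

    def _update_values(self, state, pair_id, chosen, unchosen, outcome, params):
        sel = state.options[chosen]
        ctx = state.contexts[pair_id]
        sel.q, ctx.r_max, ctx.r_min, trace = range_update(
            sel.q, ctx.r_max, ctx.r_min, params["alpha"], params["alpha_r"], outcome
        )
        return trace


class Kalman(Learner):
    learner_id = "kalman"

    def _update_values(self, state, pair_id, chosen, unchosen, outcome, params):
        opt = state.options[chosen]
        opt.q, opt.sigma, trace = kalman_update(opt.q, opt.sigma, state.sigma0, outcome)
        return trace


_LEARNER_CLASSES = {
    cls.learner_id: cls for cls in (OneAlpha, TwoAlpha, SelectReject, Relative, Range, Kalman)
}


def make_learner(learner_id: str, track_uncertainty: bool = False) -> Learner:
    try:
        cls = _LEARNER_CLASSES[learner_id]
    except KeyError:
        raise ValueError(f"unknown learner {learner_id!r}") from None
    return cls(track_uncertainty=track_uncertainty)


def attach_uncertainty_tracker(learner) -> Learner:
    """Compose a value learner with the Kalman sigma-recursion.

    Accepts a learner id or instance; returns a learner whose q follows the
    base rule and whose sigma shrinks exactly as the Kalman filter's would
    for the same choice sequence.
    """
    if isinstance(learner, Learner):
        learner_id = learner.learner_id
    else:
        learner_id = learner
    return make_learner(learner_id, track_uncertainty=True)
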