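"""Decision models: option utilities and the softmax choice rule.

Model Q scores options by expected value alone, u = q * beta_Q; model QU
adds the estimation-uncertainty term, u = q * beta_Q + sigma * beta_U.
A negative beta_U makes uncertain options aversive. Choice probabilities
come from a two-option softmax, computed as a numerically stable logistic
of the utility difference (decision weights up to |20| combined with
magnitude-10 rewards make naive exponentiation overflow).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.special import log_expit
from scipy.special import expit as _expit

DECIDER_IDS = ("q", "qu")

DECIDER_PARAMS = {
    "q": ("beta_q",),
    "qu": ("beta_q", "beta_u"),
}


@dataclass
class DecisionTrace:
    u_i: float
    u_j: float
    p_i: float


def utility_q(q: float, beta_q: float) -> float:
    return q * beta_q


def utility_qu(q: float, sigma: float, beta_q: float, beta_u: float) -> float:
    return q * beta_q + sigma * beta_u


def utility(decider_id: str, belief, params: dict) -> float:
    if decider_id == "q":
        return utility_q(belief.q, params["beta_q"])
    if decider_id == "qu":
        return utility_qu(belief.q, belief.sigma, params["beta_q"], params["beta_u"])
    raise ValueError(f"unknown decider {decider_id!r}")


def softmax_prob(u_i: float, u_j: float) -> float:
    """P(choose i) = e^{u_i} / (e^{u_i} + e^{u_j}), as a stable logistic."""
    return float(_expit(u_i - u_j))


def log_softmax_prob(u_i: float, u_j: float) -> float:
    """log P(choose i); stable for large negative utility differences."""
    return float(log_expit(u_i - u_j))


def choice_probability(decider_id: str, belief_i, belief_j, params: dict) -> DecisionTrace:
    u_i = utility(decider_id, belief_i, params)
    u_j = utility(decider_id, belief_j, params)
    return DecisionTrace(u_i=u_i, u_j=u_j, p_i=softmax_prob(u_i, u_j))
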