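"""JIT-compiled replay kernels used by model fitting.

The per-trial update recursions are inherently sequential, so the
likelihood of a subject's choice sequence is computed by a single compiled
loop over trials. The kernel mirrors the reference update rules in
:mod:`ubandit.learners` exactly; a cross-check test holds the two paths to
machine precision.

Encodings: learners 0=1alpha, 1=2alpha, 2=select_reject, 3=relative,
4=range, 5=kalman; deciders 0=Q, 1=QU; phases 0=learning, 1=test.
Parameter vectors are laid out [learner params..., beta_q, (beta_u)].
"""

from __future__ import annotations

import numpy as np
from numba import njit

LEARNER_CODE = {
    "1alpha": 0,
    "2alpha": 1,
    "select_reject": 2,
    "relative": 3,
    "range": 4,
    "kalman": 5,
}
DECIDER_CODE = {"q": 0, "qu": 1}
PHASE_CODE = {"learning": 0, "test": 1}


@njit(cache=True)
def _log_logistic(d):
    # log(1/(1+exp(-d))) without overflow
    if d >= 0.0:
        return -np.log1p(np.exp(-d))
    return d - np.log1p(np.exp(d))


@njit(cache=True)
def replay_negll(
    params,
    learner,
    n_learner_params,
    decider,
    phase,
    chosen,
    unchosen,
    ctx,
    outcome,
    n_options,
    n_ctx,
    q0,
    sigma0,
    score_phase,
):
    """Negative log-likelihood of the scored phase's choices under replay.

    Learning trials always update beliefs (using the subject's recorded
    choice and outcome); test trials never do. Only trials whose phase
    equals ``score_phase`` contribute to the likelihood.
    """
    q = np.full(n_options, q0)
    var = np.full(n_options, sigma0 * sigma0)
    v = np.zeros(n_ctx)
    rmax = np.zeros(n_ctx)
    rmin = np.zeros(n_ctx)
    s02 = sigma0 * sigma0

    beta_q = params[n_learner_params]
    beta_u = params[n_learner_params + 1] if decider == 1 else 0.0

    ll = 0.0
    for t in range(phase.shape[0]):
        c = chosen[t]
        u = unchosen[t]
        if phase[t] == score_phase:
            d = (q[c] - q[u]) * beta_q
            if decider == 1:
                d += (np.sqrt(var[c]) - np.sqrt(var[u])) * beta_u
            ll += _log_logistic(d)
        if phase[t] == 0:
            k = ctx[t]
            r = outcome[t]
            if learner == 0:
                q[c] += params[0] * (r - q[c])
            elif learner == 1:
                delta = r - q[c]
                if delta > 0.0:
                    q[c] += params[0] * delta
                elif delta < 0.0:
                    q[c] += params[1] * delta
            elif learner == 2:
                delta = r - q[c]
                q[u] += params[1] * (-delta)
                q[c] += params[0] * delta
            elif learner == 3:
                delta = r - v[k] - q[c]
                q[c] += params[0] * delta
                v[k] += params[1] * ((r + q[u]) / 2.0 - v[k])
            elif learner == 4:
                r_ran = (r - rmin[k]) / (1.0 + rmax[k] - rmin[k])
                q[c] += params[0] * (r_ran - q[c])
                if r > rmax[k]:
                    rmax[k] += params[1] * (r - rmax[k])
                if r < rmin[k]:
                    rmin[k] += params[1] * (r - rmin[k])
            else:  # kalman
                a = var[c] / (var[c] + s02)
                q[c] += a * (r - q[c])
                var[c] -= a * var[c]
            if learner != 5:
                # uncertainty tracker: sigma recursion for the sampled option
                a = var[c] / (var[c] + s02)
                var[c] -= a * var[c]
    return -ll
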