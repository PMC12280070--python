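"""Subject-level likelihoods, MAP estimation and Laplace model evidence.

Each model is fit separately to the learning and the test phase. Learning
fits replay the subject's recorded choices and outcomes, scoring the
softmax probability of each choice before the belief update. Test fits
replay the full learning history (the subject's own sampling determines
what was observed under partial feedback) to obtain frozen beliefs, then
score the test choices only; any learner parameters are fit jointly with
the test-phase decision weights.

MAP estimation maximizes log-likelihood + log-prior with bounded L-BFGS-B
from multiple restarts; priors are bound-truncated Gaussians (mean 0.5 for
learning rates, 0 for decision weights, variance 16.25). Model evidence is
a Laplace approximation around the MAP, with a finite-difference Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._kernels import DECIDER_CODE, LEARNER_CODE, PHASE_CODE, replay_negll
from .cohort import BehaviorDataset
from .learners import alphabet_stats
from .models import (
    default_prior,
    model_bounds,
    model_param_names,
    n_learner_params,
    split_model_id,
)

LOG_HALF = float(np.log(0.5))


@dataclass
class SubjectArrays:
    """A subject's trials encoded for the replay kernel."""

    phase: np.ndarray
    chosen: np.ndarray
    unchosen: np.ndarray
    ctx: np.ndarray
    outcome: np.ndarray
    n_options: int
    n_ctx: int
    q0: float
    sigma0: float

    def n_scored(self, phase: str) -> int:
        return int((self.phase == PHASE_CODE[phase]).sum())


def subject_arrays(dataset: BehaviorDataset, subject) -> SubjectArrays:
    """Encode one subject's chronologically ordered trials as index arrays."""
    df = dataset.subject_trials(subject)
    design = dataset.design
    opt_index = {oid: i for i, oid in enumerate(design.option_ids())}
    ctx_index = {p.pair_id: i for i, p in enumerate(design.learning_pairs)}

    phase = df["phase"].map(PHASE_CODE).to_numpy(dtype=np.int64)
    choice = df["choice"].to_numpy()
    left = df["option_left"].to_numpy()
    right = df["option_right"].to_numpy()
    other = np.where(choice == left, right, left)
    chosen = np.array([opt_index[o] for o in choice], dtype=np.int64)
    unchosen = np.array([opt_index[o] for o in other], dtype=np.int64)
    ctx = np.array(
        [ctx_index.get(p, -1) for p in df["pair_id"]], dtype=np.int64
    )
    outcome = df["outcome"].to_numpy(dtype=float)
    outcome = np.where(np.isnan(outcome), 0.0, outcome)
    if (ctx[phase == 0] < 0).any():
        raise ValueError("learning trial with unknown pair id")
    q0, sigma0 = alphabet_stats(design.outcome_alphabet)
    return SubjectArrays(
        phase=phase,
        chosen=chosen,
        unchosen=unchosen,
        ctx=np.where(ctx < 0, 0, ctx),
        outcome=outcome,
        n_options=len(opt_index),
        n_ctx=len(ctx_index),
        q0=q0,
        sigma0=sigma0,
    )


def phase_log_likelihood(
    model_id: str, params, arrays: SubjectArrays, phase: str = "learning"
) -> float:
    """Log-likelihood (nats) of the given phase's choices under the model."""
    learner_id, decider_id = split_model_id(model_id)
    names = model_param_names(model_id)
    if isinstance(params, dict):
        vec = np.array([params[n] for n in names], dtype=float)
    else:
        vec = np.asarray(params, dtype=float)
    if vec.shape != (len(names),):
        raise ValueError(f"expected {len(names)} parameters for {model_id}")
    if phase == "test" and not (arrays.phase == 0).any() and (arrays.phase == 1).any():
        # test choices cannot be scored without the learning history that
        # produced the beliefs, except for learners without free parameters
        # -- but even those need the sampling counts; refuse.
        raise ValueError("test-phase likelihood requires the learning history")
    nll = replay_negll(
        vec,
        LEARNER_CODE[learner_id],
        n_learner_params(model_id),
        DECIDER_CODE[decider_id],
        arrays.phase,
        arrays.chosen,
        arrays.unchosen,
        arrays.ctx,
        arrays.outcome,
        arrays.n_options,
        max(arrays.n_ctx, 1),
        arrays.q0,
        arrays.sigma0,
        PHASE_CODE[phase],
    )
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite likelihood (degenerate parameters?)")
    return -float(nll)


def pseudo_r2(log_likelihood: float, n_trials: int) -> float:
    """McFadden pseudo-R^2: 1 - LL_model / LL_null, null = coin flip per trial."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return 1.0 - log_likelihood / (n_trials * LOG_HALF)


@dataclass
class TruncGaussPrior:
    """Independent Gaussians truncated to the parameter bounds."""

    means: np.ndarray
    variances: np.ndarray
    bounds: list

    @classmethod
    def for_model(cls, model_id: str, variance_scale: float = 1.0) -> "TruncGaussPrior":
        means, variances = default_prior(model_id)
        return cls(means=means, variances=variances * variance_scale, bounds=model_bounds(model_id))

    def log_pdf(self, x: np.ndarray) -> float:
        """Normalized log-density over the truncated support."""
        sd = np.sqrt(self.variances)
        total = 0.0
        for xi, mu, s, (lo, hi) in zip(x, self.means, sd, self.bounds):
            z = stats.norm.cdf(hi, mu, s) - stats.norm.cdf(lo, mu, s)
            total += stats.norm.logpdf(xi, mu, s) - np.log(z)
        return float(total)

    def quad_penalty(self, x: np.ndarray) -> float:
        """Parameter-dependent part of -log prior (for optimization)."""
        return float(0.5 * np.sum((x - self.means) ** 2 / self.variances))

    def log_norm_const(self) -> float:
        """Constant part of the log-density (Gaussian + truncation norms)."""
        sd = np.sqrt(self.variances)
        total = 0.0
        for mu, s, (lo, hi) in zip(self.means, sd, self.bounds):
            z = stats.norm.cdf(hi, mu, s) - stats.norm.cdf(lo, mu, s)
            total += -0.5 * np.log(2 * np.pi * s * s) - np.log(z)
        return float(total)


@dataclass
class FitResult:
    subject: object
    model_id: str
    phase: str
    map_params: dict
    log_likelihood: float
    log_evidence: float
    pseudo_r2: float
    n_trials: int
    converged: bool
    n_restarts: int
    log_posterior: float = float("nan")
    hessian: np.ndarray | None = field(default=None, repr=False)


def _neg_log_posterior(model_id, arrays, phase, prior):
    learner_id, decider_id = split_model_id(model_id)
    lcode = LEARNER_CODE[learner_id]
    dcode = DECIDER_CODE[decider_id]
    nlp_count = n_learner_params(model_id)
    score = PHASE_CODE[phase]
    nctx = max(arrays.n_ctx, 1)

    def nlp(x):
        nll = replay_negll(
            x,
            lcode,
            nlp_count,
            dcode,
            arrays.phase,
            arrays.chosen,
            arrays.unchosen,
            arrays.ctx,
            arrays.outcome,
            arrays.n_options,
            nctx,
            arrays.q0,
            arrays.sigma0,
            score,
        )
        return nll + prior.quad_penalty(np.asarray(x))

    return nlp


def fit_map(
    model_id: str,
    arrays: SubjectArrays,
    phase: str = "learning",
    prior: TruncGaussPrior | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    subject="s0",
    compute_evidence: bool = True,
) -> FitResult:
    """Best-of-restarts bounded MAP fit of one subject, one model, one phase."""
    prior = prior or TruncGaussPrior.for_model(model_id)
    bounds = model_bounds(model_id)
    names = model_param_names(model_id)
    nlp = _neg_log_posterior(model_id, arrays, phase, prior)
    rng = np.random.default_rng(seed)

    starts = [np.clip(prior.means, [b[0] for b in bounds], [b[1] for b in bounds])]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))

    best = None
    n_ok = 0
    for x0 in starts:
        try:
            res = optimize.minimize(nlp, x0, method="L-BFGS-B", bounds=bounds)
        except FloatingPointError:
            continue
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        return FitResult(
            subject=subject,
            model_id=model_id,
            phase=phase,
            map_params={n: float("nan") for n in names},
            log_likelihood=float("nan"),
            log_evidence=float("nan"),
            pseudo_r2=float("nan"),
            n_trials=arrays.n_scored(phase),
            converged=False,
            n_restarts=len(starts),
        )

    x = np.asarray(best.x, dtype=float)
    ll = phase_log_likelihood(model_id, x, arrays, phase)
    n_trials = arrays.n_scored(phase)
    result = FitResult(
        subject=subject,
        model_id=model_id,
        phase=phase,
        map_params={n: float(v) for n, v in zip(names, x)},
        log_likelihood=ll,
        log_evidence=float("nan"),
        pseudo_r2=pseudo_r2(ll, n_trials),
        n_trials=n_trials,
        converged=n_ok > 0,
        n_restarts=len(starts),
        log_posterior=-float(best.fun),
    )
    if compute_evidence:
        result.log_evidence = laplace_log_evidence(model_id, arrays, phase, result, prior)
    return result


def _fd_hessian(f, x, bounds, rel_step=1e-4):
    """Central finite-difference Hessian, with steps shrunk at the bounds."""
    d = len(x)
    h = np.array([rel_step * (1.0 + abs(xi)) for xi in x])
    for i, (lo, hi) in enumerate(bounds):
        h[i] = min(h[i], max((hi - lo) * 0.5 * 1e-2, 1e-8))
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / (h[i] ** 2)
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4.0 * h[i] * h[j]
                )
    return H


def laplace_log_evidence(
    model_id: str,
    arrays: SubjectArrays,
    phase: str,
    fit: FitResult,
    prior: TruncGaussPrior | None = None,
    min_eigenvalue: float | None = None,
) -> float:
    """ln p(data | model) by a bound-aware Laplace approximation at the MAP.

    ln p ~= LL(MAP) + ln prior(MAP) + sum_i ln v_i, where v_i is the
    Gaussian integral sqrt(2*pi / w_i) along the i-th eigendirection of
    the negative-log-posterior Hessian, truncated at the width of the
    feasible parameter box along that direction. Truncation matters for
    weakly identified bounded parameters (a flat learning rate on [0, 1]):
    the untruncated integral would overstate the evidence of the more
    flexible model. Eigenvalues are floored at the prior precision, which
    is the exact curvature a flat likelihood direction must carry (the
    optimized objective includes the prior); this also regularizes a
    finite-difference Hessian at a bound. Models with no free parameters
    return the exact log-likelihood.
    """
    prior = prior or TruncGaussPrior.for_model(model_id)
    names = model_param_names(model_id)
    if not names:
        return fit.log_likelihood
    x = np.array([fit.map_params[n] for n in names], dtype=float)
    if not np.all(np.isfinite(x)):
        return float("nan")
    bounds = model_bounds(model_id)
    nlp = _neg_log_posterior(model_id, arrays, phase, prior)
    H = _fd_hessian(nlp, x, bounds)
    w, v = np.linalg.eigh(0.5 * (H + H.T))
    if min_eigenvalue is None:
        min_eigenvalue = float(1.0 / np.max(prior.variances))
    w = np.clip(w, min_eigenvalue, None)
    widths = np.array([hi - lo for lo, hi in bounds])
    log_volume = 0.0
    for i in range(len(w)):
        box_extent = float(np.abs(v[:, i]) @ widths)
        log_volume += min(0.5 * np.log(2.0 * np.pi / w[i]), np.log(box_extent))
    log_prior = prior.log_norm_const() - prior.quad_penalty(x)
    fit.hessian = (v * w) @ v.T
    return fit.log_likelihood + log_prior + log_volume


def fit_dataset(
    dataset: BehaviorDataset,
    model_ids,
    phase: str = "learning",
    n_restarts: int = 10,
    seed: int = 0,
    prior_variance_scale: float = 1.0,
) -> pd.DataFrame:
    """Fit every subject with every model; tidy DataFrame of FitResults."""
    if isinstance(model_ids, str):
        model_ids = [model_ids]
    rows = []
    for s_idx, subject in enumerate(dataset.subjects):
        arrays = subject_arrays(dataset, subject)
        for m_idx, model_id in enumerate(model_ids):
            prior = TruncGaussPrior.for_model(model_id, prior_variance_scale)
            fit = fit_map(
                model_id,
                arrays,
                phase=phase,
                prior=prior,
                n_restarts=n_restarts,
                seed=int(np.random.default_rng([seed, s_idx, m_idx]).integers(2**31)),
                subject=subject,
            )
            row = {
                "subject": subject,
                "model_id": model_id,
                "phase": phase,
                "log_likelihood": fit.log_likelihood,
                "log_evidence": fit.log_evidence,
                "pseudo_r2": fit.pseudo_r2,
                "n_trials": fit.n_trials,
                "converged": fit.converged,
            }
            for name, value in fit.map_params.items():
                row[f"param_{name}"] = value
            rows.append(row)
    return pd.DataFrame(rows)
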