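"""Random-effects Bayesian model selection over subject-level evidences.

Treats the model identity as a random effect across subjects: model
frequencies r follow a Dirichlet whose posterior is estimated by
variational Bayes from the matrix of subject x model log-evidences.
Exceedance probabilities (probability a model is the most frequent) are
computed by Dirichlet Monte Carlo; protected exceedance probabilities
additionally account for the possibility that all models are equally
frequent, via the Bayesian omnibus risk (BOR):

    PXP_k = EP_k * (1 - BOR) + BOR / K
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp


@dataclass
class BMSResult:
    model_ids: list
    alpha: np.ndarray
    model_frequencies: np.ndarray
    exceedance: np.ndarray
    protected_exceedance: np.ndarray
    bor: float
    free_energy: float

    def as_dict(self) -> dict:
        return {
            "model_ids": list(self.model_ids),
            "alpha": self.alpha.tolist(),
            "model_frequencies": self.model_frequencies.tolist(),
            "exceedance": self.exceedance.tolist(),
            "protected_exceedance": self.protected_exceedance.tolist(),
            "bor": float(self.bor),
            "free_energy": float(self.free_energy),
        }


def _vb_dirichlet(lme: np.ndarray, alpha0: float, max_iter: int, tol: float):
    n, k = lme.shape
    alpha = np.full(k, alpha0, dtype=float)
    u = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        e_log_r = digamma(alpha) - digamma(alpha.sum())
        log_u = lme + e_log_r
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    return alpha, u


def _free_energy(lme, u, alpha, alpha0):
    """Variational free energy of the random-effects model."""
    k = lme.shape[1]
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    elj = (
        gammaln(k * alpha0)
        - k * gammaln(alpha0)
        + np.sum((alpha0 - 1.0) * e_log_r)
        + np.sum(u * (e_log_r + lme))
    )
    s_qf = (
        np.sum(gammaln(alpha))
        - gammaln(alpha.sum())
        - np.sum((alpha - 1.0) * e_log_r)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        s_qm = -np.sum(np.where(u > 0, u * np.log(u), 0.0))
    return float(elj + s_qf + s_qm)


def exceedance_probabilities(
    alpha: np.ndarray, n_samples: int = 200_000, seed: int = 0
) -> np.ndarray:
    """P(r_k > r_j for all j != k) under Dirichlet(alpha), by Monte Carlo.

    The two-model case uses the exact Beta integral instead.
    """
    alpha = np.asarray(alpha, dtype=float)
    k = len(alpha)
    if k == 1:
        return np.array([1.0])
    if k == 2:
        from scipy.stats import beta

        p = float(beta.cdf(0.5, alpha[1], alpha[0]))
        return np.array([p, 1.0 - p])
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_samples)
    wins = np.bincount(np.argmax(samples, axis=1), minlength=k)
    return wins / n_samples


def rfx_bms(
    log_evidences: np.ndarray,
    model_ids=None,
    alpha0: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_samples: int = 200_000,
    seed: int = 0,
) -> BMSResult:
    """Group-level model selection from a (subjects x models) evidence matrix."""
    lme = np.asarray(log_evidences, dtype=float)
    if lme.ndim != 2:
        raise ValueError("log_evidences must be 2-D (subjects x models)")
    if not np.all(np.isfinite(lme)):
        raise ValueError("non-finite log evidences")
    n, k = lme.shape
    if model_ids is None:
        model_ids = [f"m{i}" for i in range(k)]

    alpha, u = _vb_dirichlet(lme, alpha0, max_iter, tol)
    freqs = alpha / alpha.sum()
    ep = exceedance_probabilities(alpha, n_samples=n_samples, seed=seed)

    # BOR: compare the random-effects free energy against the null model in
    # which every model is equally frequent (fixed r = 1/K).
    f1 = _free_energy(lme, u, alpha, alpha0)
    f0 = float(np.sum(logsumexp(lme, axis=1) - np.log(k)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = ep * (1.0 - bor) + bor / k

    return BMSResult(
        model_ids=list(model_ids),
        alpha=alpha,
        model_frequencies=freqs,
        exceedance=ep,
        protected_exceedance=pxp,
        bor=bor,
        free_energy=f1,
    )
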