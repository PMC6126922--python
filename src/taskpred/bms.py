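"""Random-effects Bayesian model selection over subjects.

Given per-subject log model evidences, model frequencies in the
population are treated as Dirichlet-distributed and inferred by
variational Bayes. The quantities reported are:

* ``dirichlet_alpha`` / ``expected_freq`` — posterior concentrations and
  expected model frequencies;
* ``xp`` — exceedance probabilities, P(model k is the most frequent),
  estimated by seeded Monte Carlo over the Dirichlet posterior;
* ``bor`` — the Bayes omnibus risk, the posterior probability that all
  models are equally frequent (null) rather than differing (alternative),
  from the free energies of the two hypotheses;
* ``pxp`` — protected exceedance probabilities,
  ``pxp = xp * (1 - bor) + bor / K``.

Cross-validated model scores enter as log evidences via the Gaussian
maximum-likelihood identity ``log evidence = -score / 2`` (the score is
``N * ln(MSE)``, proportional to -2 log likelihood up to a
model-independent constant). This bridge is a modeling convention of the
package, flagged in the README.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from ._utils import as_rng

__all__ = [
    "EvidenceMatrix",
    "BMSResult",
    "scores_to_log_evidence",
    "vb_dirichlet",
    "exceedance_probabilities",
    "protected_exceedance",
]


@dataclass(frozen=True)
class EvidenceMatrix:
    """Subjects x models log-evidence array with model names."""

    log_evidence: np.ndarray
    model_names: tuple[str, ...]

    def __post_init__(self):
        ev = np.asarray(self.log_evidence, dtype=float)
        if ev.ndim != 2 or ev.shape[0] < 2 or ev.shape[1] < 2:
            raise ValueError("need at least 2 subjects and 2 models")
        if not np.all(np.isfinite(ev)):
            raise ValueError("log evidences must be finite")
        if len(self.model_names) != ev.shape[1]:
            raise ValueError("model_names must match the number of columns")
        object.__setattr__(self, "log_evidence", ev)


@dataclass
class BMSResult:
    model_names: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    assignment: np.ndarray  # subjects x models posterior model attributions
    free_energy: float
    converged: bool
    xp: np.ndarray | None = None
    bor: float | None = None
    pxp: np.ndarray | None = None
    n_samples: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "model_names": list(self.model_names),
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "free_energy": self.free_energy,
            "converged": self.converged,
        }
        if self.xp is not None:
            out["xp"] = self.xp.tolist()
        if self.bor is not None:
            out["bor"] = self.bor
        if self.pxp is not None:
            out["pxp"] = self.pxp.tolist()
        if self.n_samples is not None:
            out["n_samples"] = self.n_samples
        if self.seed is not None:
            out["seed"] = self.seed
        return out


def scores_to_log_evidence(scores, model_names=None) -> EvidenceMatrix:
    """Convert a subjects x models score matrix to log evidences (-score/2)."""
    if isinstance(scores, pd.DataFrame):
        model_names = tuple(scores.columns)
        scores = scores.to_numpy(dtype=float)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if model_names is None:
        model_names = tuple(f"m{k}" for k in range(scores.shape[1]))
    return EvidenceMatrix(log_evidence=-scores / 2.0, model_names=tuple(model_names))


def _ln_dirichlet_norm(alpha: np.ndarray) -> float:
    return float(gammaln(alpha.sum()) - gammaln(alpha).sum())


def vb_dirichlet(
    ev: EvidenceMatrix,
    prior_alpha: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> BMSResult:
    """Variational posterior over model frequencies.

    Fixed-point iteration: subject-model attribution weights are
    proportional to ``exp(log_evidence + digamma(alpha_k) -
    digamma(sum alpha))``; the concentrations are the prior plus the
    summed attributions. Converged when the largest concentration change
    falls below ``tol``. The returned free energy is the variational
    bound of the alternative hypothesis (used for the omnibus risk).
    """
    if prior_alpha <= 0:
        raise ValueError("prior_alpha must be positive")
    lme = ev.log_evidence
    n, k = lme.shape
    alpha0 = np.full(k, float(prior_alpha))
    alpha = alpha0.copy()
    converged = False
    u = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        logu = lme + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    if not converged:
        warnings.warn("vb_dirichlet did not converge; returning last iterate", stacklevel=2)
    # variational free energy of H1 at convergence
    with np.errstate(divide="ignore", invalid="ignore"):
        ulogu = np.where(u > 0, u * np.log(u), 0.0)
    f1 = float((u * lme).sum() - ulogu.sum() + _ln_dirichlet_norm(alpha0) - _ln_dirichlet_norm(alpha))
    return BMSResult(
        model_names=ev.model_names,
        dirichlet_alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        assignment=u,
        free_energy=f1,
        converged=converged,
    )


def exceedance_probabilities(
    alpha: np.ndarray,
    n_samples: int = 1_000_000,
    seed: int | None = None,
) -> np.ndarray:
    """Monte Carlo P(freq_k > freq_j for all j) under Dirichlet(alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    if n_samples < 1_000:
        warnings.warn("fewer than 1000 samples; exceedance estimates will be coarse", stacklevel=2)
    rng = as_rng(seed)
    counts = np.zeros(alpha.size, dtype=np.int64)
    # draw in blocks to bound memory at ~8 MB per block
    block = max(1, min(n_samples, 1_000_000 // max(alpha.size, 1)))
    remaining = n_samples
    while remaining > 0:
        m = min(block, remaining)
        g = rng.standard_gamma(alpha, size=(m, alpha.size))
        counts += np.bincount(np.argmax(g, axis=1), minlength=alpha.size)
        remaining -= m
    return counts / n_samples


def protected_exceedance(
    ev: EvidenceMatrix,
    prior_alpha: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> BMSResult:
    """Full model-selection pipeline: VB, exceedance, omnibus risk, pxp.

    The null hypothesis (all models equally frequent) has exact log
    evidence ``sum_n logsumexp(lme_n) - N ln K``; the Bayes omnibus risk
    is its posterior probability against the variational bound of the
    alternative. Protected exceedance probabilities shrink the exceedance
    probabilities toward uniform by that risk.
    """
    res = vb_dirichlet(ev, prior_alpha=prior_alpha, tol=tol, max_iter=max_iter)
    res.xp = exceedance_probabilities(res.dirichlet_alpha, n_samples=n_samples, seed=seed)
    lme = ev.log_evidence
    n, k = lme.shape
    f0 = float(logsumexp(lme, axis=1).sum() - n * np.log(k))
    bor = float(1.0 / (1.0 + np.exp(res.free_energy - f0)))
    res.bor = bor
    res.pxp = res.xp * (1.0 - bor) + bor / k
    res.n_samples = n_samples
    res.seed = seed if isinstance(seed, int) else None
    return res
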