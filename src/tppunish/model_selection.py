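"""Random-effects Bayesian model selection with protected exceedance
probabilities.

The model identity is treated as a random effect across subjects: the
population frequencies r of the K candidate models get a Dirichlet
prior, each subject's model label a multinomial draw from r, and the
per-subject log evidences enter as likelihoods.  Variational inference
alternates subject-wise responsibilities

    z_nk ∝ exp(lme_nk + psi(alpha_k) - psi(sum alpha))

with the Dirichlet update ``alpha = alpha0 + sum_n z_n`` until the
concentration vector stabilises.

The exceedance probability EP_k = P(r_k > r_j for all j) is estimated
by Dirichlet Monte-Carlo sampling (a closed incomplete-beta form exists
for K = 2 and is kept as a cross-check).  The Bayesian omnibus risk
(BOR) is the posterior probability of the null hypothesis that all
models are equally frequent, computed by comparing the free energy of
the random-effects model with the fixed uniform-frequency null; the
protected exceedance probability shrinks EP toward chance by that risk:

    pEP_k = EP_k * (1 - BOR) + BOR / K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import betainc, digamma, gammaln, logsumexp

__all__ = [
    "BMSResult",
    "rfx_bms",
    "exceedance_probability",
    "exceedance_probability_2model",
    "protected_ep",
    "bms",
]


@dataclass
class BMSResult:
    """Outcome of random-effects model selection.

    ``alpha`` is the posterior Dirichlet concentration over model
    frequencies; ``expected_frequencies`` its mean; ``bor`` the
    posterior probability that no model is preferred (all equally
    frequent); ``protected_ep`` the exceedance probabilities shrunk
    toward chance by that risk.
    """

    alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_probabilities: Optional[np.ndarray] = None
    bor: Optional[float] = None
    protected_ep: Optional[np.ndarray] = None
    responsibilities: Optional[np.ndarray] = None
    free_energy: Optional[float] = None
    null_free_energy: Optional[float] = None
    converged: bool = True
    n_iter: int = 0
    mc_samples: int = 0
    seed: Optional[int] = None
    model_names: Optional[tuple] = None

    def summary(self) -> str:
        names = self.model_names or tuple(
            f"model_{i + 1}" for i in range(len(self.alpha)))
        lines = [f"{'model':24s} {'E[freq]':>8s} {'EP':>8s} {'pEP':>8s}"]
        for i, name in enumerate(names):
            ep = self.exceedance_probabilities
            pep = self.protected_ep
            lines.append(
                f"{name:24s} {self.expected_frequencies[i]:8.3f} "
                f"{(ep[i] if ep is not None else float('nan')):8.3f} "
                f"{(pep[i] if pep is not None else float('nan')):8.3f}"
            )
        if self.bor is not None:
            lines.append(f"Bayesian omnibus risk: {self.bor:.4f}")
        return "\n".join(lines)


def _validate_matrix(lme: np.ndarray) -> np.ndarray:
    lme = np.asarray(lme, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("evidence matrix must be subjects x (>=2) models")
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidence matrix must be finite")
    return lme


def _free_energy(lme, alpha, z, alpha0_vec):
    """Variational free energy of the random-effects model."""
    asum = alpha.sum()
    eln_r = digamma(alpha) - digamma(asum)
    elj = (gammaln(alpha0_vec.sum()) - gammaln(alpha0_vec).sum()
           + ((alpha0_vec - 1.0) * eln_r).sum()
           + (z * (eln_r[None, :] + lme)).sum())
    # entropy of q(r) (Dirichlet) + entropy of q(m) (categorical)
    h_dir = (gammaln(alpha).sum() - gammaln(asum)
             - ((alpha - 1.0) * eln_r).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        h_z = -np.where(z > 0, z * np.log(z), 0.0).sum()
    return float(elj + h_dir + h_z)


def _null_free_energy(lme):
    """Log evidence of the null: every subject picks uniformly among K."""
    n, k = lme.shape
    return float(logsumexp(lme, axis=1).sum() - n * np.log(k))


def rfx_bms(evidence_matrix: np.ndarray, alpha0: float = 1.0,
            tol: float = 1e-8, max_iter: int = 1000) -> BMSResult:
    """Variational Dirichlet-multinomial random-effects model selection.

    Returns the converged concentration vector, expected model
    frequencies, per-subject responsibilities and the variational free
    energy (used later for the omnibus risk).  Only evidence
    *differences* within a subject matter.
    """
    lme = _validate_matrix(evidence_matrix)
    n, k = lme.shape
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    alpha0_vec = np.full(k, float(alpha0))
    # per-subject centering for numerical stability (invariant anyway)
    lme_c = lme - lme.max(axis=1, keepdims=True)
    alpha = alpha0_vec.copy()
    converged = False
    for it in range(1, max_iter + 1):
        eln_r = digamma(alpha) - digamma(alpha.sum())
        logu = lme_c + eln_r[None, :]
        z = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0_vec + z.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    else:
        it = max_iter
    if not converged:
        import warnings
        warnings.warn("rfx_bms did not converge; returning last iterate",
                      RuntimeWarning)
    f1 = _free_energy(lme_c, alpha, z, alpha0_vec)
    f0 = _null_free_energy(lme_c)
    return BMSResult(
        alpha=alpha, expected_frequencies=alpha / alpha.sum(),
        responsibilities=z, free_energy=f1, null_free_energy=f0,
        converged=converged, n_iter=it,
    )


def exceedance_probability(alpha: Sequence[float], mc_samples: int = 1_000_000,
                           seed: int = 0) -> np.ndarray:
    """Monte-Carlo P(r_k is the largest frequency) under Dirichlet(alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be positive and finite")
    if mc_samples < 1:
        raise ValueError("mc_samples must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(alpha)
    counts = np.zeros(k, dtype=np.int64)
    chunk = 200_000
    remaining = int(mc_samples)
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    return counts / mc_samples


def exceedance_probability_2model(alpha: Sequence[float]) -> np.ndarray:
    """Closed-form EP for two models: P(Beta(a, b) > 1/2) via the
    regularised incomplete beta function."""
    a, b = np.asarray(alpha, dtype=float)
    if a <= 0 or b <= 0:
        raise ValueError("alpha must be positive")
    ep1 = 1.0 - betainc(a, b, 0.5)
    return np.array([ep1, 1.0 - ep1])


def protected_ep(bms_result: BMSResult, mc_samples: int = 1_000_000,
                 seed: int = 0) -> BMSResult:
    """Fill in EP, BOR and protected EP on an :func:`rfx_bms` result.

    BOR = 1 / (1 + exp(F1 - F0)) compares the free energy of the
    random-effects model (F1) against the equal-frequency null (F0).
    """
    if bms_result.free_energy is None or bms_result.null_free_energy is None:
        raise ValueError("run rfx_bms first")
    k = len(bms_result.alpha)
    ep = exceedance_probability(bms_result.alpha, mc_samples=mc_samples,
                                seed=seed)
    bor = float(1.0 / (1.0 + np.exp(bms_result.free_energy
                                    - bms_result.null_free_energy)))
    pep = ep * (1.0 - bor) + bor / k
    bms_result.exceedance_probabilities = ep
    bms_result.bor = bor
    bms_result.protected_ep = pep
    bms_result.mc_samples = int(mc_samples)
    bms_result.seed = seed
    return bms_result


def bms(evidence_matrix: np.ndarray, alpha0: float = 1.0,
        mc_samples: int = 1_000_000, seed: int = 0,
        model_names: Optional[Sequence[str]] = None,
        tol: float = 1e-8, max_iter: int = 1000) -> BMSResult:
    """One-call random-effects BMS: Dirichlet posterior, EP, BOR, pEP."""
    res = rfx_bms(evidence_matrix, alpha0=alpha0, tol=tol, max_iter=max_iter)
    res = protected_ep(res, mc_samples=mc_samples, seed=seed)
    if model_names is not None:
        res.model_names = tuple(model_names)
    return res
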