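"""Subject-level estimation of the social-distance punishment models.

Each subject's unfair-target choices are fit by maximum a posteriori
estimation on an unconstrained parameterisation (log k, log beta,
logit gamma for bounded gamma), with weak independent normal priors
and multi-start quasi-Newton optimisation.  An approximate log model
evidence is attached to every fit: by default the Laplace
approximation around the posterior mode,

    log p(y | m) ~= log p(y | theta*) + log p(theta*)
                    + (d/2) log 2*pi - 1/2 log |H|,

with H the Hessian of the negative log posterior at the mode, or the
BIC surrogate ``LL - (d/2) log n`` on request.  The evidence matrix
over subjects x models feeds random-effects Bayesian model selection
(:mod:`tppunish.model_selection`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .core_models import ModelParams, ModelSpec, get_model, log_choice_probabilities
from .synthetic_data import ChoiceDataset, _utility_matrix_for

__all__ = [
    "FitConfig",
    "SubjectFit",
    "PopulationFit",
    "negative_log_likelihood",
    "fit_subject",
    "fit_population",
    "evidence_matrix",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
# finite objective value returned where utilities overflow; keeps the
# bounded quasi-Newton search away from the degenerate region
_PENALTY = 1e10
# search box on the unconstrained scale (k, beta in [e-12, e12] etc.)
_THETA_BOUND = 12.0


@dataclass(frozen=True)
class FitConfig:
    """Settings for subject-level estimation.

    ``prior_scale`` is the s.d. of the independent N(0, s^2) priors on
    the transformed parameters; 3.0 is weak enough to leave the
    plausible natural ranges (k in [0.01, 1], beta in [0.05, 5],
    gamma away from the corners) essentially unpenalised.
    """

    n_restarts: int = 10
    seed: int = 0
    evidence: str = "laplace"  # or "bic"
    prior_scale: float = 3.0
    start_scale: float = 1.5
    xtol: float = 1e-8
    max_iter: int = 500

    def __post_init__(self):
        if self.evidence not in ("laplace", "bic"):
            raise ValueError("evidence must be 'laplace' or 'bic'")


@dataclass
class SubjectFit:
    """Result of fitting one model to one subject."""

    subject_id: str
    model: str
    params: ModelParams
    log_likelihood: float
    n_trials: int
    evidence: float
    evidence_method: str
    converged: bool
    n_restarts: int
    hessian_logdet: float = float("nan")
    boundary_flags: tuple = ()
    true_params: Optional[ModelParams] = None

    def row(self) -> dict:
        d = {
            "subject": self.subject_id, "model": self.model,
            "log_likelihood": self.log_likelihood, "n_trials": self.n_trials,
            "evidence": self.evidence, "evidence_method": self.evidence_method,
            "converged": self.converged,
        }
        d.update(self.params.as_dict())
        return d


def _fittable_arrays(dataset: ChoiceDataset):
    mask = dataset.fittable_mask()
    if not mask.any():
        raise ValueError(f"subject {dataset.subject_id}: no fittable trials")
    trials = dataset.trials.loc[mask]
    choices = dataset.choices[mask]
    return trials, choices


def negative_log_likelihood(dataset: ChoiceDataset, model: ModelSpec,
                            params: ModelParams) -> float:
    """Negative log likelihood of the observed choices under the model.

    Sums ``-log P(choice)`` over unfair target trials with a response;
    fillers and missing responses are excluded.
    """
    trials, choices = _fittable_arrays(dataset)
    u = _utility_matrix_for(trials, dataset.options, dataset.multiplier,
                            params, model)
    if not np.all(np.isfinite(u)):
        bad = int(np.flatnonzero(~np.isfinite(u).all(axis=1))[0])
        raise FloatingPointError(f"non-finite utility at fitted trial {bad}")
    logp = log_choice_probabilities(u, params.beta)
    return float(-logp[np.arange(len(choices)), choices].sum())


def _objective_factory(dataset, model, config):
    """Negative log posterior on the unconstrained parameter space."""
    trials, choices = _fittable_arrays(dataset)
    costly = trials["condition"].to_numpy() == "costly"
    sd = trials["sd"].to_numpy(float)
    x1 = trials["x1"].to_numpy(float)
    x2 = trials["x2"].to_numpy(float)
    x3 = trials["x3"].to_numpy(float)
    idx = np.arange(len(choices))
    inv_var = 1.0 / config.prior_scale ** 2
    from .core_models import option_utility_matrix

    def nll(theta):
        params = model.from_unconstrained(theta)
        with np.errstate(over="ignore", invalid="ignore"):
            u = option_utility_matrix(costly, sd, x1, x2, x3, dataset.options,
                                      dataset.multiplier, params, model)
            if not np.all(np.isfinite(u)):
                return _PENALTY
            logp = log_choice_probabilities(u, params.beta)
        total = -logp[idx, choices].sum()
        return float(total) if np.isfinite(total) else _PENALTY

    def neg_log_post(theta):
        return nll(theta) + 0.5 * inv_var * float(np.dot(theta, theta)) \
            + 0.5 * len(theta) * (_LOG_2PI + 2.0 * np.log(config.prior_scale))

    return nll, neg_log_post, len(choices)


def _numeric_hessian(f, x, eps=1e-4):
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = eps
            ej = np.zeros(d); ej[j] = eps
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / eps ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * eps ** 2)
    return H


def fit_subject(dataset: ChoiceDataset, model: ModelSpec,
                config: FitConfig = FitConfig(),
                true_params: Optional[ModelParams] = None) -> SubjectFit:
    """Fit one model to one subject by multi-start MAP estimation.

    Starts are drawn around the prior mean in the unconstrained space;
    the best optimum over restarts is kept.  The returned evidence is
    the Laplace approximation (default) or BIC, per ``config``.
    """
    nll, neg_log_post, n_trials = _objective_factory(dataset, model, config)
    rng = np.random.default_rng(config.seed)
    d = model.n_params
    starts = [np.zeros(d)]
    starts += [rng.normal(0.0, config.start_scale, size=d)
               for _ in range(max(config.n_restarts - 1, 0))]

    best = None
    any_converged = False
    for x0 in starts:
        try:
            res = optimize.minimize(
                neg_log_post, x0, method="L-BFGS-B",
                bounds=[(-_THETA_BOUND, _THETA_BOUND)] * d,
                options={"maxiter": config.max_iter, "ftol": config.xtol},
            )
        except FloatingPointError:
            continue
        if not np.isfinite(res.fun):
            continue
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} restarts failed for subject "
            f"{dataset.subject_id}, model {model.name}"
        )

    theta = best.x
    params = model.from_unconstrained(theta)
    ll = -nll(theta)

    flags = []
    if model.target == "punishment":
        if params.gamma_sd < 1e-2 or params.gamma_sd > 1 - 1e-2:
            flags.append("gamma_boundary")
    if params.k < 1e-4 or params.k > 1e4:
        flags.append("k_extreme")

    hess_logdet = float("nan")
    if config.evidence == "bic":
        evidence = ll - 0.5 * d * np.log(n_trials)
    else:
        H = _numeric_hessian(neg_log_post, theta)
        # prior curvature guarantees a floor; clip stray non-positive
        # eigenvalues from finite differencing
        eigs = np.linalg.eigvalsh(0.5 * (H + H.T))
        eigs = np.clip(eigs, 1e-8, None)
        hess_logdet = float(np.sum(np.log(eigs)))
        log_prior = (-0.5 * np.dot(theta, theta) / config.prior_scale ** 2
                     - 0.5 * d * (_LOG_2PI + 2.0 * np.log(config.prior_scale)))
        evidence = ll + log_prior + 0.5 * d * _LOG_2PI - 0.5 * hess_logdet

    return SubjectFit(
        subject_id=dataset.subject_id, model=model.name, params=params,
        log_likelihood=ll, n_trials=n_trials, evidence=float(evidence),
        evidence_method=config.evidence, converged=any_converged,
        n_restarts=len(starts), hessian_logdet=hess_logdet,
        boundary_flags=tuple(flags), true_params=true_params,
    )


@dataclass
class PopulationFit:
    """Subject x model fit table with helpers for model selection."""

    fits: List[SubjectFit]
    model_names: tuple
    failures: List[dict] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([f.row() for f in self.fits])

    def evidence_matrix(self) -> np.ndarray:
        """Subjects x models log-evidence array (model order as fitted)."""
        df = self.table().pivot(index="subject", columns="model",
                                values="evidence")
        return df[list(self.model_names)].to_numpy(float)

    def subjects(self) -> list:
        return sorted({f.subject_id for f in self.fits})

    def fits_for(self, model_name: str) -> List[SubjectFit]:
        return [f for f in self.fits if f.model == model_name]


def fit_population(datasets: Sequence[ChoiceDataset],
                   models: Optional[Sequence[ModelSpec]] = None,
                   config: FitConfig = FitConfig()) -> PopulationFit:
    """Fit every model to every subject.

    Per-subject failures are recorded and the subject is dropped from
    the evidence matrix only if every model fails for them.
    """
    if models is None:
        from .core_models import MODEL_NAMES
        models = [get_model(n) for n in MODEL_NAMES]
    fits: List[SubjectFit] = []
    failures: List[dict] = []
    for i, ds in enumerate(datasets):
        sub_cfg = FitConfig(
            n_restarts=config.n_restarts,
            seed=int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31)),
            evidence=config.evidence, prior_scale=config.prior_scale,
            start_scale=config.start_scale, xtol=config.xtol,
            max_iter=config.max_iter,
        )
        sub_fits = []
        for m in models:
            try:
                sub_fits.append(fit_subject(ds, m, sub_cfg,
                                            true_params=ds.generator_params))
            except (RuntimeError, FloatingPointError, ValueError) as exc:
                failures.append({"subject": ds.subject_id, "model": m.name,
                                 "error": str(exc)})
        if len(sub_fits) == len(models):
            fits.extend(sub_fits)
        elif sub_fits:
            # only complete rows enter the evidence matrix
            failures.append({"subject": ds.subject_id, "model": "*",
                             "error": "incomplete model set; subject excluded"})
    return PopulationFit(fits=fits, model_names=tuple(m.name for m in models),
                         failures=failures)


def evidence_matrix(pop: PopulationFit) -> np.ndarray:
    """Convenience alias for :meth:`PopulationFit.evidence_matrix`."""
    return pop.evidence_matrix()
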