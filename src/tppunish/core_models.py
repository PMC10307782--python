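"""Utility models for third-party punishment under social distance.

The observer (third party) watches a dictator split 100 CNY with a
recipient and may spend punishment money ``p`` from their own endowment
``x3`` to reduce the dictator's payoff by ``multiplier * p``.  The
third-party inequity-aversion (TPIA) utility trades the observer's own
payoff against the post-punishment |dictator - recipient| gap, weighted
by the inequity-aversion parameter ``gamma``:

    U = max(x3 - p, 0) - gamma * |max(x1 - m*p, 0) - x2|

Social distance (SD, rank 1 = closest friend, 100 = stranger) enters
through one of four transforms applied before the utility is evaluated:

* ``hyperbolic_punishment`` -- p is inflated by (1 + 1/(k*SD))
* ``hyperbolic_inequity``   -- gamma = sigmoid((1 + 1/(k*SD)) * gamma_sd)
* ``power_punishment``      -- p is inflated additively by k * SD**w
* ``power_inequity``        -- gamma = sigmoid(gamma_sd + k * SD**w)

Choices among the 7 punishment options are modelled with a softmax rule
with inverse temperature ``beta``; the deterministic "pick the best
option" account is the beta -> infinity limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, log_softmax, softmax

__all__ = [
    "STUDY_SD_LEVELS",
    "STUDY_OPTIONS",
    "TrialDesign",
    "ModelParams",
    "ModelSpec",
    "MODEL_NAMES",
    "get_model",
    "tpia_utility",
    "hyperbolic_punishment",
    "hyperbolic_inequity",
    "power_punishment",
    "power_inequity",
    "option_utilities",
    "option_utility_matrix",
    "choice_probabilities",
    "log_choice_probabilities",
]

STUDY_SD_LEVELS = (1, 2, 3, 5, 10, 20, 50, 100)
STUDY_OPTIONS = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass(frozen=True)
class TrialDesign:
    """One trial of the third-party dictator game.

    Parameters
    ----------
    condition
        ``"costly"`` (punishment deducted from the observer's endowment)
        or ``"free"`` (control; punishment costs the observer nothing).
    sd
        Social distance between observer and dictator (rank >= 1).
    x1, x2
        Dictator and recipient pre-punishment payoffs (CNY).
    x3
        Observer endowment, 50 CNY in the study design.
    options
        Ordered punishment amounts on offer; must start at 0 and be
        strictly increasing.
    multiplier
        Factor by which the dictator's payoff is reduced per unit spent.
    """

    condition: str
    sd: int
    x1: float
    x2: float
    x3: float = 50.0
    options: tuple = STUDY_OPTIONS
    multiplier: float = 3.0

    def __post_init__(self):
        if self.condition not in ("costly", "free"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.sd < 1:
            raise ValueError(f"social distance must be >= 1, got {self.sd}")
        opts = np.asarray(self.options, dtype=float)
        if opts.size < 2 or opts[0] != 0 or np.any(np.diff(opts) <= 0):
            raise ValueError(
                "options must be strictly increasing and start at 0"
            )
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")

    @property
    def costly(self) -> bool:
        return self.condition == "costly"


@dataclass(frozen=True)
class ModelParams:
    """Parameters of a social-distance punishment model.

    ``gamma_sd`` is the pre-transform inequity-aversion parameter: for
    punishment-transform models it is gamma itself (bounded [0, 1]);
    for inequity-transform models it is unbounded and mapped to (0, 1)
    through the sigmoid.  ``k`` is the discount rate / curvature,
    ``w`` the power exponent (power models only), ``beta`` the inverse
    temperature of the softmax choice rule.
    """

    gamma_sd: float
    k: float
    beta: float
    w: Optional[float] = None

    def as_dict(self) -> dict:
        d = {"gamma_sd": self.gamma_sd, "k": self.k, "beta": self.beta}
        if self.w is not None:
            d["w"] = self.w
        return d


# parameter -> transform used to map onto the unconstrained fitting space
_TRANSFORMS = {"log": (np.log, np.exp), "logit": (None, None), "identity": (None, None)}


def _logit(x):
    x = np.clip(x, 1e-12, 1 - 1e-12)
    return np.log(x / (1 - x))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one of the four candidate models."""

    name: str
    target: str  # "punishment" or "inequity" -- what the SD transform acts on
    form: str  # "hyperbolic" or "power"
    param_names: tuple
    transforms: dict = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def validate(self, params: ModelParams) -> None:
        if params.k <= 0:
            raise ValueError("k must be positive")
        if params.beta <= 0:
            raise ValueError("beta must be positive")
        if self.target == "punishment" and not (0.0 <= params.gamma_sd <= 1.0):
            raise ValueError(
                "gamma must lie in [0, 1] for punishment-transform models"
            )
        if self.form == "power" and params.w is None:
            raise ValueError(f"model {self.name} requires a power exponent w")

    # --- unconstrained <-> natural space -------------------------------
    def to_unconstrained(self, params: ModelParams) -> np.ndarray:
        vals = params.as_dict()
        out = []
        for name in self.param_names:
            t = self.transforms[name]
            v = vals[name]
            if t == "log":
                out.append(np.log(v))
            elif t == "logit":
                out.append(_logit(v))
            else:
                out.append(v)
        return np.asarray(out, dtype=float)

    def from_unconstrained(self, vec: Sequence[float]) -> ModelParams:
        kw = {}
        for name, v in zip(self.param_names, vec):
            t = self.transforms[name]
            if t == "log":
                kw[name] = float(np.exp(v))
            elif t == "logit":
                kw[name] = float(expit(v))
            else:
                kw[name] = float(v)
        return ModelParams(**kw)


def _make_spec(name, target, form):
    names = ["gamma_sd", "k", "beta"] + (["w"] if form == "power" else [])
    transforms = {
        "gamma_sd": "logit" if target == "punishment" else "identity",
        "k": "log",
        "beta": "log",
        "w": "identity",
    }
    return ModelSpec(name, target, form, tuple(names), transforms)


_SPECS = {
    "hyperbolic_punishment": _make_spec("hyperbolic_punishment", "punishment", "hyperbolic"),
    "hyperbolic_inequity": _make_spec("hyperbolic_inequity", "inequity", "hyperbolic"),
    "power_punishment": _make_spec("power_punishment", "punishment", "power"),
    "power_inequity": _make_spec("power_inequity", "inequity", "power"),
}

MODEL_NAMES = tuple(_SPECS)


def get_model(name: str) -> ModelSpec:
    """Return the :class:`ModelSpec` for a model name."""
    try:
        return _SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; choose from {MODEL_NAMES}"
        ) from None


# ---------------------------------------------------------------------------
# elementary equations
# ---------------------------------------------------------------------------

def tpia_utility(x1, x2, x3, p, gamma, multiplier=3.0, costly=True):
    """Third-party inequity-aversion utility of punishing ``p``.

    ``U = own_payoff - gamma * |max(x1 - multiplier*p, 0) - x2|`` where
    the own payoff is ``max(x3 - p, 0)`` in the costly condition and the
    untouched endowment ``x3`` in the free (control) condition.
    Broadcasts over array inputs.
    """
    p = np.asarray(p, dtype=float)
    g = np.asarray(gamma, dtype=float)
    if np.any(p < 0):
        raise ValueError("punishment p must be non-negative")
    if np.any((g < 0) | (g > 1)):
        raise ValueError("gamma must lie in [0, 1]")
    dictator = np.maximum(np.asarray(x1, float) - multiplier * p, 0.0)
    inequity = np.abs(dictator - np.asarray(x2, float))
    if np.ndim(costly) == 0:
        own = np.maximum(np.asarray(x3, float) - p, 0.0) if costly else np.asarray(x3, float)
    else:
        own = np.where(
            np.asarray(costly, bool),
            np.maximum(np.asarray(x3, float) - p, 0.0),
            np.asarray(x3, float),
        )
    out = own - g * inequity
    return float(out) if out.ndim == 0 else out


def _check_sd_k(sd, k=None):
    if np.any(np.asarray(sd) < 1):
        raise ValueError("social distance must be >= 1")
    if k is not None and np.any(np.asarray(k) <= 0):
        raise ValueError("discount rate k must be positive")


def hyperbolic_punishment(p_sd, sd, k):
    """Subjective punishment ``(1 + 1/(k*SD)) * p_sd``.

    Strictly decreasing in SD for fixed ``p_sd > 0``, approaching the
    nominal amount as SD grows: close others' transgressions feel as if
    punished harder, so less actual punishment is spent on them.
    """
    _check_sd_k(sd, k)
    out = (1.0 + 1.0 / (np.asarray(k, float) * np.asarray(sd, float))) * np.asarray(p_sd, float)
    return float(out) if np.ndim(out) == 0 else out


def hyperbolic_inequity(gamma_sd, sd, k):
    """Inequity aversion ``sigmoid((1 + 1/(k*SD)) * gamma_sd)`` in (0, 1)."""
    _check_sd_k(sd, k)
    z = (1.0 + 1.0 / (np.asarray(k, float) * np.asarray(sd, float))) * np.asarray(gamma_sd, float)
    out = expit(z)
    return float(out) if np.ndim(out) == 0 else out


def power_punishment(p_sd, sd, k, w):
    """Subjective punishment ``p_sd + k * SD**w`` (additive inflation)."""
    _check_sd_k(sd)
    out = np.asarray(p_sd, float) + np.asarray(k, float) * np.asarray(sd, float) ** np.asarray(w, float)
    return float(out) if np.ndim(out) == 0 else out


def power_inequity(gamma_sd, sd, k, w):
    """Inequity aversion ``sigmoid(gamma_sd + k * SD**w)`` in (0, 1)."""
    _check_sd_k(sd)
    z = np.asarray(gamma_sd, float) + np.asarray(k, float) * np.asarray(sd, float) ** np.asarray(w, float)
    out = expit(z)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# option-wise evaluation
# ---------------------------------------------------------------------------

def option_utility_matrix(costly, sd, x1, x2, x3, options, multiplier,
                          params: ModelParams, model: ModelSpec) -> np.ndarray:
    """Vectorised utilities, shape ``(n_trials, n_options)``.

    ``costly``, ``sd``, ``x1``, ``x2``, ``x3`` are per-trial arrays;
    ``options`` is the shared option set.  For punishment-transform
    models the social-distance transform scales the punishment's
    *impact* on the dictator (the reduction term of the utility); the
    observer's own cost is always the nominal amount spent.  Applying
    the transform to the cost term as well would make close-distance
    punishment saturate both payoff clamps and invert the observed
    rise of punishment with social distance.
    """
    model.validate(params)
    costly = np.atleast_1d(np.asarray(costly, bool))
    sd = np.atleast_1d(np.asarray(sd, float))
    x1 = np.atleast_1d(np.asarray(x1, float))
    x2 = np.atleast_1d(np.asarray(x2, float))
    x3 = np.atleast_1d(np.asarray(x3, float))
    opts = np.asarray(options, dtype=float)[None, :]  # (1, n_options)
    sd_col = sd[:, None]

    if model.target == "punishment":
        gamma = params.gamma_sd
        if model.form == "hyperbolic":
            p_impact = hyperbolic_punishment(opts, sd_col, params.k)
        else:
            p_impact = power_punishment(opts, sd_col, params.k, params.w)
    else:
        p_impact = np.broadcast_to(opts, (sd.size, opts.size))
        if model.form == "hyperbolic":
            gamma = hyperbolic_inequity(params.gamma_sd, sd_col, params.k)
        else:
            gamma = power_inequity(params.gamma_sd, sd_col, params.k, params.w)

    dictator = np.maximum(x1[:, None] - multiplier * p_impact, 0.0)
    inequity = np.abs(dictator - x2[:, None])
    own = np.where(costly[:, None], np.maximum(x3[:, None] - opts, 0.0), x3[:, None])
    return own - gamma * inequity


def option_utilities(trial: TrialDesign, params: ModelParams,
                     model: ModelSpec) -> np.ndarray:
    """Utility of every punishment option on one trial (length 7 by default)."""
    u = option_utility_matrix(
        trial.costly, trial.sd, trial.x1, trial.x2, trial.x3,
        trial.options, trial.multiplier, params, model,
    )
    return u[0]


def choice_probabilities(utilities, beta) -> np.ndarray:
    """Softmax choice rule ``P(i) ∝ exp(beta * U_i)``.

    Positive, sums to 1, invariant to adding a constant to all utilities.
    """
    u = np.asarray(utilities, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("utilities must be finite")
    if beta <= 0:
        raise ValueError("beta must be positive")
    return softmax(beta * u, axis=-1)


def log_choice_probabilities(utilities, beta) -> np.ndarray:
    """Log of :func:`choice_probabilities`, computed stably."""
    u = np.asarray(utilities, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("utilities must be finite")
    if beta <= 0:
        raise ValueError("beta must be positive")
    return log_softmax(beta * u, axis=-1)
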