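"""Study-faithful trial designs and simulated choice data.

The generator replicates the modified third-party dictator game used in
the scanner: 6 sessions of 54 trials.  Each session holds 12 blocks (6
costly, 6 free); the 48 unfair target trials per session cover all 24
combinations of 8 social distances {1, 2, 3, 5, 10, 20, 50, 100} and 3
unfair allocations {90/10, 85/15, 80/20} once per payment condition,
4 targets per block.  Six quasi-fair filler trials (65/35, 60/40,
55/45, each twice) are sprinkled over the blocks; they kept unfairness
from becoming the norm in the study and are excluded from fitting.

Choices are simulated from any of the four candidate models by
sampling the softmax choice rule, so the whole pipeline runs with no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core_models import (
    STUDY_OPTIONS,
    STUDY_SD_LEVELS,
    ModelParams,
    ModelSpec,
    choice_probabilities,
    option_utility_matrix,
)

__all__ = [
    "StudyDesign",
    "ChoiceDataset",
    "DATASET_COLUMNS",
    "build_design",
    "simulate_choices",
    "sample_population",
    "default_param_distributions",
]

DATASET_COLUMNS = [
    "subject", "session", "block", "condition", "sd",
    "x1", "x2", "x3", "option_chosen", "punishment_amount", "is_filler",
]


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of the scanning-phase task design (defaults = study)."""

    n_sessions: int = 6
    trials_per_session: int = 54
    blocks_per_session: int = 12
    sd_levels: tuple = STUDY_SD_LEVELS
    allocations: tuple = ((90.0, 10.0), (85.0, 15.0), (80.0, 20.0))
    filler_allocations: tuple = ((65.0, 35.0), (60.0, 40.0), (55.0, 45.0))
    conditions: tuple = ("costly", "free")
    endowment: float = 50.0
    options: tuple = STUDY_OPTIONS
    multiplier: float = 3.0
    # If True, half the fillers go to each condition's blocks; if False
    # (default) fillers land on any of the session's blocks at random.
    symmetric_fillers: bool = False

    @property
    def n_combinations(self) -> int:
        return len(self.sd_levels) * len(self.allocations)

    @property
    def targets_per_session(self) -> int:
        return self.n_combinations * len(self.conditions)

    @property
    def fillers_per_session(self) -> int:
        return self.trials_per_session - self.targets_per_session

    def validate(self) -> None:
        if len(self.conditions) != 2:
            raise ValueError("design requires the two payment conditions")
        blocks_per_cond = self.blocks_per_session // len(self.conditions)
        if self.blocks_per_session % len(self.conditions):
            raise ValueError("blocks_per_session must split evenly by condition")
        if self.n_combinations % blocks_per_cond:
            raise ValueError(
                f"{self.n_combinations} sd x allocation combinations do not "
                f"divide into {blocks_per_cond} blocks per condition"
            )
        if self.fillers_per_session < 0:
            raise ValueError("trials_per_session too small for the target set")
        if self.fillers_per_session % len(self.filler_allocations):
            raise ValueError(
                "fillers per session must be a multiple of the filler allocations"
            )


@dataclass
class ChoiceDataset:
    """Per-subject trial sequence plus chosen option indices.

    ``trials`` is a DataFrame with columns session, block, condition,
    sd, x1, x2, x3, is_filler (one row per trial, in presentation
    order).  ``choices`` holds the chosen option index per trial, with
    -1 marking a missing response.  Generator metadata (model name,
    true parameters, seed) makes simulated data reproducible.
    """

    subject_id: str
    trials: pd.DataFrame
    choices: np.ndarray
    options: tuple = STUDY_OPTIONS
    multiplier: float = 3.0
    generator_model: Optional[str] = None
    generator_params: Optional[ModelParams] = None
    seed: Optional[int] = None

    def __post_init__(self):
        self.choices = np.asarray(self.choices, dtype=int)
        if len(self.choices) != len(self.trials):
            raise ValueError("one choice per trial required")
        valid = (self.choices >= -1) & (self.choices < len(self.options))
        if not valid.all():
            bad = int(np.flatnonzero(~valid)[0])
            raise ValueError(f"choice index out of range at trial {bad}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def fittable_mask(self) -> np.ndarray:
        """Unfair target trials with a recorded response."""
        return (~self.trials["is_filler"].to_numpy(bool)) & (self.choices >= 0)

    def to_frame(self) -> pd.DataFrame:
        """Flat per-trial table in the interchange column layout."""
        df = self.trials.copy()
        df.insert(0, "subject", self.subject_id)
        df["option_chosen"] = self.choices
        opts = np.asarray(self.options, float)
        amounts = np.where(self.choices >= 0, opts[np.clip(self.choices, 0, None)], np.nan)
        df["punishment_amount"] = amounts
        return df[DATASET_COLUMNS]


def _session_trials(design: StudyDesign, session: int, rng: np.random.Generator
                    ) -> List[dict]:
    """Build one session: condition-balanced blocks of targets + fillers."""
    n_cond = len(design.conditions)
    blocks_per_cond = design.blocks_per_session // n_cond
    targets_per_block = design.n_combinations // blocks_per_cond

    # block order: 6 costly + 6 free labels, shuffled
    block_conditions = np.repeat(np.arange(n_cond), blocks_per_cond)
    rng.shuffle(block_conditions)

    combos = [(sd, a) for sd in design.sd_levels for a in design.allocations]

    # per condition: shuffle the 24 combos and deal them into blocks of 4
    per_cond_chunks: Dict[int, List[List[tuple]]] = {}
    for ci in range(n_cond):
        order = rng.permutation(len(combos))
        chunks = [
            [combos[j] for j in order[i * targets_per_block:(i + 1) * targets_per_block]]
            for i in range(blocks_per_cond)
        ]
        per_cond_chunks[ci] = chunks

    # fillers: each quasi-fair allocation appears the same number of times
    reps = design.fillers_per_session // len(design.filler_allocations)
    filler_allocs = [a for a in design.filler_allocations for _ in range(reps)]
    rng.shuffle(filler_allocs)
    filler_sds = rng.choice(design.sd_levels, size=len(filler_allocs), replace=True)
    if design.symmetric_fillers:
        # split fillers evenly over the two conditions' blocks
        half = len(filler_allocs) // 2
        cond_blocks = {
            ci: [b for b in range(design.blocks_per_session) if block_conditions[b] == ci]
            for ci in range(n_cond)
        }
        filler_blocks = np.concatenate([
            rng.choice(cond_blocks[0], size=half, replace=True),
            rng.choice(cond_blocks[1], size=len(filler_allocs) - half, replace=True),
        ])
    else:
        filler_blocks = rng.choice(design.blocks_per_session,
                                   size=len(filler_allocs), replace=True)

    rows: List[dict] = []
    cond_cursor = [0] * n_cond
    for b, ci in enumerate(block_conditions):
        cond = design.conditions[ci]
        block_rows = []
        for sd, (x1, x2) in per_cond_chunks[ci][cond_cursor[ci]]:
            block_rows.append(dict(session=session, block=b + 1, condition=cond,
                                   sd=int(sd), x1=x1, x2=x2, x3=design.endowment,
                                   is_filler=False))
        cond_cursor[ci] += 1
        for fi in np.flatnonzero(filler_blocks == b):
            x1, x2 = filler_allocs[fi]
            block_rows.append(dict(session=session, block=b + 1, condition=cond,
                                   sd=int(filler_sds[fi]), x1=x1, x2=x2,
                                   x3=design.endowment, is_filler=True))
        order = rng.permutation(len(block_rows))
        rows.extend(block_rows[i] for i in order)
    return rows


def build_design(design: StudyDesign = StudyDesign(), seed: int = 0) -> pd.DataFrame:
    """Pseudo-randomised (seeded) trial list honouring the block structure.

    Returns a DataFrame with one row per trial in presentation order,
    columns session, block, condition, sd, x1, x2, x3, is_filler.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    rows: List[dict] = []
    for s in range(1, design.n_sessions + 1):
        rows.extend(_session_trials(design, s, rng))
    df = pd.DataFrame(rows)
    df.index.name = "trial"
    return df


def _utility_matrix_for(trials: pd.DataFrame, options, multiplier,
                        params: ModelParams, model: ModelSpec) -> np.ndarray:
    return option_utility_matrix(
        trials["condition"].to_numpy() == "costly",
        trials["sd"].to_numpy(float),
        trials["x1"].to_numpy(float),
        trials["x2"].to_numpy(float),
        trials["x3"].to_numpy(float),
        options, multiplier, params, model,
    )


def simulate_choices(design_trials: pd.DataFrame, model: ModelSpec,
                     params: ModelParams, seed: int = 0,
                     subject_id: str = "sim",
                     options=STUDY_OPTIONS, multiplier: float = 3.0,
                     miss_rate: float = 0.0) -> ChoiceDataset:
    """Sample one subject's choices from a model's softmax choice rule.

    Fillers are simulated under the same model but flagged so fitting
    skips them.  ``miss_rate`` injects missing responses (index -1) at
    the given per-trial probability; the study default is 0.
    """
    model.validate(params)
    if not 0.0 <= miss_rate < 1.0:
        raise ValueError("miss_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    u = _utility_matrix_for(design_trials, options, multiplier, params, model)
    probs = choice_probabilities(u, params.beta)
    cum = np.cumsum(probs, axis=1)
    draws = rng.random(len(design_trials))
    choices = (draws[:, None] > cum).sum(axis=1)
    if miss_rate > 0:
        choices[rng.random(len(choices)) < miss_rate] = -1
    return ChoiceDataset(
        subject_id=subject_id,
        trials=design_trials.reset_index(drop=True),
        choices=choices,
        options=tuple(options),
        multiplier=multiplier,
        generator_model=model.name,
        generator_params=params,
        seed=seed,
    )


DistSpec = Union[Tuple[float, float], Callable[[np.random.Generator], float]]


def default_param_distributions(model: ModelSpec) -> Dict[str, DistSpec]:
    """Population distributions used for recovery studies.

    Uniform ranges chosen to span clearly punishing, clearly
    discounting subjects without boundary pile-up: gamma in (0.2, 0.8)
    (or an unbounded gamma_sd in (-1, 1) for inequity-transform
    models), discount rate k in (0.02, 0.5), inverse temperature beta
    in (0.2, 1.0) and, for power models, exponent w in (0.3, 1.0).
    """
    dists: Dict[str, DistSpec] = {
        "gamma_sd": (0.2, 0.8) if model.target == "punishment" else (-1.0, 1.0),
        "k": (0.02, 0.5),
        "beta": (0.2, 1.0),
    }
    if model.form == "power":
        dists["w"] = (0.3, 1.0)
    return dists


def _draw_params(model: ModelSpec, dists: Dict[str, DistSpec],
                 rng: np.random.Generator, max_retries: int = 100) -> ModelParams:
    for _ in range(max_retries):
        kw = {}
        for name in model.param_names:
            spec = dists[name]
            if callable(spec):
                kw[name] = float(spec(rng))
            else:
                lo, hi = spec
                kw[name] = float(rng.uniform(lo, hi))
        params = ModelParams(**kw)
        try:
            model.validate(params)
        except ValueError:
            continue
        return params
    raise RuntimeError(
        f"could not draw in-bounds parameters for {model.name} "
        f"after {max_retries} attempts"
    )


def sample_population(n_subjects: int, model: ModelSpec,
                      param_distributions: Optional[Dict[str, DistSpec]] = None,
                      seed: int = 0,
                      design: StudyDesign = StudyDesign(),
                      miss_rate: float = 0.0) -> List[ChoiceDataset]:
    """Simulate a group of subjects with per-subject parameters.

    One integer seed drives everything through independent sub-streams
    (design shuffling, parameter draws, choice sampling), so the
    population is reproducible from ``(model, distributions, design,
    seed)``.  True parameters are kept on each dataset for recovery
    scoring.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    dists = param_distributions or default_param_distributions(model)
    ss = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.generate_state(2 * n_subjects, dtype=np.uint32)
    datasets = []
    for i in range(n_subjects):
        params = _draw_params(model, dists, param_rng)
        trials = build_design(design, seed=int(child_seeds[2 * i]))
        ds = simulate_choices(
            trials, model, params, seed=int(child_seeds[2 * i + 1]),
            subject_id=f"sub-{i + 1:03d}", options=design.options,
            multiplier=design.multiplier, miss_rate=miss_rate,
        )
        datasets.append(ds)
    return datasets
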