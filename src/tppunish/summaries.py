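"""Descriptive summaries of punishment behaviour and model utilities.

``punishment_summary`` tabulates mean chosen punishment per payment
condition x social distance x inequity level (the behavioural
punishment-severity curves); ``utility_surface`` evaluates, for a fitted
model, the utility of the utility-maximising punishment option on a
social-distance x allocation grid (the heatmap view of how attractive
sanctioning is across the design).  Tables are tidy DataFrames ready
for external plotting or mixed-model packages; no smoothing is applied.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_models import (
    STUDY_OPTIONS,
    ModelParams,
    ModelSpec,
    option_utility_matrix,
)
from .synthetic_data import ChoiceDataset

__all__ = ["punishment_summary", "utility_surface"]


def _allocation_label(x1, x2):
    return f"{x1:g}v{x2:g}"


def punishment_summary(datasets: Union[ChoiceDataset, Iterable[ChoiceDataset]],
                       include_fillers: bool = False) -> pd.DataFrame:
    """Mean punishment per (condition, sd, allocation) cell.

    Pools responded trials across the supplied datasets (fillers and
    missing responses excluded by default); returns mean, standard
    error and trial count per cell.  Cells with no trials are absent
    from the table rather than reported as zero.
    """
    if isinstance(datasets, ChoiceDataset):
        datasets = [datasets]
    frames = []
    for ds in datasets:
        df = ds.to_frame()
        keep = df["option_chosen"] >= 0
        if not include_fillers:
            keep &= ~df["is_filler"].astype(bool)
        frames.append(df.loc[keep])
    if not frames:
        raise ValueError("at least one dataset required")
    data = pd.concat(frames, ignore_index=True)
    if data.empty:
        raise ValueError("no fittable trials to summarise")
    data["allocation"] = [
        _allocation_label(a, b) for a, b in zip(data["x1"], data["x2"])
    ]
    g = data.groupby(["condition", "sd", "allocation"], sort=True)
    out = g["punishment_amount"].agg(
        mean_punishment="mean",
        sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
        n="size",
    ).reset_index()
    return out


def utility_surface(model: ModelSpec, params: ModelParams,
                    sd_grid: Sequence[int] = (1, 2, 3, 5, 10, 20, 50, 100),
                    allocations: Sequence[tuple] = ((90.0, 10.0), (85.0, 15.0), (80.0, 20.0)),
                    condition: str = "costly",
                    x3: float = 50.0,
                    options: Sequence[float] = STUDY_OPTIONS,
                    multiplier: float = 3.0) -> pd.DataFrame:
    """Best-option utility on a social-distance x allocation grid.

    Each cell holds ``max_p U(p)`` over the punishment options -- the
    value of the utility-maximising sanction for that trial type.
    Rows are social distances, columns allocation labels.
    """
    if condition not in ("costly", "free"):
        raise ValueError(f"unknown condition {condition!r}")
    sd_grid = list(sd_grid)
    cells = np.empty((len(sd_grid), len(allocations)))
    for j, (x1, x2) in enumerate(allocations):
        u = option_utility_matrix(
            np.full(len(sd_grid), condition == "costly"),
            np.asarray(sd_grid, float),
            np.full(len(sd_grid), float(x1)),
            np.full(len(sd_grid), float(x2)),
            np.full(len(sd_grid), float(x3)),
            options, multiplier, params, model,
        )
        cells[:, j] = u.max(axis=1)
    cols = [_allocation_label(x1, x2) for x1, x2 in allocations]
    out = pd.DataFrame(cells, index=pd.Index(sd_grid, name="sd"), columns=cols)
    return out
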