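"""Classification metrics and multi-seed experiment reports.

Six standard diagnostic metrics are computed from the 2x2 confusion table
(positive class = patient by default):

    ACC = (TP+TN)/(TP+FN+TN+FP)   SEN = TP/(TP+FN)   SPE = TN/(TN+FP)
    BAC = (SEN+SPE)/2             PPV = TP/(TP+FP)   NPV = TN/(TN+FN)

Zero-denominator metrics come back as an explicit ``None`` marker, never a
silent 0; report aggregation excludes them from means and counts them in a
footnote column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricSet", "confusion_counts", "metrics", "run_experiment"]

METRIC_NAMES = ("ACC", "SEN", "SPE", "BAC", "PPV", "NPV")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSet:
    """Proportions in [0, 1]; ``None`` marks an undefined (0/0) metric."""

    ACC: float | None
    SEN: float | None
    SPE: float | None
    BAC: float | None
    PPV: float | None
    NPV: float | None

    def as_dict(self) -> dict[str, float | None]:
        return dataclasses.asdict(self)

    def as_percent(self) -> dict[str, float | None]:
        return {k: (None if v is None else 100.0 * v) for k, v in self.as_dict().items()}


def confusion_counts(
    y_true: Sequence[int], y_pred: Sequence[int], positive_class: int
) -> ConfusionCounts:
    """2x2 confusion counts with respect to ``positive_class``."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos_t = yt == positive_class
    pos_p = yp == positive_class
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(counts: ConfusionCounts) -> MetricSet:
    """All six metrics from a confusion table; 0/0 cases marked undefined."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    sen = _ratio(counts.TP, counts.TP + counts.FN)
    spe = _ratio(counts.TN, counts.TN + counts.FP)
    bac = None if sen is None or spe is None else (sen + spe) / 2.0
    return MetricSet(
        ACC=(counts.TP + counts.TN) / counts.total,
        SEN=sen,
        SPE=spe,
        BAC=bac,
        PPV=_ratio(counts.TP, counts.TP + counts.FP),
        NPV=_ratio(counts.TN, counts.TN + counts.FN),
    )


def run_experiment(
    tasks: Mapping[str, Callable[[int], tuple[np.ndarray, np.ndarray]]],
    n_seeds: int = 5,
    positive_class: int = 2,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Aggregate metrics over seeds for a set of named tasks.

    Each task is a callable ``seed -> (y_true, y_pred)`` (typically a closure
    running one pipeline mode on one generated dataset).  Returns a tidy table
    with per-task mean and sd of each metric in percent, plus a count of
    undefined metric values excluded from the means.  A task that raises is
    recorded as an error row and the run continues.
    """
    rows = []
    for name, fn in tasks.items():
        per_seed: list[dict[str, float | None]] = []
        error: str | None = None
        for s in range(n_seeds):
            try:
                y_true, y_pred = fn(base_seed + s)
            except Exception as exc:  # record and continue with other tasks
                error = f"{type(exc).__name__}: {exc}"
                break
            per_seed.append(metrics(confusion_counts(y_true, y_pred, positive_class)).as_percent())
        row: dict[str, object] = {"task": name, "n_seeds": len(per_seed)}
        if error is not None:
            row["error"] = error
        n_undef = 0
        for m in METRIC_NAMES:
            vals = [d[m] for d in per_seed if d.get(m) is not None]
            n_undef += sum(1 for d in per_seed if d.get(m) is None)
            row[f"{m}_mean"] = round(float(np.mean(vals)), 2) if vals else None
            row[f"{m}_sd"] = round(float(np.std(vals)), 2) if vals else None
        row["n_undefined"] = n_undef
        rows.append(row)
    return pd.DataFrame(rows)
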