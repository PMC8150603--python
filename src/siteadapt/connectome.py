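"""ROI time series -> Pearson functional-connectivity feature vectors.

Each subject's regional BOLD time series (T timepoints x R regions, e.g.
R = 90 for the AAL atlas) is summarised by the R x R matrix of pairwise
Pearson correlations; the strict upper triangle, flattened row-major, is the
subject's feature vector of length R(R-1)/2 (4005 for R = 90).  Raw Pearson
values are used — no Fisher z-transform — and the upper-triangle ordering
(i < j, 0-based, row-major) is frozen because feature indices are part of the
model I/O contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import FeatureTable

__all__ = [
    "ROITimeSeries",
    "pearson_fc",
    "vectorize_upper",
    "scatter_upper",
    "build_feature_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's T x R matrix of mean regional BOLD signals."""

    values: np.ndarray
    subject_id: str = ""
    roi_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("time series must be 2-D (T x R)")
        if v.shape[0] < 2:
            raise ValueError("need at least T=2 timepoints")
        if not np.isfinite(v).all():
            raise ValueError("time series contains non-finite values")
        object.__setattr__(self, "values", v)
        if self.roi_labels is not None and len(self.roi_labels) != v.shape[1]:
            raise ValueError("roi_labels length must equal R")


def pearson_fc(ts: ROITimeSeries | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of ROI columns.

    Constant (zero-variance) columns get correlation 0 against everything
    (diagonal stays 1) rather than NaN, with a logged warning — this keeps
    downstream linear algebra finite.
    """
    if not isinstance(ts, ROITimeSeries):
        ts = ROITimeSeries(values=np.asarray(ts, dtype=float))
    X = ts.values
    sd = X.std(axis=0)
    degenerate = sd == 0.0
    if degenerate.any():
        logger.warning(
            "subject %r: %d constant ROI column(s); correlations set to 0",
            ts.subject_id,
            int(degenerate.sum()),
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            fc = np.corrcoef(X, rowvar=False)
        fc[degenerate, :] = 0.0
        fc[:, degenerate] = 0.0
        np.fill_diagonal(fc, 1.0)
        fc = np.nan_to_num(fc, nan=0.0)
    else:
        fc = np.corrcoef(X, rowvar=False)
    fc = np.clip(fc, -1.0, 1.0)
    return (fc + fc.T) / 2.0


def vectorize_upper(fc: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a symmetric R x R matrix, row-major over
    pairs (i, j) with i < j; length R(R-1)/2."""
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {fc.shape}")
    if fc.shape[0] < 2:
        raise ValueError("need R >= 2 regions")
    iu = np.triu_indices(fc.shape[0], k=1)
    return fc[iu]


def scatter_upper(vec: np.ndarray, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: rebuild the symmetric matrix with a
    constant diagonal."""
    vec = np.asarray(vec, dtype=float)
    m = vec.size
    R = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if R < 2 or R * (R - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not R(R-1)/2 for integer R")
    fc = np.full((R, R), diag, dtype=float)
    iu = np.triu_indices(R, k=1)
    fc[iu] = vec
    fc[(iu[1], iu[0])] = vec
    return fc


def build_feature_table(manifest: str | Path, domain: str = "source") -> tuple[FeatureTable, np.ndarray]:
    """Read a manifest TSV (subject_id, group, path) of per-subject time-series
    files and return the subjects x R(R-1)/2 connectivity feature table plus
    the group labels.

    All subjects must share the same number of regions R.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest, sep="\t")
    if df.empty:
        raise ValueError(f"manifest {manifest} lists no subjects")
    rows = []
    R_seen: int | None = None
    for rec in df.itertuples(index=False):
        p = Path(rec.path)
        if not p.exists():
            raise FileNotFoundError(f"time-series file not found: {p}")
        ts = np.loadtxt(p, delimiter="\t", ndmin=2)
        if R_seen is None:
            R_seen = ts.shape[1]
        elif ts.shape[1] != R_seen:
            raise ValueError(
                f"inconsistent ROI count: {p} has R={ts.shape[1]}, expected {R_seen}"
            )
        fc = pearson_fc(ROITimeSeries(values=ts, subject_id=str(rec.subject_id)))
        rows.append(vectorize_upper(fc))
    X = np.vstack(rows)
    table = FeatureTable(
        subject_ids=tuple(df["subject_id"].astype(str)),
        domain=domain,
        X=X,
        labels=None,
    )
    return table, df["group"].to_numpy(dtype=int)
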