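"""Synthetic two-domain benchmarks with controlled distribution shift.

Multisite neuroimaging studies suffer from scanner/site effects: the source
site (where labels exist) and the target site (unlabelled) do not follow the
same distribution, neither marginally P(X) nor conditionally P(X|Y).  This
module generates the smallest datasets exhibiting both kinds of shift —
class-conditional Gaussians whose target copy is rotated in the plane of the
first two feature axes and translated by a constant vector — plus synthetic
ROI time series with group-dependent block-correlation structure, so the whole
adaptation pipeline is testable without any imaging download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ShiftConfig",
    "TimeSeriesConfig",
    "FeatureTable",
    "gen_domain_shift",
    "gen_roi_timeseries",
    "write_timeseries_dataset",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class FeatureTable:
    """Subjects-by-features matrix with identifiers and domain tags.

    ``labels`` is ``None`` for unlabelled (target-domain) tables; evaluation
    code receives the held-out truth through a separate object, never through
    the table handed to the pipeline.
    """

    subject_ids: tuple[str, ...]
    domain: str
    X: np.ndarray  # (n, d)
    labels: np.ndarray | None = None  # (n,) ints in {1..C} or None

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("subject_ids length must match rows of X")
        if self.labels is not None and len(self.labels) != self.X.shape[0]:
            raise ValueError("labels length must match rows of X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        width = max(4, len(str(self.d)))
        cols = [f"f{i + 1:0{width}d}" for i in range(self.d)]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "subject_id", list(self.subject_ids))
        df.insert(1, "domain", self.domain)
        if self.labels is not None:
            df.insert(2, "label", self.labels.astype(int))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        if not feat_cols:
            raise ValueError(f"no feature columns found in {path}")
        labels = None
        if "label" in df.columns:
            labels = df["label"].to_numpy(dtype=int)
        domains = df["domain"].unique()
        if len(domains) != 1:
            raise ValueError("a FeatureTable holds exactly one domain")
        return cls(
            subject_ids=tuple(df["subject_id"].astype(str)),
            domain=str(domains[0]),
            X=df[feat_cols].to_numpy(dtype=float),
            labels=labels,
        )


@dataclass(frozen=True)
class ShiftConfig:
    """Two-domain, two-class Gaussian benchmark with marginal+conditional shift.

    The source domain draws each class from an isotropic Gaussian with
    standard deviation ``noise_sd``; class means sit ``class_sep`` apart along
    the first feature axis.  The target domain draws from the same
    class-conditionals, then rotates every sample by ``rotation_deg`` in the
    plane of the first two axes and translates it by a vector of length
    ``shift_mag``.  Rotation changes P(X|Y) relative to the source (conditional
    shift); translation changes P(X) (marginal shift).
    """

    n_source: int = 200
    n_target: int = 200
    dims: int = 20
    class_sep: float = 3.0
    rotation_deg: float = 30.0
    shift_mag: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_source < 2 or self.n_target < 2:
            raise ConfigurationError("per-class counts must be >= 2")
        if self.dims < 2:
            raise ConfigurationError("dims must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")


def _rotation_matrix(dims: int, angle_deg: float) -> np.ndarray:
    theta = np.deg2rad(angle_deg)
    R = np.eye(dims)
    c, s = np.cos(theta), np.sin(theta)
    R[0, 0], R[0, 1] = c, -s
    R[1, 0], R[1, 1] = s, c
    return R


def gen_domain_shift(config: ShiftConfig) -> tuple[FeatureTable, FeatureTable, np.ndarray]:
    """Generate a labelled source table, an unlabelled target table, and the
    target's held-out true labels.

    Returns ``(source, target, target_truth)``.  ``target.labels`` is ``None``
    by construction: the truth array exists only for post-hoc evaluation and
    must never be fed to the adaptation pipeline.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    d = cfg.dims
    mu1 = np.zeros(d)
    mu2 = np.zeros(d)
    mu1[0] = -cfg.class_sep / 2.0
    mu2[0] = +cfg.class_sep / 2.0

    def draw(n_per_class: int) -> tuple[np.ndarray, np.ndarray]:
        X1 = rng.normal(mu1, cfg.noise_sd, size=(n_per_class, d))
        X2 = rng.normal(mu2, cfg.noise_sd, size=(n_per_class, d))
        X = np.vstack([X1, X2])
        y = np.concatenate([np.ones(n_per_class, dtype=int), np.full(n_per_class, 2, dtype=int)])
        return X, y

    Xs, ys = draw(cfg.n_source)
    Xt, yt = draw(cfg.n_target)

    R = _rotation_matrix(d, cfg.rotation_deg)
    # site effect modelled as a global additive offset: every feature gains
    # shift_mag, the way batch/scanner effects shift connectivity features
    # broadly rather than along one axis
    shift = np.full(d, cfg.shift_mag)
    Xt = Xt @ R.T + shift

    src = FeatureTable(
        subject_ids=tuple(f"src{i:04d}" for i in range(len(ys))),
        domain="source",
        X=Xs,
        labels=ys,
    )
    tgt = FeatureTable(
        subject_ids=tuple(f"tgt{i:04d}" for i in range(len(yt))),
        domain="target",
        X=Xt,
        labels=None,
    )
    return src, tgt, yt


@dataclass(frozen=True)
class TimeSeriesConfig:
    """Synthetic ROI time-series generator settings.

    Each subject is a T x R matrix drawn from a group-specific covariance with
    latent-network block structure: ROIs inside a block share a within-block
    correlation, and the groups differ in ``between_block_corr`` — a crude but
    sufficient stand-in for group differences in functional connectivity.
    """

    n_subjects_per_group: int = 10
    n_rois: int = 90
    n_timepoints: int = 150
    block_structure: tuple[int, ...] = (30, 30, 30)
    within_block_corr: float = 0.5
    between_block_corr: tuple[float, float] = (0.0, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ConfigurationError("n_subjects_per_group must be >= 1")
        if self.n_timepoints < 10:
            raise ConfigurationError("n_timepoints must be >= 10")
        if sum(self.block_structure) != self.n_rois:
            raise ConfigurationError(
                f"block_structure sums to {sum(self.block_structure)}, expected n_rois={self.n_rois}"
            )
        for r in (self.within_block_corr, *self.between_block_corr):
            if not -1.0 <= r <= 1.0:
                raise ConfigurationError("correlation levels must lie in [-1, 1]")


def _block_covariance(blocks: Sequence[int], within: float, between: float) -> np.ndarray:
    R = sum(blocks)
    cov = np.full((R, R), between, dtype=float)
    start = 0
    for b in blocks:
        cov[start : start + b, start : start + b] = within
        start += b
    np.fill_diagonal(cov, 1.0)
    # guard positive definiteness for extreme settings
    w, V = np.linalg.eigh(cov)
    if w.min() < 1e-8:
        cov = (V * np.maximum(w, 1e-8)) @ V.T
    return cov


def gen_roi_timeseries(
    config: TimeSeriesConfig,
) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Draw per-subject T x R time series for two groups.

    Returns ``(series_list, group_labels, subject_ids)`` with groups labelled
    1 and 2.  Group g uses between-block correlation
    ``config.between_block_corr[g-1]``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    series: list[np.ndarray] = []
    groups: list[int] = []
    ids: list[str] = []
    for g, between in enumerate(cfg.between_block_corr, start=1):
        cov = _block_covariance(cfg.block_structure, cfg.within_block_corr, between)
        L = np.linalg.cholesky(cov)
        for s in range(cfg.n_subjects_per_group):
            Z = rng.standard_normal((cfg.n_timepoints, cfg.n_rois))
            series.append(Z @ L.T)
            groups.append(g)
            ids.append(f"g{g}s{s:03d}")
    return series, np.asarray(groups, dtype=int), ids


def write_timeseries_dataset(
    outdir: str | Path,
    series: Sequence[np.ndarray],
    groups: Sequence[int],
    subject_ids: Sequence[str],
) -> Path:
    """Write one headerless TSV per subject plus a manifest TSV.

    Returns the manifest path.  Manifest columns: subject_id, group, path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, g, sid in zip(series, groups, subject_ids, strict=True):
        p = outdir / f"{sid}.tsv"
        np.savetxt(p, ts, delimiter="\t")
        rows.append({"subject_id": sid, "group": int(g), "path": str(p)})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
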