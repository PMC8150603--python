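"""Joint marginal + conditional MMD minimisation in a learned linear subspace.

Given a labelled source domain Xs (d x ns) and an unlabelled target domain
Xt (d x nt), we learn a linear transform W (d x k) that minimises the maximum
mean discrepancy (MMD) between the projected domains — both the marginal
distance ||mean(W^T Xs) - mean(W^T Xt)||^2 and, once target pseudolabels are
available, the per-class conditional distances — subject to the
variance-preserving constraint W^T X H X^T W = I, where X = [Xs, Xt] and H is
the centering matrix.  The MMD terms reduce to traces tr(W^T X Mc X^T W) over
block-constant coefficient matrices M0 (marginal) and Mc (one per class), so
the Lagrangian stationarity condition is the generalized eigenproblem

    (sum_c X Mc X^T + lambda I) w = phi * (X H X^T) w,

solved for the k eigenvectors with smallest eigenvalue.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

__all__ = [
    "DomainPair",
    "ProjectionModel",
    "mmd_matrix_marginal",
    "mmd_matrix_conditional",
    "mmd_distance",
    "centering_matrix",
    "solve_projection",
    "project",
]

logger = logging.getLogger(__name__)

#: ridge added to X H X^T, which is rank-deficient by construction (the
#: centering matrix annihilates the constant direction)
RIGHT_RIDGE = 1e-9


@dataclass
class DomainPair:
    """Source/target sample matrices in column convention (features x samples).

    ``ys`` holds source labels in {1..C}; ``pseudolabels_t`` is ``None`` until
    the pipeline assigns provisional target labels.
    """

    Xs: np.ndarray  # (d, ns)
    ys: np.ndarray  # (ns,)
    Xt: np.ndarray  # (d, nt)
    pseudolabels_t: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Xs = np.asarray(self.Xs, dtype=float)
        self.Xt = np.asarray(self.Xt, dtype=float)
        self.ys = np.asarray(self.ys, dtype=int)
        if self.Xs.shape[0] != self.Xt.shape[0]:
            raise ValueError("source and target must share the feature dimension d")
        if self.Xs.shape[1] < 2 or self.Xt.shape[1] < 2:
            raise ValueError("need at least 2 samples per domain")
        if self.ys.shape != (self.Xs.shape[1],):
            raise ValueError("ys must have one label per source sample")
        if self.pseudolabels_t is not None:
            self.pseudolabels_t = np.asarray(self.pseudolabels_t, dtype=int)
            if self.pseudolabels_t.shape != (self.Xt.shape[1],):
                raise ValueError("pseudolabels_t must have one label per target sample")

    @property
    def d(self) -> int:
        return self.Xs.shape[0]

    @property
    def ns(self) -> int:
        return self.Xs.shape[1]

    @property
    def nt(self) -> int:
        return self.Xt.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.ys)


@dataclass(frozen=True)
class ProjectionModel:
    """Learned subspace transform with its generalized eigenvalues."""

    W: np.ndarray  # (d, k)
    eigenvalues: np.ndarray  # (k,), ascending
    k: int
    lambda_reg: float
    mean_: np.ndarray  # pooled feature means used for centering, (d,)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "W.tsv", self.W, delimiter="\t")
        np.savetxt(outdir / "mean.tsv", self.mean_, delimiter="\t")
        meta = {
            "k": int(self.k),
            "lambda_reg": float(self.lambda_reg),
            "eigenvalues": [float(v) for v in self.eigenvalues],
        }
        (outdir / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, outdir: str | Path) -> "ProjectionModel":
        outdir = Path(outdir)
        meta = json.loads((outdir / "model.json").read_text())
        return cls(
            W=np.loadtxt(outdir / "W.tsv", delimiter="\t", ndmin=2),
            mean_=np.loadtxt(outdir / "mean.tsv", delimiter="\t"),
            eigenvalues=np.asarray(meta["eigenvalues"], dtype=float),
            k=meta["k"],
            lambda_reg=meta["lambda_reg"],
        )


def mmd_matrix_marginal(ns: int, nt: int) -> np.ndarray:
    """Marginal MMD coefficient matrix M0 of shape (ns+nt, ns+nt).

    Entries: 1/ns^2 within the source block, 1/nt^2 within the target block,
    -1/(ns*nt) across.  Every row sums to zero, so constant vectors lie in
    its null space.
    """
    if ns < 1 or nt < 1:
        raise ValueError("ns and nt must be positive")
    n = ns + nt
    M = np.empty((n, n), dtype=float)
    M[:ns, :ns] = 1.0 / ns**2
    M[ns:, ns:] = 1.0 / nt**2
    M[:ns, ns:] = -1.0 / (ns * nt)
    M[ns:, :ns] = -1.0 / (ns * nt)
    return M


def mmd_matrix_conditional(
    ys: np.ndarray, pseudolabels_t: np.ndarray, c: int
) -> np.ndarray:
    """Class-conditional MMD coefficient matrix Mc for class ``c``.

    Rows/columns are ordered source-then-target.  Entries: 1/ns_c^2 within the
    source class-c block, 1/nt_c^2 within the target class-c block,
    -1/(ns_c*nt_c) across, 0 elsewhere.  If the class is absent from the
    target pseudolabels the conditional term is undefined and the zero matrix
    is returned (logged) so the class is simply skipped in the objective.
    """
    ys = np.asarray(ys, dtype=int)
    yt = np.asarray(pseudolabels_t, dtype=int)
    ns, nt = ys.size, yt.size
    src_c = np.flatnonzero(ys == c)
    if src_c.size == 0:
        raise ValueError(f"class {c} absent from source labels")
    tgt_c = np.flatnonzero(yt == c)
    n = ns + nt
    M = np.zeros((n, n), dtype=float)
    if tgt_c.size == 0:
        logger.info("class %d absent from target pseudolabels; Mc set to zero", c)
        return M
    nsc, ntc = src_c.size, tgt_c.size
    tgt_c_full = tgt_c + ns
    M[np.ix_(src_c, src_c)] = 1.0 / nsc**2
    M[np.ix_(tgt_c_full, tgt_c_full)] = 1.0 / ntc**2
    M[np.ix_(src_c, tgt_c_full)] = -1.0 / (nsc * ntc)
    M[np.ix_(tgt_c_full, src_c)] = -1.0 / (nsc * ntc)
    return M


def mmd_distance(Zs: np.ndarray, Zt: np.ndarray) -> float:
    """Squared MMD between two embedded samples: ||mean(Zs) - mean(Zt)||^2.

    Accepts (k, n) column-sample matrices.
    """
    Zs = np.asarray(Zs, dtype=float)
    Zt = np.asarray(Zt, dtype=float)
    if Zs.size == 0 or Zt.size == 0:
        raise ValueError("both samples must be non-empty")
    if Zs.shape[0] != Zt.shape[0]:
        raise ValueError("embedding dimensions differ")
    diff = Zs.mean(axis=1) - Zt.mean(axis=1)
    return float(diff @ diff)


def centering_matrix(n: int) -> np.ndarray:
    """H = I - (1/n) * ones(n, n)."""
    return np.eye(n) - np.full((n, n), 1.0 / n)


def solve_projection(
    pair: DomainPair, k: int = 30, lambda_reg: float = 1.0
) -> ProjectionModel:
    """Solve the constrained joint-MMD minimisation for the transform W.

    When ``pair.pseudolabels_t`` is ``None`` only the marginal matrix M0 enters
    the objective (the pipeline's first iteration); otherwise the per-class
    conditional matrices are added.  Features are centered with the pooled
    source+target mean before solving; the returned model stores that mean so
    :func:`project` applies it consistently.
    """
    d, ns, nt = pair.d, pair.ns, pair.nt
    n = ns + nt
    if not 1 <= k <= min(d, n):
        raise ValueError(f"k={k} must satisfy 1 <= k <= min(d, ns+nt) = {min(d, n)}")

    X = np.hstack([pair.Xs, pair.Xt])
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]

    M = mmd_matrix_marginal(ns, nt)
    if pair.pseudolabels_t is not None:
        for c in pair.classes:
            M = M + mmd_matrix_conditional(pair.ys, pair.pseudolabels_t, int(c))

    H = centering_matrix(n)
    A = Xc @ M @ Xc.T + lambda_reg * np.eye(d)
    B = Xc @ H @ Xc.T + RIGHT_RIDGE * np.eye(d)
    A = (A + A.T) / 2.0
    B = (B + B.T) / 2.0

    eigvals, eigvecs = scipy.linalg.eigh(A, B, subset_by_index=(0, k - 1))
    # eigh returns B-orthonormal eigenvectors in ascending eigenvalue order
    return ProjectionModel(
        W=eigvecs, eigenvalues=eigvals, k=k, lambda_reg=lambda_reg, mean_=mean
    )


def project(X: np.ndarray, model: ProjectionModel) -> np.ndarray:
    """Embed column-sample data: Z = W^T (X - mean)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != model.W.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} feature rows, model expects {model.W.shape[0]}"
        )
    return model.W.T @ (X - model.mean_[:, None])
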