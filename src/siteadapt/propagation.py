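"""Graph label propagation for secondary decisions on deferred samples.

Boundary-region target samples are relabelled by spreading anchor labels —
source-domain truth plus accepted (Pos) target pseudolabels — over a
symmetrized k-nearest-neighbour affinity graph built in the projected space.
Propagation is the classic clamped iteration F <- D^-1 W F with anchor rows
reset each sweep; the returned label is the row argmax, with ties broken by
the lowest class index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .fuzzy3wd import RegionPartition

__all__ = ["PropagationGraph", "build_affinity", "propagate_labels", "refine_pseudolabels"]

logger = logging.getLogger(__name__)


@dataclass
class PropagationGraph:
    """Symmetric nonnegative affinity matrix plus clamped anchor labels.

    ``anchors`` maps node index -> label in {1..C}; all other nodes are
    unlabeled and receive propagated labels.
    """

    affinities: np.ndarray  # (n, n), symmetric, nonnegative, zero diagonal
    anchors: dict[int, int]

    def __post_init__(self) -> None:
        A = self.affinities
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("affinities must be square")
        if not np.allclose(A, A.T):
            raise ValueError("affinities must be symmetric")
        if (A < 0).any():
            raise ValueError("affinities must be nonnegative")

    @property
    def n(self) -> int:
        return self.affinities.shape[0]


def build_affinity(
    Z: np.ndarray,
    anchors: dict[int, int],
    n_neighbors: int = 10,
    bandwidth: float | None = None,
    scaling: str = "local",
) -> PropagationGraph:
    """Symmetrized k-NN graph with Gaussian weights.

    ``Z`` holds column samples (k x n).  With ``scaling='local'`` (default)
    weights are self-tuned per node, ``exp(-d_ij^2 / (s_i s_j))`` with ``s_i``
    the distance from node i to its ``n_neighbors``-th neighbour — robust to
    density variation between the two domains.  With ``scaling='global'`` a
    single Gaussian bandwidth is used, ``exp(-d^2 / (2 s^2))``, where ``s`` is
    ``bandwidth`` or, when unset, the median pairwise distance.  If all points
    coincide the graph degenerates to uniform weights, with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[1]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if scaling not in ("local", "global"):
        raise ValueError("scaling must be 'local' or 'global'")
    D = squareform(pdist(Z.T))
    pos = D[D > 0]
    if pos.size == 0:
        logger.warning("all points identical; using uniform affinities")
        W = np.ones((n, n)) - np.eye(n)
        return PropagationGraph(affinities=W, anchors=dict(anchors))

    nn = min(n_neighbors, n - 1)
    D_offdiag = D.copy()
    np.fill_diagonal(D_offdiag, np.inf)
    order = np.argsort(D_offdiag, axis=1)[:, :nn]

    if bandwidth is not None:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        Wfull = np.exp(-(D**2) / (2.0 * float(bandwidth) ** 2))
    elif scaling == "global":
        sigma = float(np.median(pos))
        Wfull = np.exp(-(D**2) / (2.0 * sigma**2))
    else:
        # self-tuning: per-node scale = distance to the n_neighbors-th
        # neighbour; degenerate (duplicate-heavy) nodes fall back to median
        s = np.sort(D_offdiag, axis=1)[:, nn - 1]
        s[~np.isfinite(s) | (s <= 0)] = float(np.median(pos))
        Wfull = np.exp(-(D**2) / (s[:, None] * s[None, :]))
    np.fill_diagonal(Wfull, 0.0)

    # keep the n_neighbors nearest edges per node, then symmetrize (union)
    keep = np.zeros_like(Wfull, dtype=bool)
    rows = np.repeat(np.arange(n), nn)
    keep[rows, order.ravel()] = True
    keep |= keep.T
    W = np.where(keep, Wfull, 0.0)
    return PropagationGraph(affinities=W, anchors=dict(anchors))


def propagate_labels(
    graph: PropagationGraph,
    tol: float = 1e-6,
    max_sweeps: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Clamped label propagation; returns (labels, confidences) for all nodes.

    Anchor rows are reset to their one-hot labels after every sweep so anchor
    labels are never modified.  Stops when the maximum change of the label
    distribution falls below ``tol``.  Ties at the argmax go to the lowest
    class index (deterministic), logged when they occur.
    """
    if not graph.anchors:
        raise ValueError("propagation requires at least one anchor")
    n = graph.n
    classes = np.unique(sorted(graph.anchors.values()))
    C = classes.size
    col_of = {c: j for j, c in enumerate(classes)}

    F = np.full((n, C), 1.0 / C)
    clamp = np.zeros((n, C))
    anchor_idx = np.fromiter(graph.anchors.keys(), dtype=int)
    for i, c in graph.anchors.items():
        clamp[i, col_of[c]] = 1.0
    F[anchor_idx] = clamp[anchor_idx]

    W = graph.affinities
    deg = W.sum(axis=1)
    deg[deg == 0] = 1.0  # isolated nodes keep their current distribution
    P = W / deg[:, None]

    for _ in range(max_sweeps):
        F_new = P @ F
        F_new[anchor_idx] = clamp[anchor_idx]
        isolated = (W.sum(axis=1) == 0) & ~np.isin(np.arange(n), anchor_idx)
        if isolated.any():
            F_new[isolated] = 1.0 / C
        delta = np.abs(F_new - F).max()
        F = F_new
        if delta < tol:
            break

    best = F.argmax(axis=1)
    ties = (F == F.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("propagation ties at %d node(s); broken by lowest class index", int(ties.sum()))
    labels = classes[best]
    conf = F.max(axis=1)
    return labels.astype(int), conf


def refine_pseudolabels(
    pseudolabels_t: np.ndarray,
    partition: RegionPartition,
    propagated_t: np.ndarray,
    classes: np.ndarray,
    neg_action: str = "flip",
) -> np.ndarray:
    """Apply region actions to target pseudolabels.

    Pos keeps its pseudolabel (accepted); Bnd takes the propagated label
    (deferred, secondary decision); Neg is rejected — in the binary case the
    default action flips to the other class, otherwise (or with
    ``neg_action='defer'``) the propagated label is used.
    """
    out = np.asarray(pseudolabels_t, dtype=int).copy()
    out[partition.bnd] = propagated_t[partition.bnd]
    classes = np.asarray(classes, dtype=int)
    if neg_action == "flip" and classes.size == 2:
        flip = {classes[0]: classes[1], classes[1]: classes[0]}
        out[partition.neg] = [flip[int(v)] for v in out[partition.neg]]
    elif neg_action in ("defer", "flip"):
        out[partition.neg] = propagated_t[partition.neg]
    else:
        raise ValueError(f"unknown neg_action {neg_action!r}")
    return out
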