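"""Triangular-fuzzy-similarity three-way decision triage of target samples.

Given target samples described by m attributes scaled to [0, 1], each object
is summarised by a triangular fuzzy number built from its information
difference structure:

* the information difference between two attribute values x_ij, x_ik is
  ``ID = exp(log2 r)`` with ``r = |x_ij - x_ik| / (x_ij + x_ik)`` (and r := 0
  when the denominator vanishes, ID := 0 when r = 0) — a dissimilarity in
  [0, 1] that is bounded, symmetric, and monotone in the relative gap;
* per object, the m x m matrix of pairwise attribute differences has row sums
  S_j; the triangular fuzzy number is [L, M, T] = [min_j S_j, mean_j S_j,
  max_j S_j] / m, guaranteeing 0 <= L <= M <= T <= 1;
* similarity between two objects is 1 minus the root-mean-square distance of
  their fuzzy triples, again in [0, 1].

An object's membership probability is the fraction of its delta-similar
neighbours sharing its pseudolabel; comparing that probability against the
decision thresholds (alpha, beta) — supplied directly or derived from a
3 x 2 misclassification/deferral cost matrix by Bayesian minimum risk —
splits the target domain into acceptance (Pos), deferral (Bnd), and
rejection (Neg) regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TriangularFuzzyNumber",
    "CostMatrix",
    "RegionPartition",
    "information_difference",
    "triangular_fuzzy_number",
    "tf_similarity",
    "similarity_matrix",
    "delta_level_classes",
    "membership_probability",
    "thresholds_from_costs",
    "partition_regions",
    "minmax_scale_attributes",
    "triage",
]

_LOG2_INV = 1.0 / np.log(2.0)  # exp(log2 r) == r ** (1/ln 2)


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """Fuzzy quantity [L, M, T]: lower bound, median, upper bound in [0, 1]."""

    L: float
    M: float
    T: float

    def __post_init__(self) -> None:
        eps = 1e-12
        if not (-eps <= self.L <= self.M + eps and self.M <= self.T + eps and self.T <= 1 + eps):
            raise ValueError(f"require 0 <= L <= M <= T <= 1, got {(self.L, self.M, self.T)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.M, self.T], dtype=float)


@dataclass(frozen=True)
class CostMatrix:
    """Decision losses for accept (P), defer (B), reject (N) actions when the
    object truly belongs to the similar state (second subscript P) or not (N).

    Orderings l_PP < l_BP < l_NP and l_NN < l_BN < l_PN must hold for the
    derived thresholds to satisfy beta < alpha.
    """

    lPP: float
    lBP: float
    lNP: float
    lNN: float
    lBN: float
    lPN: float

    def __post_init__(self) -> None:
        vals = (self.lPP, self.lBP, self.lNP, self.lNN, self.lBN, self.lPN)
        if any(v < 0 for v in vals):
            raise ValueError("costs must be nonnegative")
        if not (self.lPP < self.lBP < self.lNP):
            raise ValueError("require lPP < lBP < lNP")
        if not (self.lNN < self.lBN < self.lPN):
            raise ValueError("require lNN < lBN < lPN")


@dataclass(frozen=True)
class RegionPartition:
    """Disjoint index sets over target samples plus the thresholds used."""

    pos: np.ndarray
    bnd: np.ndarray
    neg: np.ndarray
    alpha: float
    beta: float
    delta: float = float("nan")

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.pos, self.bnd, self.neg])
        if len(np.unique(all_idx)) != all_idx.size:
            raise ValueError("regions must be pairwise disjoint")

    @property
    def n(self) -> int:
        return self.pos.size + self.bnd.size + self.neg.size

    def sizes(self) -> tuple[int, int, int]:
        return self.pos.size, self.bnd.size, self.neg.size


def information_difference(x: np.ndarray) -> np.ndarray:
    """m x m information-difference matrix of one object's attribute vector.

    Requires attribute values in [0, 1] (see :func:`minmax_scale_attributes`).
    Entry (j, k) is ``r ** (1/ln 2)`` with ``r = |x_j - x_k| / (x_j + x_k)``;
    r is defined as 0 when x_j + x_k = 0 (both values vanish, hence no
    difference) and the r -> 0 limit gives ID = 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D attribute vector")
    if x.min() < -1e-12 or x.max() > 1 + 1e-12:
        raise ValueError("attribute values must be scaled to [0, 1]")
    diff = np.abs(x[:, None] - x[None, :])
    s = x[:, None] + x[None, :]
    r = np.divide(diff, s, out=np.zeros_like(diff), where=s > 0)
    ID = np.zeros_like(r)
    np.power(r, _LOG2_INV, out=ID, where=r > 0)
    np.fill_diagonal(ID, 0.0)
    return ID


def triangular_fuzzy_number(ID: np.ndarray) -> TriangularFuzzyNumber:
    """Summarise an object's information-difference matrix as [L, M, T].

    With row sums S_j = sum_k ID(j, k): L = min_j S_j / m, T = max_j S_j / m,
    M = mean_j S_j / m.  Normalising by m keeps all components in [0, 1] and
    the mean rule guarantees L <= M <= T.
    """
    ID = np.asarray(ID, dtype=float)
    m = ID.shape[0]
    if ID.ndim != 2 or ID.shape[1] != m or m < 2:
        raise ValueError("ID must be a square matrix with m >= 2")
    S = ID.sum(axis=1)
    return TriangularFuzzyNumber(
        L=float(S.min() / m), M=float(S.mean() / m), T=float(S.max() / m)
    )


def tf_similarity(a: TriangularFuzzyNumber, b: TriangularFuzzyNumber) -> float:
    """Similarity 1 - d(a, b), with d the RMS distance of the fuzzy triples."""
    da = a.as_array() - b.as_array()
    return float(1.0 - np.sqrt((da @ da) / 3.0))


def similarity_matrix(tfns: list[TriangularFuzzyNumber]) -> np.ndarray:
    """Pairwise triangular-fuzzy similarity matrix (vectorised)."""
    A = np.vstack([t.as_array() for t in tfns])
    sq = ((A[:, None, :] - A[None, :, :]) ** 2).sum(axis=2)
    return 1.0 - np.sqrt(sq / 3.0)


def delta_level_classes(
    sim_row: np.ndarray, delta: float, i: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split the other objects by whether similarity to object i strictly
    exceeds delta: (similar set, dissimilar set)."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    sim_row = np.asarray(sim_row, dtype=float)
    others = np.flatnonzero(np.arange(sim_row.size) != i)
    similar = others[sim_row[others] > delta]
    dissimilar = others[sim_row[others] <= delta]
    return similar, dissimilar


def membership_probability(
    sim: np.ndarray, pseudolabels: np.ndarray, delta: float, i: int
) -> float:
    """Fraction of object i's delta-similar neighbours sharing its pseudolabel.

    An empty neighbourhood gives 0.5 — maximal uncertainty, sending the object
    toward the deferral region for the usual alpha > 0.5 > beta settings.
    """
    similar, _ = delta_level_classes(sim[i], delta, i)
    if similar.size == 0:
        return 0.5
    labels = np.asarray(pseudolabels)
    return float(np.mean(labels[similar] == labels[i]))


def thresholds_from_costs(costs: CostMatrix) -> tuple[float, float]:
    """Bayesian minimum-risk thresholds from the cost matrix:

    alpha = (lPN - lBN) / ((lPN - lBN) + (lBP - lPP)),
    beta  = (lBN - lNN) / ((lBN - lNN) + (lNP - lBP)).

    Both are scale-invariant ratios; configurations yielding alpha <= beta are
    rejected because the three regions would not be well defined.
    """
    alpha = (costs.lPN - costs.lBN) / ((costs.lPN - costs.lBN) + (costs.lBP - costs.lPP))
    beta = (costs.lBN - costs.lNN) / ((costs.lBN - costs.lNN) + (costs.lNP - costs.lBP))
    if not beta < alpha:
        raise ValueError(f"cost matrix yields alpha={alpha} <= beta={beta}")
    return float(alpha), float(beta)


def partition_regions(
    probabilities: np.ndarray, alpha: float, beta: float, delta: float = float("nan")
) -> RegionPartition:
    """Three-way split of the index range by membership probability:
    p >= alpha -> Pos; beta < p < alpha -> Bnd; p <= beta -> Neg."""
    if not 0.0 <= beta < alpha <= 1.0:
        raise ValueError(f"require 0 <= beta < alpha <= 1, got alpha={alpha}, beta={beta}")
    p = np.asarray(probabilities, dtype=float)
    return RegionPartition(
        pos=np.flatnonzero(p >= alpha),
        bnd=np.flatnonzero((p > beta) & (p < alpha)),
        neg=np.flatnonzero(p <= beta),
        alpha=float(alpha),
        beta=float(beta),
        delta=float(delta),
    )


def minmax_scale_attributes(Z: np.ndarray) -> np.ndarray:
    """Min-max scale each attribute (row of a k x n matrix) to [0, 1] over the
    samples entering the triage step; constant attributes map to 0."""
    Z = np.asarray(Z, dtype=float)
    lo = Z.min(axis=1, keepdims=True)
    rng = Z.max(axis=1, keepdims=True) - lo
    out = np.zeros_like(Z)
    nz = rng[:, 0] > 0
    out[nz] = (Z[nz] - lo[nz]) / rng[nz]
    return out


def triage(
    Zt: np.ndarray,
    pseudolabels_t: np.ndarray,
    delta: float,
    alpha: float,
    beta: float,
) -> tuple[RegionPartition, np.ndarray]:
    """Run the full three-way triage on projected target features.

    ``Zt`` is the k x nt projected target matrix.  Attributes are min-max
    scaled, each object summarised by its triangular fuzzy number, pairwise
    similarities computed, membership probabilities evaluated against the
    delta-level neighbourhoods, and the (alpha, beta) rule applied.

    Returns ``(partition, probabilities)``.
    """
    Zt = np.asarray(Zt, dtype=float)
    X01 = minmax_scale_attributes(Zt)
    nt = Zt.shape[1]
    tfns = [triangular_fuzzy_number(information_difference(X01[:, i])) for i in range(nt)]
    sim = similarity_matrix(tfns)
    probs = np.array(
        [membership_probability(sim, pseudolabels_t, delta, i) for i in range(nt)]
    )
    return partition_regions(probs, alpha, beta, delta=delta), probs
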