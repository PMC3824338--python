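"""Fuzzy-relation cluster analysis of attribute tables, plus Ward linkage.

Objects are rated on ``m`` attributes by trapezoidal fuzzy numbers
``(c, a, b, d)`` with support ``[c, d]`` and core ``[a, b]``; crisp values
are the degenerate case ``c = a = b = d``.  The clustering proceeds:

1. columnwise min-max normalization of the ratings into [0, 1];
2. a fuzzy *compatibility relation* ``R(i, k) = 1 − η · Σ_j d²(x̃_ij, x̃_kj)``
   where ``d²`` is Chen's modified geometrical distance (squared, p = 2) and
   ``η`` is the reciprocal of the largest summed distance, so the farthest
   pair sits exactly at 0 and the diagonal at 1;
3. the max–min transitive closure of ``R`` (iterated self-composition),
   which is a fuzzy equivalence relation;
4. λ-cuts of the closure for λ descending over its distinct values, giving a
   nested series of crisp partitions;
5. a validity index ``L = T / (n · d²_min)`` — total within-cluster scatter
   over ``n`` times the smallest squared centroid separation — whose minimum
   over the series marks the preferred cluster count.

Ward's minimum-variance hierarchical clustering of the same (crisp)
attribute vectors is provided alongside, with Newick and merge-table export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateAttributeError,
    InvalidPartitionError,
    NotTransitiveError,
    ValidityUndefinedError,
)

#: Componentwise weight of Chen's distance; 1/4 averages the four corners.
CHEN_WEIGHT = 0.25


@dataclass(frozen=True)
class TrapezoidalFuzzyNumber:
    """Trapezoidal fuzzy number ``(c, a, b, d)``, ``c ≤ a ≤ b ≤ d``."""

    c: float
    a: float
    b: float
    d: float

    def __post_init__(self) -> None:
        if not (self.c <= self.a <= self.b <= self.d):
            raise ValueError(
                f"require c <= a <= b <= d, got ({self.c}, {self.a}, {self.b}, {self.d})"
            )

    @classmethod
    def crisp(cls, x: float) -> "TrapezoidalFuzzyNumber":
        return cls(x, x, x, x)

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.a, self.b, self.d], dtype=float)


@dataclass
class AttributeMatrix:
    """``n`` objects rated on ``m`` attributes; ratings shape ``(n, m, 4)``."""

    ratings: np.ndarray
    object_ids: list = field(default_factory=list)
    attribute_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.ratings.ndim != 3 or self.ratings.shape[2] != 4:
            raise ValueError("ratings must have shape (n, m, 4)")
        if np.any(np.diff(self.ratings, axis=2) < -1e-12):
            raise ValueError("every rating must satisfy c <= a <= b <= d")
        if not self.object_ids:
            self.object_ids = list(range(self.ratings.shape[0]))
        if not self.attribute_names:
            self.attribute_names = list(range(self.ratings.shape[1]))

    @property
    def n(self) -> int:
        return self.ratings.shape[0]

    @property
    def m(self) -> int:
        return self.ratings.shape[1]


def crisp_matrix(
    values: np.ndarray,
    object_ids: Sequence | None = None,
    attribute_names: Sequence | None = None,
) -> AttributeMatrix:
    """Wrap a crisp ``(n, m)`` table as degenerate trapezoidal ratings."""
    values = np.asarray(values, dtype=float)
    ratings = np.repeat(values[:, :, None], 4, axis=2)
    return AttributeMatrix(
        ratings,
        list(object_ids) if object_ids is not None else [],
        list(attribute_names) if attribute_names is not None else [],
    )


@dataclass
class NormalizedAttributeMatrix:
    """Column-normalized ratings with the per-attribute statistics used."""

    ratings: np.ndarray
    c_star: np.ndarray
    d_star: np.ndarray
    t_star: np.ndarray
    object_ids: list
    attribute_names: list
    dropped_attributes: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.ratings.shape[0]

    @property
    def m(self) -> int:
        return self.ratings.shape[1]


def normalize(matrix: AttributeMatrix) -> NormalizedAttributeMatrix:
    """Min-max normalize each attribute column into [0, 1].

    Per column ``j``: ``c*_j = min_i c_ij``, ``d*_j = max_i d_ij``,
    ``t*_j = d*_j − c*_j``; every component of every rating is mapped by
    ``(x − c*_j) / t*_j``.  Constant columns (``t*_j = 0``) carry no
    information and are dropped with a warning; if all columns are constant
    a :class:`DegenerateAttributeError` is raised.
    """
    c_star = matrix.ratings[:, :, 0].min(axis=0)
    d_star = matrix.ratings[:, :, 3].max(axis=0)
    t_star = d_star - c_star
    keep = t_star > 0
    if not np.any(keep):
        raise DegenerateAttributeError("all attribute columns are constant")
    dropped = [n for n, k in zip(matrix.attribute_names, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping constant attribute columns {dropped}", stacklevel=2
        )
    ratings = (matrix.ratings[:, keep, :] - c_star[keep][None, :, None]) / t_star[
        keep
    ][None, :, None]
    ratings = np.clip(ratings, 0.0, 1.0)
    names = [n for n, k in zip(matrix.attribute_names, keep) if k]
    return NormalizedAttributeMatrix(
        ratings=ratings,
        c_star=c_star[keep],
        d_star=d_star[keep],
        t_star=t_star[keep],
        object_ids=list(matrix.object_ids),
        attribute_names=names,
        dropped_attributes=dropped,
    )


def chen_distance_sq(x, y, weight: float = CHEN_WEIGHT) -> float | np.ndarray:
    """Chen's modified geometrical distance, squared (p = 2).

    ``d²(x, y) = weight · Σ_{k ∈ {c,a,b,d}} (x_k − y_k)²`` — with the default
    weight 1/4 this averages the four corner differences, and on crisp inputs
    reduces to the plain squared difference.  Accepts
    :class:`TrapezoidalFuzzyNumber` instances or arrays whose last axis has
    length 4 (broadcast over leading axes).
    """
    xa = x.as_array() if isinstance(x, TrapezoidalFuzzyNumber) else np.asarray(x, dtype=float)
    ya = y.as_array() if isinstance(y, TrapezoidalFuzzyNumber) else np.asarray(y, dtype=float)
    return weight * np.sum((xa - ya) ** 2, axis=-1)


def _pairwise_summed_distance(ratings: np.ndarray, weight: float = CHEN_WEIGHT) -> np.ndarray:
    """``D[i, k] = Σ_j d²(x̃_ij, x̃_kj)`` for ratings of shape (n, m, 4)."""
    flat = ratings.reshape(ratings.shape[0], -1)
    return weight * cdist(flat, flat, metric="sqeuclidean")


@dataclass
class CompatibilityMatrix:
    """Fuzzy compatibility relation with its scaling constant ``eta``.

    ``eta is None`` flags the degenerate all-identical-objects case, where
    the relation defaults to all ones.
    """

    values: np.ndarray
    eta: float | None
    object_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("compatibility matrix must be square")
        if not self.object_ids:
            self.object_ids = list(range(n))

    @property
    def n(self) -> int:
        return self.values.shape[0]


def compatibility(normalized: NormalizedAttributeMatrix) -> CompatibilityMatrix:
    """Build the fuzzy compatibility relation from normalized ratings.

    ``R(i, k) = 1 − η Σ_j d²(x̃_ij, x̃_kj)`` with ``η`` the reciprocal of the
    largest summed distance, so R is symmetric with unit diagonal, all
    entries in [0, 1], and exactly 0 for the farthest pair.  If all objects
    are identical ``η`` is undefined; R is returned as all ones with
    ``eta=None``.
    """
    if normalized.n < 2:
        raise ValueError("need at least two objects")
    D = _pairwise_summed_distance(normalized.ratings)
    dmax = float(D.max())
    if dmax == 0.0:
        warnings.warn(
            "all objects identical: compatibility degenerate (eta undefined)",
            stacklevel=2,
        )
        return CompatibilityMatrix(
            np.ones_like(D), eta=None, object_ids=list(normalized.object_ids)
        )
    eta = 1.0 / dmax
    R = 1.0 - eta * D
    R = np.clip(R, 0.0, 1.0)
    np.fill_diagonal(R, 1.0)
    R = 0.5 * (R + R.T)  # kill round-off asymmetry
    return CompatibilityMatrix(R, eta=eta, object_ids=list(normalized.object_ids))


def _maxmin_compose(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Max–min composition ``(A ∘ B)[i, j] = max_k min(A[i,k], B[k,j])``."""
    return np.max(np.minimum(A[:, :, None], B[None, :, :]), axis=1)


def is_transitive(values: np.ndarray, tol: float = 1e-12) -> bool:
    """True when ``R ∘ R ≤ R`` elementwise (max–min transitivity)."""
    return bool(np.all(_maxmin_compose(values, values) <= values + tol))


def transitive_closure(R: CompatibilityMatrix) -> CompatibilityMatrix:
    """Max–min transitive closure by repeated self-composition (squaring).

    For a reflexive symmetric relation the sequence ``R, R², R⁴, …`` is
    monotone non-decreasing and reaches its fixpoint — the smallest fuzzy
    equivalence relation containing R — in at most ``⌈log₂(n−1)⌉`` squarings.
    """
    current = R.values.copy()
    n = current.shape[0]
    max_steps = max(1, int(np.ceil(np.log2(max(n - 1, 1)))) + 1)
    for _ in range(max_steps):
        nxt = _maxmin_compose(current, current)
        if np.array_equal(nxt, current):
            break
        current = nxt
    return CompatibilityMatrix(current, eta=R.eta, object_ids=list(R.object_ids))


@dataclass
class Partition:
    """Crisp partition produced by a λ-cut."""

    lam: float
    clusters: list[list]
    object_ids: list

    @property
    def h(self) -> int:
        return len(self.clusters)

    def labels(self) -> np.ndarray:
        """Cluster index per object, in object order."""
        pos = {oid: i for i, oid in enumerate(self.object_ids)}
        lab = np.empty(len(self.object_ids), dtype=int)
        for r, members in enumerate(self.clusters):
            for oid in members:
                lab[pos[oid]] = r
        return lab


def lambda_cut(Rt: CompatibilityMatrix, lam: float) -> Partition:
    """Threshold a fuzzy equivalence relation at level ``lam``.

    Objects i, k share a cluster iff ``Rt(i, k) ≥ lam``; transitivity of Rt
    guarantees the ≥-blocks are disjoint, which is validated up front.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if not is_transitive(Rt.values, tol=1e-9):
        raise NotTransitiveError(
            "lambda-cut requires a max-min transitive relation; "
            "apply transitive_closure first"
        )
    adj = Rt.values >= lam
    n = Rt.n
    seen = np.zeros(n, dtype=bool)
    clusters: list[list] = []
    for i in range(n):
        if seen[i]:
            continue
        members = np.flatnonzero(adj[i])
        seen[members] = True
        clusters.append([Rt.object_ids[j] for j in members])
    return Partition(lam=lam, clusters=clusters, object_ids=list(Rt.object_ids))


def lambda_series(Rt: CompatibilityMatrix) -> list[Partition]:
    """λ-cut partitions at every distinct value of Rt, λ descending from 1.

    The resulting series is nested: as λ decreases clusters only merge.
    Consecutive duplicates (same partition at different λ) are kept only at
    the largest λ that produces them.
    """
    values = np.unique(Rt.values)[::-1]
    series: list[Partition] = []
    prev_h = None
    for lam in values:
        part = lambda_cut(Rt, float(lam))
        if prev_h is None or part.h != prev_h:
            series.append(part)
            prev_h = part.h
    return series


@dataclass
class ValidityResult:
    """Validity index ``L = T / (n · d²_min)`` and its ingredients."""

    h: int
    L: float
    T: float
    d_min_sq: float
    memberships: np.ndarray
    centroids: np.ndarray


def validity_index(
    normalized: NormalizedAttributeMatrix, partition: Partition
) -> ValidityResult:
    """Compactness-over-separation validity of a partition.

    ``T`` is the total squared Chen distance of objects to their cluster
    centroid (componentwise mean of member ratings); ``d²_min`` the smallest
    squared distance between two centroids.  Smaller L = tighter, better
    separated clustering.  Needs ``h ≥ 2`` clusters, all non-empty.
    """
    h = partition.h
    if h < 2:
        raise ValidityUndefinedError(
            "validity index needs at least two clusters (d_min undefined)"
        )
    if any(len(c) == 0 for c in partition.clusters):
        raise InvalidPartitionError("partition contains an empty cluster")
    pos = {oid: i for i, oid in enumerate(normalized.object_ids)}
    n = normalized.n
    memberships = np.zeros((n, h), dtype=int)
    centroids = np.empty((h, normalized.m, 4))
    T = 0.0
    for r, members in enumerate(partition.clusters):
        rows = [pos[oid] for oid in members]
        memberships[rows, r] = 1
        centroids[r] = normalized.ratings[rows].mean(axis=0)
        diffs = normalized.ratings[rows] - centroids[r][None, :, :]
        T += CHEN_WEIGHT * float(np.sum(diffs**2))
    flat = centroids.reshape(h, -1)
    D = CHEN_WEIGHT * cdist(flat, flat, metric="sqeuclidean")
    d_min_sq = float(D[np.triu_indices(h, k=1)].min())
    if d_min_sq == 0.0:
        raise InvalidPartitionError("two cluster centroids coincide")
    L = T / (n * d_min_sq)
    return ValidityResult(
        h=h, L=L, T=T, d_min_sq=d_min_sq, memberships=memberships, centroids=centroids
    )


def validity_table(
    normalized: NormalizedAttributeMatrix, partitions: Sequence[Partition]
) -> pd.DataFrame:
    """Evaluate L over a λ-series, skipping degenerate partitions.

    Partitions with ``h < 2`` and the all-singleton partition (where ``T = 0``
    makes L trivially minimal) are excluded from the comparison.
    """
    rows = []
    n = normalized.n
    for part in partitions:
        if part.h < 2 or part.h >= n:
            continue
        res = validity_index(normalized, part)
        rows.append(dict(lam=part.lam, h=part.h, L=res.L, T=res.T, d_min_sq=res.d_min_sq))
    return pd.DataFrame(rows, columns=["lam", "h", "L", "T", "d_min_sq"])


def best_partition(
    normalized: NormalizedAttributeMatrix, partitions: Sequence[Partition]
) -> Partition:
    """The partition with smallest L among non-degenerate candidates."""
    table = validity_table(normalized, partitions)
    if table.empty:
        raise ValidityUndefinedError("no partition with 2 <= h < n in the series")
    best_h = int(table.loc[table["L"].idxmin(), "h"])
    for part in partitions:
        if part.h == best_h:
            return part
    raise RuntimeError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# Ward hierarchical clustering of crisp attribute vectors.

@dataclass
class Dendrogram:
    """Ward linkage over crisp attribute vectors, with labelled leaves."""

    linkage: np.ndarray
    object_ids: list

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (0-based) from cutting the tree into k groups."""
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust") - 1

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return str(self.object_ids[node.id])
            left, right = node.get_left(), node.get_right()
            return (
                f"({render(left)}:{node.dist - left.dist:.6g},"
                f"{render(right)}:{node.dist - right.dist:.6g})"
            )

        return render(tree) + ";"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "size"]
        )


def ward_dendrogram(
    vectors: np.ndarray, object_ids: Sequence | None = None
) -> Dendrogram:
    """Full agglomerative tree under Ward's minimum-variance criterion on
    Euclidean distances between (crisp) attribute vectors."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two objects")
    Z = hierarchy.linkage(vectors, method="ward")
    ids = list(object_ids) if object_ids is not None else list(range(vectors.shape[0]))
    return Dendrogram(linkage=Z, object_ids=ids)
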