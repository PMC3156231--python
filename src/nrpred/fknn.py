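"""Fuzzy K-nearest-neighbor classification.

A query's fuzzy membership in class i is the inverse-distance-weighted
fraction of its K nearest reference neighbors belonging to that class:

    mu_i(q) = sum_j mu_ij * d_j^(-2/(m-1)) / sum_j d_j^(-2/(m-1))

with crisp reference memberships mu_ij in {0, 1} and Euclidean distances
d_j.  The fuzzy coefficient m > 1 controls how heavily distance is
weighted: m -> 1+ recovers the single nearest neighbor, m -> infinity the
plain K-neighbor vote.  The query is assigned to the class of highest
membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError
from .fusion import PseaacVector

#: Distances below this are treated as exact coincidence with a reference
#: point; membership then becomes a uniform vote over the coincident points.
ZERO_DISTANCE = 1e-12


@dataclass(frozen=True)
class FknnParams:
    """Number of neighbors K, fuzzy coefficient m, and the distance metric."""

    K: int = 3
    m: float = 2.0
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ParameterError(f"K must be >= 1, got {self.K}")
        if not self.m > 1:
            raise ParameterError(f"m must be > 1, got {self.m}")
        if self.metric != "euclidean":
            raise ParameterError(f"unsupported metric {self.metric!r}")


@dataclass
class ReferenceSet:
    """Labeled feature vectors serving as the FKNN training instances.

    ``classes`` is the ordered list of distinct class tags (order of first
    appearance unless given); ``label_indices`` maps each row to its class
    index.  ``identifiers`` and ``sequences`` are optional provenance used
    for leakage checks.
    """

    X: np.ndarray
    labels: list[str]
    classes: list[str] = field(default=None)  # type: ignore[assignment]
    identifiers: Optional[list[str]] = None
    sequences: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise ParameterError("X must be (N, d) with one label per row")
        if self.X.shape[0] < 2:
            raise ParameterError("reference set needs at least 2 instances")
        if self.classes is None:
            self.classes = list(dict.fromkeys(self.labels))
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ParameterError(f"labels outside the class list: {sorted(unknown)}")
        if len(self.classes) < 2:
            raise ParameterError("reference set needs at least 2 distinct classes")
        index = {c: i for i, c in enumerate(self.classes)}
        self.label_indices = np.array([index[l] for l in self.labels], dtype=np.intp)

    @property
    def n(self) -> int:
        return self.X.shape[0]


def _as_array(query) -> np.ndarray:
    if isinstance(query, PseaacVector):
        return query.values
    return np.asarray(query, dtype=float)


def neighbor_search(
    query, ref: ReferenceSet, K: int
) -> list[tuple[float, str]]:
    """The K smallest Euclidean distances with their labels, ascending.

    Distance ties are broken by reference insertion order (stable sort).
    """
    if K < 1 or K > ref.n:
        raise ParameterError(f"K={K} out of range for reference set of size {ref.n}")
    d = np.linalg.norm(ref.X - _as_array(query), axis=1)
    order = np.argsort(d, kind="stable")[:K]
    return [(float(d[i]), ref.labels[i]) for i in order]


def _profiles(
    dists: np.ndarray, neighbor_classes: np.ndarray, n_classes: int, m: float
) -> np.ndarray:
    """Membership profiles from (n, K) neighbor distances and class indices.

    Distances are normalized per row by the smallest positive entry before
    exponentiation; the membership ratio is invariant under that scaling and
    it keeps d^(-2/(m-1)) finite even for m close to 1.
    """
    n, K = dists.shape
    zero = dists < ZERO_DISTANCE
    any_zero = zero.any(axis=1)
    weights = np.zeros_like(dists)

    regular = ~any_zero
    if regular.any():
        d = dists[regular]
        scale = d.min(axis=1, keepdims=True)
        with np.errstate(over="ignore", under="ignore"):
            w = (d / scale) ** (-2.0 / (m - 1.0))
        weights[regular] = w
    # coincident reference points: uniform vote over the zero-distance ones
    weights[any_zero] = zero[any_zero].astype(float)

    prof = np.zeros((n, n_classes))
    rows = np.repeat(np.arange(n), K)
    np.add.at(prof, (rows, neighbor_classes.ravel()), weights.ravel())
    prof /= prof.sum(axis=1, keepdims=True)
    return prof


def _decide(
    prof: np.ndarray, nearest_class: np.ndarray
) -> np.ndarray:
    """Argmax with ties broken toward the nearest neighbor's class, then order."""
    best = prof.max(axis=1)
    is_tied = (prof == best[:, None]).sum(axis=1) > 1
    decision = prof.argmax(axis=1)
    for i in np.nonzero(is_tied)[0]:
        tied = np.nonzero(prof[i] == best[i])[0]
        decision[i] = nearest_class[i] if nearest_class[i] in tied else tied[0]
    return decision


@dataclass(frozen=True)
class MembershipProfile:
    """Per-class fuzzy membership values for one query; sums to 1."""

    memberships: dict[str, float]


def memberships(
    query, ref: ReferenceSet, params: FknnParams = FknnParams()
) -> MembershipProfile:
    """Fuzzy membership of a query in each reference class."""
    if params.K > ref.n:
        raise ParameterError(f"K={params.K} exceeds reference size {ref.n}")
    d = np.linalg.norm(ref.X - _as_array(query), axis=1)
    order = np.argsort(d, kind="stable")[: params.K]
    prof = _profiles(
        d[order][None, :],
        ref.label_indices[order][None, :],
        len(ref.classes),
        params.m,
    )[0]
    return MembershipProfile(dict(zip(ref.classes, prof.tolist())))


def predict(
    query, ref: ReferenceSet, params: FknnParams = FknnParams()
) -> tuple[str, float]:
    """Crisp decision: the class of highest membership and its value."""
    if params.K > ref.n:
        raise ParameterError(f"K={params.K} exceeds reference size {ref.n}")
    d = np.linalg.norm(ref.X - _as_array(query), axis=1)
    order = np.argsort(d, kind="stable")[: params.K]
    nbr_classes = ref.label_indices[order][None, :]
    prof = _profiles(d[order][None, :], nbr_classes, len(ref.classes), params.m)
    cls = _decide(prof, nbr_classes[:, 0])[0]
    return ref.classes[cls], float(prof[0, cls])


def predict_batch(
    queries: np.ndarray, ref: ReferenceSet, params: FknnParams = FknnParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized crisp decisions for a (n, d) query matrix.

    Returns (class indices into ``ref.classes``, winning memberships).
    """
    if params.K > ref.n:
        raise ParameterError(f"K={params.K} exceeds reference size {ref.n}")
    D = cdist(np.atleast_2d(queries), ref.X)
    order = np.argsort(D, axis=1, kind="stable")[:, : params.K]
    dists = np.take_along_axis(D, order, axis=1)
    nbr_classes = ref.label_indices[order]
    prof = _profiles(dists, nbr_classes, len(ref.classes), params.m)
    decision = _decide(prof, nbr_classes[:, 0])
    return decision, prof[np.arange(len(decision)), decision]
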