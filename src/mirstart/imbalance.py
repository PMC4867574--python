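"""Class-imbalance handling.

Sliding-window enumeration yields one true start against tens of
decoys per hairpin.  The first boosting round therefore trains on a
balanced subset: the negatives are clustered (k-means, Euclidean
distance on normalized features) and each cluster contributes its
centroid-nearest members.  Later rounds grow the subset with the
samples the previous round misclassified on the full training set —
hard-example mining with deduplication.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .features import N_FEATURES
from .io import MirstartError

SampleKey = tuple[str, int]  # (hairpin_id, window start)

DEFAULT_CLUSTERS = 10


@dataclass
class TrainingSet:
    """Aligned feature matrix, ±1 labels and (hairpin_id, start) keys."""

    vectors: np.ndarray
    labels: np.ndarray
    sample_keys: list[SampleKey]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.vectors.shape[0]
        if len(self.labels) != n or len(self.sample_keys) != n:
            raise MirstartError("vectors, labels and sample_keys must align")
        if len(set(self.sample_keys)) != n:
            raise MirstartError("sample_keys must be unique")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise MirstartError("labels must be +1/-1")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def positive_keys(self) -> list[SampleKey]:
        return [k for k, y in zip(self.sample_keys, self.labels) if y == 1]

    def index_of(self, keys) -> np.ndarray:
        lookup = {k: i for i, k in enumerate(self.sample_keys)}
        return np.array(sorted(lookup[k] for k in keys), dtype=int)


@dataclass(frozen=True)
class BalancedSubset:
    """Membership of one boosting round's training subset."""

    member_keys: frozenset[SampleKey]
    round_index: int

    def __len__(self) -> int:
        return len(self.member_keys)


def feature_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two 110-dim feature vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (N_FEATURES,) or b.shape != (N_FEATURES,):
        raise MirstartError(
            f"feature vectors must both have length {N_FEATURES}"
        )
    return float(np.linalg.norm(a - b))


def cluster_negatives(
    neg_matrix: np.ndarray, k: int = DEFAULT_CLUSTERS, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the negative samples into k groups with seeded
    k-means; returns (assignments, centroids)."""
    neg_matrix = np.asarray(neg_matrix, dtype=float)
    if neg_matrix.shape[0] < k:
        raise MirstartError(
            f"need at least k={k} negatives, got {neg_matrix.shape[0]}"
        )
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed)
    assignments = km.fit_predict(neg_matrix)
    return assignments, km.cluster_centers_


def select_representatives(
    neg_matrix: np.ndarray,
    neg_keys: list[SampleKey],
    assignments: np.ndarray,
    centroids: np.ndarray,
    n_total: int,
) -> list[SampleKey]:
    """Centroid-nearest undersampling: from each cluster take the
    ceil(n_total / k) members closest to its centroid (ties broken by
    sample key), then trim globally to n_total dropping the farthest.
    """
    neg_matrix = np.asarray(neg_matrix, dtype=float)
    if n_total > neg_matrix.shape[0]:
        raise MirstartError("n_total exceeds number of negatives")
    k = centroids.shape[0]
    per_cluster = math.ceil(n_total / k)
    pool: list[tuple[float, SampleKey]] = []
    for c in range(k):
        idx = np.flatnonzero(assignments == c)
        if idx.size == 0:
            continue
        dists = np.linalg.norm(neg_matrix[idx] - centroids[c], axis=1)
        members = sorted(
            zip(dists.tolist(), (neg_keys[i] for i in idx)),
            key=lambda t: (t[0], t[1]),
        )
        pool.extend(members[:per_cluster])
    pool.sort(key=lambda t: (t[0], t[1]))
    return [key for _, key in pool[:n_total]]


def build_initial_subset(
    train: TrainingSet,
    k: int = DEFAULT_CLUSTERS,
    seed: int = 0,
    n_negatives: int | None = None,
) -> BalancedSubset:
    """Round-1 subset: all positives plus centroid-nearest negative
    representatives (default as many negatives as positives)."""
    pos_keys = train.positive_keys()
    if not pos_keys:
        raise MirstartError("training set has no positives")
    neg_mask = train.labels == -1
    neg_keys = [kk for kk, y in zip(train.sample_keys, train.labels) if y == -1]
    if n_negatives is None:
        n_negatives = len(pos_keys)
    assignments, centroids = cluster_negatives(
        train.vectors[neg_mask], k=k, seed=seed
    )
    reps = select_representatives(
        train.vectors[neg_mask], neg_keys, assignments, centroids, n_negatives
    )
    return BalancedSubset(
        member_keys=frozenset(pos_keys) | frozenset(reps), round_index=1
    )


def assemble_round_subset(
    prev: BalancedSubset, incorrect_keys
) -> BalancedSubset:
    """Next round's subset: previous members plus the misclassified
    sample keys, deduplicated (positives are members already and stay).
    """
    return BalancedSubset(
        member_keys=prev.member_keys | frozenset(incorrect_keys),
        round_index=prev.round_index + 1,
    )
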