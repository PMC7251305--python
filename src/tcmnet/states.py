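"""Symbolic dynamics: discretize block series into categorical state sequences.

The three linguistic features of one role (POS, NEG, AB) are z-scored and
partitioned with K-means; each cluster is a *state* of the system and each
block is replaced by its state label, yielding a symbolic time series fit for
Markov analysis.  States are relabeled 1..k by descending occupancy so that a
fitted model is deterministic given its seed.  Scarcely populated states are
treated as outliers: their blocks are deleted and the surviving sequence is
re-concatenated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

Role = str  # "patient" | "therapist" | "dyad"


class StateError(ValueError):
    """Raised on degenerate inputs to the discretization stage."""


@dataclass
class ClusterModel:
    """K-means state model for one role, in standardized feature space."""

    role: Role
    k: int
    feature_means: np.ndarray  # (3,)
    feature_sds: np.ndarray  # (3,)
    centroids: np.ndarray  # (k, 3), standardized units, row i = state i+1
    occupancy: np.ndarray  # (k,) training counts per state
    variance_explained: float  # between-cluster SS / total SS
    active_states: tuple[int, ...] = ()  # 1-based labels surviving pruning

    def __post_init__(self) -> None:
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=int)
        if not self.active_states:
            self.active_states = tuple(range(1, self.k + 1))
        if not np.all(np.isfinite(self.centroids)):
            raise StateError("centroids must be finite")
        if not (0.0 <= self.variance_explained <= 1.0 + 1e-12):
            raise StateError("variance_explained must lie in [0, 1]")
        if not set(self.active_states) <= set(range(1, self.k + 1)):
            raise StateError("active_states must be a subset of 1..k")

    def to_json(self, path) -> None:
        payload = {
            "role": self.role,
            "k": self.k,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "centroids": self.centroids.tolist(),
            "occupancy": self.occupancy.tolist(),
            "variance_explained": self.variance_explained,
            "active_states": list(self.active_states),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload["active_states"] = tuple(payload["active_states"])
        return cls(**payload)


@dataclass
class StateSequence:
    """Ordered 1-based state labels for one subject and role.

    ``block_indices`` keeps the original block positions of the surviving
    labels so that two roles of one dyad can be re-aligned after each was
    pruned independently; ``dropped_indices`` records what pruning removed.
    """

    labels: np.ndarray
    role: Role
    subject_id: str = ""
    block_indices: np.ndarray | None = None
    dropped_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.block_indices is None:
            self.block_indices = np.arange(len(self.labels))
        self.block_indices = np.asarray(self.block_indices, dtype=int)
        self.dropped_indices = np.asarray(self.dropped_indices, dtype=int)
        if len(self.block_indices) != len(self.labels):
            raise StateError("block_indices and labels must have equal length")

    def __len__(self) -> int:
        return len(self.labels)


def standardize(
    X: np.ndarray, constants: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Z-score feature columns; returns (Z, (means, sds)).

    When ``constants`` is given (means, sds from a training fit) they are
    applied unchanged, so new data land in the same standardized space.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise StateError("need a 2-D matrix with at least 2 rows")
    if constants is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0)  # population SD: standardized columns have SD exactly 1
        zero = np.nonzero(sds == 0)[0]
        if zero.size:
            raise StateError(f"zero-variance feature column(s): {zero.tolist()}")
    else:
        means, sds = (np.asarray(a, dtype=float) for a in constants)
        if np.any(sds <= 0):
            raise StateError("stored feature SDs must be positive")
    return (X - means) / sds, (means, sds)


def _total_ss(Z: np.ndarray) -> float:
    return float(((Z - Z.mean(axis=0)) ** 2).sum())


def fit_states(
    Z: np.ndarray,
    k: int = 8,
    n_restarts: int = 50,
    seed: int = 0,
    role: Role = "patient",
    constants: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[ClusterModel, np.ndarray]:
    """Fit a k-state K-means model on standardized data; returns (model, labels).

    Best of ``n_restarts`` runs by within-cluster sum of squares.  States are
    relabeled 1..k by descending occupancy (ties by the provisional label), so
    the labeling is deterministic given the seed.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < k:
        raise StateError(f"need at least k={k} rows, got {Z.shape[0]}")
    if k < 2:
        raise StateError("k must be >= 2")
    if np.unique(Z, axis=0).shape[0] < k:
        raise StateError("k exceeds the number of distinct data points")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(Z)
    counts = np.bincount(raw, minlength=k)
    order = np.argsort(-counts, kind="stable")  # rank 0 = most occupied
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw] + 1
    centroids = km.cluster_centers_[order]
    occupancy = counts[order]
    tss = _total_ss(Z)
    ve = 1.0 - km.inertia_ / tss if tss > 0 else 1.0
    if constants is None:
        means = np.zeros(Z.shape[1])
        sds = np.ones(Z.shape[1])
    else:
        means, sds = constants
    model = ClusterModel(
        role=role,
        k=k,
        feature_means=means,
        feature_sds=sds,
        centroids=centroids,
        occupancy=occupancy,
        variance_explained=float(min(max(ve, 0.0), 1.0)),
    )
    return model, labels


def variance_explained(model: ClusterModel, Z: np.ndarray) -> float:
    """Between-cluster SS over total SS for ``Z`` under the model's centroids."""
    Z = np.asarray(Z, dtype=float)
    labels = _nearest(Z, model.centroids)
    wcss = float(((Z - model.centroids[labels]) ** 2).sum())
    tss = _total_ss(Z)
    if tss == 0:
        return 1.0
    return 1.0 - wcss / tss


def _nearest(Z: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """0-based index of the nearest centroid; ties go to the lowest index."""
    d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def assign(
    X: np.ndarray, model: ClusterModel, standardized: bool = False
) -> np.ndarray:
    """Map feature rows to 1-based state labels (nearest centroid).

    ``X`` is raw-scale unless ``standardized=True``; raw data are z-scored
    with the model's stored constants first.  Euclidean distance in
    standardized space; ties break to the lowest state label.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.centroids.shape[1]:
        raise StateError(
            f"expected {model.centroids.shape[1]} feature columns, got {X.shape}"
        )
    if not standardized:
        X = (X - model.feature_means) / model.feature_sds
    return _nearest(X, model.centroids) + 1


def prune_outlier_states(
    model: ClusterModel,
    labels: np.ndarray,
    min_share: float = 0.01,
    role: Role | None = None,
    subject_id: str = "",
) -> tuple[ClusterModel, StateSequence]:
    """Delete scarcely populated states and their blocks.

    States whose occupancy share over the model's training data is below
    ``min_share`` are removed from ``active_states``; every block labeled with
    a pruned state is deleted and the survivors are re-concatenated, so a
    transition may span a deletion.  Dropped positions are recorded.
    """
    labels = np.asarray(labels, dtype=int)
    total = int(model.occupancy.sum())
    shares = model.occupancy / total if total else np.zeros(model.k)
    active = tuple(s for s in range(1, model.k + 1) if shares[s - 1] >= min_share)
    if not active:
        raise StateError("pruning removed every state; lower min_share")
    keep = np.isin(labels, active)
    pruned_model = ClusterModel(
        role=model.role,
        k=model.k,
        feature_means=model.feature_means,
        feature_sds=model.feature_sds,
        centroids=model.centroids,
        occupancy=model.occupancy,
        variance_explained=model.variance_explained,
        active_states=active,
    )
    seq = StateSequence(
        labels=labels[keep],
        role=role or model.role,
        subject_id=subject_id,
        block_indices=np.nonzero(keep)[0],
        dropped_indices=np.nonzero(~keep)[0],
    )
    return pruned_model, seq
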