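"""Nearest-prototype classifier over byte-quantised feature vectors.

Emulates a capacity-limited associative memory: up to ``capacity`` labelled
vectors, one byte per element, classified by 1-nearest-neighbour under L1
(default) or Euclidean distance. When training data exceeds capacity a
class-stratified k-medoids selection keeps a representative subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureVector
from .signals import BEHAVIOURS, validate_behaviour

METRICS = ("l1", "euclidean")
_CDIST_NAME = {"l1": "cityblock", "euclidean": "euclidean"}

#: Additive range guard for degenerate (constant) features; they map to 0.
_DEGENERATE_EPS = 1e-12


@dataclass
class QuantisationScaling:
    """Per-feature (lo, hi) bounds mapping training values onto bytes 0-255."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.lo.shape != self.hi.shape:
            raise ValueError("lo/hi shape mismatch")
        if np.any(self.hi <= self.lo):
            raise ValueError("hi must exceed lo for every feature")

    @classmethod
    def fit(cls, X: np.ndarray) -> "QuantisationScaling":
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        degenerate = hi <= lo
        hi = np.where(degenerate, lo + _DEGENERATE_EPS, hi)
        return cls(lo=lo, hi=hi)


def quantise(vec: FeatureVector | np.ndarray, scaling: QuantisationScaling) -> np.ndarray:
    """Map a feature vector onto integer bytes: round(255·(x−lo)/(hi−lo)), clipped.

    Rounding is half-up, so the exact midpoint maps to 128. Out-of-range
    inputs saturate at 0/255 (hardware bytes clip).
    """
    x = vec.values if isinstance(vec, FeatureVector) else np.asarray(vec, dtype=float)
    scaled = 255.0 * (x - scaling.lo) / (scaling.hi - scaling.lo)
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.int64)


@dataclass
class PrototypeModel:
    """Byte-quantised labelled prototypes with a distance metric."""

    prototypes: np.ndarray  # (m, n_features) ints in [0, 255]
    labels: list[str]
    scaling: QuantisationScaling
    capacity: int = 128
    metric: str = "l1"

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=np.int64)
        if self.prototypes.ndim != 2:
            raise ValueError("prototypes must be a 2-D array")
        m = self.prototypes.shape[0]
        if not 0 < m <= self.capacity:
            raise ValueError(f"prototype count {m} outside (0, {self.capacity}]")
        if len(self.labels) != m:
            raise ValueError("labels/prototypes length mismatch")
        if self.prototypes.min() < 0 or self.prototypes.max() > 255:
            raise ValueError("prototype bytes outside [0, 255]")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        for label in self.labels:
            validate_behaviour(label)

    def __len__(self) -> int:
        return int(self.prototypes.shape[0])


def _class_quotas(counts: dict[str, int], capacity: int) -> dict[str, int]:
    """Largest-remainder proportional quotas, minimum 1 per class."""
    total = sum(counts.values())
    raw = {c: capacity * n / total for c, n in counts.items()}
    quota = {c: max(1, int(raw[c])) for c in counts}
    # distribute the remainder by descending fractional part, then class order
    while sum(quota.values()) < capacity:
        rem = sorted(
            (c for c in counts if quota[c] < counts[c]),
            key=lambda c: (-(raw[c] - int(raw[c])), list(counts).index(c)),
        )
        if not rem:
            break
        quota[rem[0]] += 1
    while sum(quota.values()) > capacity:
        over = max((c for c in counts if quota[c] > 1), key=lambda c: quota[c])
        quota[over] -= 1
    return {c: min(quota[c], counts[c]) for c in counts}


def _kmedoids(X: np.ndarray, k: int, metric: str, rng: np.random.Generator) -> np.ndarray:
    """Deterministic (given rng) k-medoids; returns selected row indices."""
    m = X.shape[0]
    if k >= m:
        return np.arange(m)
    D = cdist(X, X, metric=_CDIST_NAME[metric])
    medoids = np.sort(rng.choice(m, size=k, replace=False))
    for _ in range(100):
        assign = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(assign == j)
            if members.size == 0:
                continue
            sub = D[np.ix_(members, members)]
            new[j] = members[int(np.argmin(sub.sum(axis=0)))]
        new = np.sort(new)
        if np.array_equal(new, medoids):
            break
        medoids = new
    return medoids


def fit_prototypes(
    train: Sequence[tuple[FeatureVector, str]],
    capacity: int = 128,
    seed: int = 0,
    metric: str = "l1",
) -> PrototypeModel:
    """Fit scaling on the training range and select up to ``capacity`` prototypes.

    Under capacity, every training vector is stored. Over capacity, a
    class-stratified k-medoids (quota proportional to class frequency,
    minimum one per class) picks the stored subset. Deterministic given seed.
    """
    if not train:
        raise ValueError("empty training set")
    X = np.vstack([fv.values for fv, _ in train])
    labels = [validate_behaviour(lab) for _, lab in train]
    present = set(labels)
    missing = [b for b in BEHAVIOURS if b not in present]
    if missing:
        raise ValueError(f"class(es) absent from training data: {missing}")
    scaling = QuantisationScaling.fit(X)
    Q = np.vstack([quantise(x, scaling) for x in X])
    if len(train) <= capacity:
        return PrototypeModel(Q, labels, scaling, capacity=capacity, metric=metric)
    rng = np.random.default_rng(seed)
    counts = {b: labels.count(b) for b in BEHAVIOURS if b in present}
    quotas = _class_quotas(counts, capacity)
    keep: list[int] = []
    for b in BEHAVIOURS:
        if b not in quotas:
            continue
        idx = np.flatnonzero(np.array(labels) == b)
        chosen = _kmedoids(Q[idx], quotas[b], metric, rng)
        keep.extend(idx[chosen].tolist())
    keep = sorted(keep)
    return PrototypeModel(
        Q[keep], [labels[i] for i in keep], scaling, capacity=capacity, metric=metric
    )


def _distances(model: PrototypeModel, q: np.ndarray) -> np.ndarray:
    return cdist(q.reshape(1, -1), model.prototypes, metric=_CDIST_NAME[model.metric])[0]


def knn_predict(model: PrototypeModel, vec: FeatureVector | np.ndarray) -> str:
    """1-NN label of the quantised query; ties go to the earliest prototype."""
    if len(model) == 0:
        raise ValueError("empty model")
    q = quantise(vec, model.scaling)
    return model.labels[int(np.argmin(_distances(model, q)))]


def knn_predict_many(
    model: PrototypeModel, vecs: Sequence[FeatureVector] | np.ndarray
) -> list[str]:
    """Vectorised 1-NN over many queries (same tie rule as knn_predict)."""
    if len(model) == 0:
        raise ValueError("empty model")
    if len(vecs) and isinstance(vecs[0], FeatureVector):
        X = np.vstack([fv.values for fv in vecs])
    else:
        X = np.asarray(vecs, dtype=float)
    Q = np.vstack([quantise(x, model.scaling) for x in X])
    D = cdist(Q, model.prototypes, metric=_CDIST_NAME[model.metric])
    return [model.labels[i] for i in np.argmin(D, axis=1)]


def save_model(model: PrototypeModel, path: str | Path) -> None:
    """Write the model as JSON; floats round-trip bit-exactly via repr."""
    doc = {
        "capacity": model.capacity,
        "metric": model.metric,
        "scaling": {"lo": model.scaling.lo.tolist(), "hi": model.scaling.hi.tolist()},
        "prototypes": model.prototypes.tolist(),
        "labels": model.labels,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> PrototypeModel:
    doc = json.loads(Path(path).read_text())
    return PrototypeModel(
        prototypes=np.asarray(doc["prototypes"], dtype=np.int64),
        labels=list(doc["labels"]),
        scaling=QuantisationScaling(
            lo=np.asarray(doc["scaling"]["lo"]), hi=np.asarray(doc["scaling"]["hi"])
        ),
        capacity=int(doc["capacity"]),
        metric=doc["metric"],
    )
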