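"""Streaming three-centre 1-D k-means over the window activity index.

The state holds three scalar centres and their accumulated point counts.
Each incoming point is first classified by its nearest centre (using the
state from before the point's own contribution), then the winning centre is
updated with the exact running mean. Levels high/medium/low follow the
descending order of the centre values, recomputed every step.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

LEVELS: tuple[str, ...] = ("high", "medium", "low")


@dataclass
class CentroidState:
    """Three evolving centres with per-centre counts and an optional trace."""

    centres: np.ndarray
    counts: np.ndarray
    history: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.centres.shape != (3,) or self.counts.shape != (3,):
            raise ValueError("state requires exactly 3 centres and 3 counts")
        if not np.all(np.isfinite(self.centres)):
            raise ValueError("non-finite centre")
        if np.any(self.counts < 1):
            raise ValueError("counts must be >= 1 after initialisation")

    def levels_by_centre(self) -> list[str]:
        """Level name of each centre index (descending centre value)."""
        order = np.argsort(-self.centres, kind="stable")
        out = [""] * 3
        for rank, idx in enumerate(order):
            out[int(idx)] = LEVELS[rank]
        return out

    def sorted_centres(self) -> tuple[float, float, float]:
        """Centres ordered high, medium, low."""
        c = np.sort(self.centres)[::-1]
        return float(c[0]), float(c[1]), float(c[2])


def _batch_kmeans_1d(
    x: np.ndarray, k: int, rng: np.random.Generator, n_restarts: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's algorithm on scalars with seeded restarts; returns (centres, sizes)."""
    uniq = np.unique(x)
    best_inertia = np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    inits = [np.quantile(uniq, [1 / 6, 3 / 6, 5 / 6])]  # deterministic spread init
    for _ in range(n_restarts):
        inits.append(rng.choice(uniq, size=k, replace=False))
    for centres in inits:
        centres = np.array(sorted(centres), dtype=float)
        for _ in range(300):
            assign = np.argmin(np.abs(x[:, None] - centres[None, :]), axis=1)
            new = centres.copy()
            for j in range(k):
                pts = x[assign == j]
                if pts.size:
                    new[j] = pts.mean()
                else:  # re-seed an empty cluster at the farthest point
                    far = int(np.argmax(np.min(np.abs(x[:, None] - new[None, :]), axis=1)))
                    new[j] = x[far]
            if np.allclose(new, centres):
                break
            centres = new
        assign = np.argmin(np.abs(x[:, None] - centres[None, :]), axis=1)
        inertia = float(np.sum((x - centres[assign]) ** 2))
        if inertia < best_inertia - 1e-12:
            best_inertia = inertia
            sizes = np.array([int(np.sum(assign == j)) for j in range(k)])
            best = (centres, sizes)
    assert best is not None
    return best


def init_centroids(
    points: Sequence[float] | None = None,
    priors: Sequence[float] | None = None,
    seed: int = 0,
    n_init: int = 100,
    prior_count: int = 1,
) -> CentroidState:
    """Initialise the three centres from prior values or a leading subset.

    With ``priors``, the centres are taken verbatim and every count starts at
    ``prior_count``. With ``points``, batch k-means (k=3, seeded restarts) on
    the first ``n_init`` points sets the centres and counts.
    """
    if (points is None) == (priors is None):
        raise ValueError("provide exactly one of points or priors")
    if priors is not None:
        centres = np.asarray(priors, dtype=float)
        if centres.shape != (3,):
            raise ValueError("priors must be three values")
        return CentroidState(centres=centres, counts=np.full(3, prior_count))
    x = np.asarray(points, dtype=float)[:n_init]
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct values to initialise centroids")
    rng = np.random.default_rng(seed)
    centres, sizes = _batch_kmeans_1d(x, 3, rng)
    return CentroidState(centres=centres, counts=np.maximum(sizes, 1))


def km_step(state: CentroidState, z: float) -> tuple[str, CentroidState]:
    """Classify one point against the current centres, then update the winner.

    The level is decided before the update (predict-then-update). Distance
    ties go to the higher-valued centre. The winning centre moves by the
    exact running mean C <- C + (z - C) / (count + 1).
    """
    if not np.isfinite(z):
        raise ValueError(f"non-finite activity value {z!r}")
    d = np.abs(state.centres - z)
    candidates = np.flatnonzero(d == d.min())
    winner = int(candidates[np.argmax(state.centres[candidates])])
    level = state.levels_by_centre()[winner]
    new = CentroidState(
        centres=state.centres.copy(),
        counts=state.counts.copy(),
        history=list(state.history),
    )
    new.centres[winner] += (z - new.centres[winner]) / (new.counts[winner] + 1)
    new.counts[winner] += 1
    return level, new


def run_stream(
    state: CentroidState, zs: Sequence[float], track_history: bool = True
) -> tuple[list[str], CentroidState]:
    """Apply km_step sequentially; returns one level per point and final state."""
    cur = copy.deepcopy(state)
    levels: list[str] = []
    for z in zs:
        level, cur = km_step(cur, float(z))
        levels.append(level)
        if track_history:
            cur.history.append(cur.sorted_centres())
    return levels, cur


def write_trajectory_csv(state: CentroidState, path: str | Path) -> None:
    """Centre trajectory (step, C_high, C_medium, C_low) for drift diagnostics."""
    df = pd.DataFrame(state.history, columns=["C_high", "C_medium", "C_low"])
    df.insert(0, "step", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)
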