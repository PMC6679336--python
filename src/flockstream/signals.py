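"""Sensor-stream data model: IMU samples, windows, observation logs, CSV I/O.

Streams are array-backed (one row per sample) with strictly increasing
timestamps. Windowing advances at a fixed cadence from the stream start;
gaps larger than 1.5 sample periods split the stream into segments that are
windowed independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

#: The closed set of behaviour labels.
BEHAVIOURS: tuple[str, ...] = ("walking", "standing", "lying")

#: Deterministic tie-break priority for majority labelling (first wins).
DEFAULT_PRIORITY: tuple[str, ...] = ("walking", "standing", "lying")

IMU_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


def validate_behaviour(label: str) -> str:
    if label not in BEHAVIOURS:
        raise ValueError(f"unknown behaviour label {label!r}; expected one of {BEHAVIOURS}")
    return label


class ImuSample(NamedTuple):
    """One IMU row: time (s), acceleration (g), angular rate (deg/s)."""

    t: float
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float


@dataclass
class SampleStream:
    """Ordered tri-axial accelerometer + gyroscope samples at a nominal rate.

    Parameters
    ----------
    t : array of shape (n,)
        Timestamps in seconds, strictly increasing.
    acc : array of shape (n, 3)
        Acceleration per axis in g.
    gyro : array of shape (n, 3)
        Angular rate per axis in deg/s.
    rate_hz : float
        Nominal sampling rate (default 16).
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    rate_hz: float = 16.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.t.shape[0]
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"shape mismatch: t has {n} rows, acc {self.acc.shape}, gyro {self.gyro.shape}"
            )
        for name, arr in (("t", self.t), ("acc", self.acc), ("gyro", self.gyro)):
            if not np.all(np.isfinite(arr)):
                bad = int(np.argwhere(~np.isfinite(arr))[0][0])
                raise ValueError(f"non-finite value in {name} at row {bad}")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                raise ValueError(
                    f"timestamps not strictly increasing at row {bad} (t={self.t[bad]!r})"
                )
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration(self) -> float:
        """Span in seconds including one trailing sample period."""
        if len(self) == 0:
            return 0.0
        return float(self.t[-1] - self.t[0]) + 1.0 / self.rate_hz

    def sample(self, i: int) -> ImuSample:
        return ImuSample(self.t[i], *self.acc[i], *self.gyro[i])

    @classmethod
    def from_samples(cls, samples: Sequence[ImuSample], rate_hz: float = 16.0) -> "SampleStream":
        arr = np.asarray(samples, dtype=float).reshape(-1, 7)
        return cls(t=arr[:, 0], acc=arr[:, 1:4], gyro=arr[:, 4:7], rate_hz=rate_hz)


@dataclass
class Window:
    """A fixed-length contiguous slice of a stream used for one classification."""

    start_t: float
    acc: np.ndarray
    gyro: np.ndarray
    rate_hz: float = 16.0

    def __len__(self) -> int:
        return int(self.acc.shape[0])


@dataclass
class ObservationLog:
    """Ground-truth behaviour intervals ``(start_t, end_t, label)``.

    Intervals must be non-overlapping with ``end_t > start_t``; they are kept
    sorted by start time.
    """

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted((float(a), float(b), validate_behaviour(l)) for a, b, l in self.intervals)
        for a, b, _ in ivs:
            if not b > a:
                raise ValueError(f"interval ({a}, {b}) has non-positive duration")
        for (_, b0, _), (a1, _, _) in zip(ivs, ivs[1:]):
            if a1 < b0 - 1e-9:
                raise ValueError(f"intervals overlap at t={a1}")
        self.intervals = ivs

    @property
    def span(self) -> tuple[float, float]:
        if not self.intervals:
            raise ValueError("empty observation log")
        return self.intervals[0][0], self.intervals[-1][1]

    def overlap_durations(self, start: float, end: float) -> dict[str, float]:
        """Seconds of each behaviour intersecting ``[start, end)``."""
        out = {b: 0.0 for b in BEHAVIOURS}
        for a, b, label in self.intervals:
            lo, hi = max(a, start), min(b, end)
            if hi > lo:
                out[label] += hi - lo
        return out


def read_imu_csv(path: str | Path, rate_hz: float = 16.0) -> SampleStream:
    """Read an IMU CSV with header columns ``t,ax,ay,az,gx,gy,gz``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no samples") from None
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no samples")
    numeric = df[list(IMU_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ValueError(f"{path}: non-numeric cell in data row {row}")
    arr = numeric.to_numpy(dtype=float)
    dt = np.diff(arr[:, 0])
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"{path}: non-monotone timestamp at data row {row} (t={arr[row, 0]})")
    return SampleStream(t=arr[:, 0], acc=arr[:, 1:4], gyro=arr[:, 4:7], rate_hz=rate_hz)


def write_imu_csv(stream: SampleStream, path: str | Path) -> None:
    arr = np.column_stack([stream.t, stream.acc, stream.gyro])
    pd.DataFrame(arr, columns=list(IMU_COLUMNS)).to_csv(path, index=False)


def read_observation_csv(path: str | Path) -> ObservationLog:
    """Read an observation CSV with columns ``start_t,end_t,label``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in ("start_t", "end_t", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return ObservationLog(
        [(float(r.start_t), float(r.end_t), str(r.label)) for r in df.itertuples()]
    )


def write_observation_csv(log: ObservationLog, path: str | Path) -> None:
    pd.DataFrame(log.intervals, columns=["start_t", "end_t", "label"]).to_csv(path, index=False)


def _split_segments(stream: SampleStream) -> list[tuple[int, int]]:
    """Index ranges of contiguous runs; a gap > 1.5 sample periods splits."""
    n = len(stream)
    if n == 0:
        return []
    gap = 1.5 / stream.rate_hz
    breaks = np.flatnonzero(np.diff(stream.t) > gap) + 1
    edges = [0, *breaks.tolist(), n]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def segment_windows(
    stream: SampleStream, window_s: float = 7.0, cadence_s: float = 10.0
) -> list[Window]:
    """Cut fixed-cadence windows of ``window_s`` seconds from a stream.

    Windows are anchored to each contiguous segment's first sample and
    advance by exactly ``cadence_s``; trailing partial windows are dropped.
    A stream shorter than one window yields an empty list.
    """
    if cadence_s < window_s:
        raise ValueError("cadence_s must be >= window_s")
    spw = int(round(window_s * stream.rate_hz))
    stride = int(round(cadence_s * stream.rate_hz))
    if spw < 2:
        raise ValueError("window too short for the sampling rate")
    windows: list[Window] = []
    for lo, hi in _split_segments(stream):
        nseg = hi - lo
        if nseg < spw:
            continue
        for start in range(lo, hi - spw + 1, stride):
            windows.append(
                Window(
                    start_t=float(stream.t[start]),
                    acc=stream.acc[start : start + spw],
                    gyro=stream.gyro[start : start + spw],
                    rate_hz=stream.rate_hz,
                )
            )
    return windows


def align_labels(
    windows: Sequence[Window],
    log: ObservationLog,
    cadence_s: float = 10.0,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> list[str]:
    """Ground-truth label per window by majority overlap over ``cadence_s``.

    If a single behaviour covers the whole interval it is returned directly;
    otherwise the behaviour with the greatest overlap wins, ties broken by
    ``priority`` order.
    """
    rank = {b: i for i, b in enumerate(priority)}
    labels: list[str] = []
    uncovered: list[float] = []
    for w in windows:
        durs = log.overlap_durations(w.start_t, w.start_t + cadence_s)
        total = sum(durs.values())
        if total <= 0:
            uncovered.append(w.start_t)
            continue
        best = max(durs.items(), key=lambda kv: (kv[1], -rank[kv[0]]))
        labels.append(best[0])
    if uncovered:
        raise ValueError(
            f"{len(uncovered)} window(s) have no overlap with the observation log: "
            f"starts {uncovered[:5]}"
        )
    return labels
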