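"""Window feature extraction.

Four per-window variable series (acceleration magnitude, its signed first
difference, gyroscope magnitude, its signed first difference) are each
summarised by five characteristics (mean, population SD, IQR, population
Pearson kurtosis, min), giving a 20-element vector in variable-major order.
The mean acceleration magnitude additionally yields the activity index:
gravity-subtracted, floored at zero, and discretised into integer bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signals import ImuSample, SampleStream, Window, segment_windows

VARIABLES = ("amag", "amag_diff", "gmag", "gmag_diff")
CHARACTERISTICS = ("mean", "sd", "iqr", "kurtosis", "min")

#: Canonical 20-feature order: variable-major, characteristic-minor.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{v}_{c}" for v in VARIABLES for c in CHARACTERISTICS
)

#: Number of activity-index bins; values clip into [0, MAX_ACTIVITY_BIN].
MAX_ACTIVITY_BIN = 20


@dataclass
class FeatureVector:
    """20 summary features plus the raw and discretised activity index."""

    values: np.ndarray
    mean_amag_raw: float
    mean_amag: int
    window_start_t: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20,):
            raise ValueError(f"expected 20 feature values, got shape {self.values.shape}")
        if not (0 <= self.mean_amag <= MAX_ACTIVITY_BIN):
            raise ValueError(f"discrete activity index {self.mean_amag} out of range")
        if self.mean_amag_raw < 0:
            raise ValueError("raw activity index must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def acceleration_magnitude(sample: ImuSample) -> float:
    """Euclidean norm of the acceleration axes of one sample, in g."""
    return float(np.sqrt(sample.ax**2 + sample.ay**2 + sample.az**2))


def window_variables(window: Window) -> dict[str, np.ndarray]:
    """The four per-window series; difference series are one element shorter."""
    if len(window) < 2:
        raise ValueError("window must contain at least 2 samples")
    amag = np.linalg.norm(window.acc, axis=1)
    gmag = np.linalg.norm(window.gyro, axis=1)
    return {
        "amag": amag,
        "amag_diff": np.diff(amag),
        "gmag": gmag,
        "gmag_diff": np.diff(gmag),
    }


def _characterise(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, population SD, IQR, population kurtosis, min) of one series.

    Zero-variance series return kurtosis 0 by convention so vectors stay
    finite and quantisable.
    """
    mean = float(np.mean(x))
    sd = float(np.std(x))  # population (ddof=0)
    iqr = float(np.percentile(x, 75) - np.percentile(x, 25))
    if sd == 0.0:
        kurt = 0.0
    else:
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    return mean, sd, iqr, kurt, float(np.min(x))


def half_up(x: float) -> int:
    """Round half away from zero (for non-negative inputs: half up)."""
    return int(np.floor(x + 0.5))


def mean_amag(
    window: Window, gravity: float = 1.0, step: float = 0.1
) -> tuple[float, int]:
    """Raw and discretised activity index of a window.

    raw = max(mean(|acc|) - gravity, 0); discrete = clip(round(raw / step),
    0, 20). With acceleration in g the gravity constant defaults to 1.
    """
    amag = np.linalg.norm(window.acc, axis=1)
    raw = max(float(np.mean(amag)) - gravity, 0.0)
    discrete = int(np.clip(half_up(raw / step), 0, MAX_ACTIVITY_BIN))
    return raw, discrete


def feature_vector(
    window: Window, gravity: float = 1.0, step: float = 0.1
) -> FeatureVector:
    """Extract the 20-feature vector and activity index for one window."""
    series = window_variables(window)
    values = np.array(
        [v for name in VARIABLES for v in _characterise(series[name])], dtype=float
    )
    raw, discrete = mean_amag(window, gravity=gravity, step=step)
    return FeatureVector(
        values=values,
        mean_amag_raw=raw,
        mean_amag=discrete,
        window_start_t=window.start_t,
    )


def extract_features(
    stream: SampleStream,
    window_s: float = 7.0,
    cadence_s: float = 10.0,
    gravity: float = 1.0,
    step: float = 0.1,
) -> list[FeatureVector]:
    """Window a stream and extract one FeatureVector per window."""
    return [
        feature_vector(w, gravity=gravity, step=step)
        for w in segment_windows(stream, window_s=window_s, cadence_s=cadence_s)
    ]


def features_to_frame(fvs: Sequence[FeatureVector]) -> pd.DataFrame:
    rows = [
        {
            "window_start_t": fv.window_start_t,
            **fv.as_dict(),
            "mean_amag_raw": fv.mean_amag_raw,
            "mean_amag": fv.mean_amag,
        }
        for fv in fvs
    ]
    return pd.DataFrame(
        rows, columns=["window_start_t", *FEATURE_NAMES, "mean_amag_raw", "mean_amag"]
    )


def write_features_csv(fvs: Sequence[FeatureVector], path: str | Path) -> None:
    features_to_frame(fvs).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(path)
    return [
        FeatureVector(
            values=row[list(FEATURE_NAMES)].to_numpy(dtype=float),
            mean_amag_raw=float(row["mean_amag_raw"]),
            mean_amag=int(row["mean_amag"]),
            window_start_t=float(row["window_start_t"]),
        )
        for _, row in df.iterrows()
    ]
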