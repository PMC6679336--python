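import numpy as np
import pytest

from flockstream.signals import SampleStream, Window


def make_stream(duration_s: float = 20.0, rate_hz: float = 16.0, seed: int = 0) -> SampleStream:
    """A mildly noisy stream around gravity, strictly regular timestamps."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    acc = np.column_stack(
        [
            rng.normal(0.0, 0.01, n),
            rng.normal(0.0, 0.01, n),
            1.0 + rng.normal(0.0, 0.01, n),
        ]
    )
    gyro = rng.normal(0.0, 1.0, (n, 3))
    return SampleStream(t=t, acc=acc, gyro=gyro, rate_hz=rate_hz)


def make_window(acc: np.ndarray, gyro: np.ndarray | None = None, start_t: float = 0.0) -> Window:
    acc = np.asarray(acc, dtype=float)
    if gyro is None:
        gyro = np.zeros_like(acc)
    return Window(start_t=start_t, acc=acc, gyro=np.asarray(gyro, dtype=float), rate_hz=16.0)


def constant_window(ax: float, ay: float, az: float, n: int = 112) -> Window:
    return make_window(np.tile([ax, ay, az], (n, 1)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def stream():
    return make_stream()
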