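import numpy as np
import pytest

from catransient.signal_io import FEATURE_COLUMNS, Signal
from catransient.simulate import DEFAULT_PROFILES, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed dataset (all four classes, native sampling rates)."""
    cfg = SimConfig(class_counts={"LQT1": 5, "HCM": 5, "CPVT": 5, "WT": 5}, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture
def triangle_signal():
    """Noise-free triangular peak on a flat baseline: exact geometry known.

    fs = 10 Hz; rises linearly 0 -> 2 over samples 10..15, back to 0 over
    15..20; peak (a, c, g) = (10, 15, 20), area h*w/2 = 2*1/2 = 1.0.
    """
    x = np.zeros(31)
    x[10:16] = np.linspace(0.0, 2.0, 6)
    x[15:21] = np.linspace(2.0, 0.0, 6)
    return Signal("tri", x + 5.0, fs=10.0, label="UNKNOWN")


def make_feature_frame(rng, n_per_class, shift=0.0, labels=("LQT1", "WT")):
    """Gaussian feature-space classes, all ten variables shifted apart."""
    import pandas as pd

    frames = []
    for i, lbl in enumerate(labels):
        X = rng.normal(loc=i * shift, scale=1.0, size=(n_per_class, 10))
        df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        df["label"] = lbl
        df["abnormal"] = False
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def feature_frame_factory():
    return make_feature_frame
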