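"""Shared fixtures: small schedules, cohorts and network specs.

Everything is generated programmatically and seeded; the only packaged
data are the two reference accuracy tables shipped with the package.
"""

import numpy as np
import pytest

from fnirs_transfer.model import CnnSpec, LayerSpec
from fnirs_transfer.paradigm import build_schedule
from fnirs_transfer.pipeline import RunConfig, _preprocess_cohort
from fnirs_transfer.preprocess import EpochSet
from fnirs_transfer.simulate import make_cohort


@pytest.fixture(scope="session")
def default_schedule():
    return build_schedule()


@pytest.fixture(scope="session")
def short_schedule():
    """One session, three series — 186 s per subject, fast to simulate."""
    return build_schedule(sessions=1, series_per_session=3)


@pytest.fixture(scope="session")
def small_cohort_epochs(short_schedule):
    """Four preprocessed subjects on the short schedule (21 windows each)."""
    cfg = RunConfig()
    cohort = make_cohort(n_subjects=4, master_seed=42, schedule=short_schedule)
    return _preprocess_cohort(cfg, cohort)


@pytest.fixture(scope="session")
def subject_epochs(small_cohort_epochs):
    return small_cohort_epochs[0]


@pytest.fixture(scope="session")
def tiny_spec():
    """A miniature but topology-complete CNN for fast training tests.

    Input (12, 2, 30): conv1 (3,4)/(1,2) -> (10, 14, 4); conv2 (3,3)/(1,1)
    -> (8, 12, 6); pool 2x2 -> (4, 6, 6); dense 8; output 3.
    """
    return CnnSpec(
        layers=(
            LayerSpec("conv", filters=4, size=(3, 4), stride=(1, 2)),
            LayerSpec("conv", filters=6, size=(3, 3), stride=(1, 1)),
            LayerSpec("maxpool", size=(2, 2), stride=(2, 2)),
            LayerSpec("flatten"),
            LayerSpec("dense", units=8),
            LayerSpec("output", units=3, activation="softmax"),
        ),
        input_shape=(12, 2, 30),
        n_classes=3,
    )


def make_toy_epochs(n_per_class=12, n_channels=12, window=30, seed=0, separation=2.0):
    """Synthetic epoch set with linearly separable class means.

    Class c adds ``separation * c`` to the first third of the channels, so
    even a tiny CNN can reach high accuracy quickly.
    """
    rng = np.random.default_rng(seed)
    X, y, series = [], [], []
    for c in range(3):
        for i in range(n_per_class):
            ex = rng.normal(size=(n_channels, 2, window))
            ex[: n_channels // 3, :, :] += separation * c
            X.append(ex)
            y.append(c)
            series.append(c * 10 + i % 6)  # six single-class pseudo-series per class
    X = np.stack(X)
    y = np.asarray(y)
    return EpochSet(
        X=X,
        y=y,
        subject_ids=np.array(["toy"] * len(y)),
        series_idx=np.asarray(series),
        window_s=3.0,
        step_s=3.0,
        class_mode="3class",
        sampling_rate=10.0,
    )


@pytest.fixture()
def toy_epochs():
    return make_toy_epochs()
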