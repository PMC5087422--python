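"""Shared fixtures: synthetic trials and small deterministic signals."""

from dataclasses import replace

import numpy as np
import pytest

from gaitevents.preprocess import AccelTrace
from gaitevents.synthetic import GaitProfile, generate_trial, terrain_presets

FS = 148.15


@pytest.fixture(scope="session")
def noiseless_level_trial():
    """Deterministic level-ground walk: no noise, no cadence jitter."""
    profile = replace(terrain_presets()["level"], noise_sigma=0.0, cadence_jitter=0.0)
    return generate_trial(profile, duration=12.0, seed=1)


@pytest.fixture(scope="session")
def noisy_level_trial():
    profile = terrain_presets()["level"]  # default noise_sigma = 0.05
    return generate_trial(profile, duration=12.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_trace(axes: np.ndarray, fs: float = FS) -> AccelTrace:
    return AccelTrace.from_array(np.asarray(axes, dtype=float), fs=fs)


@pytest.fixture()
def random_trace(rng):
    return make_trace(rng.normal(0, 0.3, size=(400, 3)))
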