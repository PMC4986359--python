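"""Shared fixtures: a scaled-down session configuration for unit tests.

The small configuration keeps the full protocol structure (6 classes
including rest, blocked training, randomized testing order) but shortens
trials and repetition counts so every module test runs in seconds.
"""

import numpy as np
import pytest

from myodecode import (SynthConfig, envelope, generate_session,
                       make_ground_truth)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(trial_duration=1.0, rest_duration=0.5, reps_train=4,
                       reps_test=4, noise_sd=0.02, rep_variability=0.05,
                       seed=11)


@pytest.fixture(scope="session")
def truth(small_config):
    return make_ground_truth(small_config)


@pytest.fixture(scope="session")
def train_session(small_config, truth):
    return generate_session(small_config, truth, "training")


@pytest.fixture(scope="session")
def test_session(small_config, truth):
    return generate_session(small_config, truth, "testing")


@pytest.fixture(scope="session")
def train_env(train_session):
    return envelope(train_session, mode="offline")
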