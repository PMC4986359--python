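"""Minimum-jerk profile and the simulated online decoding loop."""

import numpy as np
import pytest

from myodecode import (OnlineConfig, OnlineDecoder, WindowSpec, fit_elm,
                       minimum_jerk, run_testing_phase, run_trial)
from myodecode.features import extract_emg_features
from myodecode.preprocess import envelope


def test_minimum_jerk_boundaries_and_symmetry():
    assert minimum_jerk(0.0) == 0.0
    assert minimum_jerk(1.0) == 1.0
    assert minimum_jerk(0.5) == pytest.approx(0.5)


def test_minimum_jerk_boundary_derivatives_vanish():
    """Velocity and acceleration are zero at both ends (analytic quintic)."""
    # d/dt (10t^3 - 15t^4 + 6t^5) = 30t^2 - 60t^3 + 30t^4
    vel = np.polynomial.Polynomial([0, 0, 30, -60, 30])
    acc = vel.deriv()
    for t in (0.0, 1.0):
        assert vel(t) == pytest.approx(0.0, abs=1e-12)
        assert acc(t) == pytest.approx(0.0, abs=1e-12)


def test_minimum_jerk_domain():
    with pytest.raises(ValueError):
        minimum_jerk(1.2)
    with pytest.raises(ValueError):
        minimum_jerk(-0.1)


class _FixedDecoder(OnlineDecoder):
    """Decoder stub emitting a prescribed label sequence (cycled)."""

    def __init__(self, labels, spec=WindowSpec()):
        self.spec = spec
        self._labels = list(labels)

    def predict_stream(self, stream, sample_rate):
        n = self.spec.n_windows(stream.shape[1])
        times = (self.spec.window + self.spec.step * np.arange(n)) / sample_rate
        preds = np.array([self._labels[i % len(self._labels)] for i in range(n)],
                         dtype=object)
        return times, preds


def test_oracle_decoder_timing():
    """Always-correct decoder: selection 0, completion = transition + hold."""
    cfg = OnlineConfig(debounce_steps=1, transition_duration=1.0,
                       hold_duration=0.5)
    dec = _FixedDecoder(["elbow_flexion"])
    stream = np.zeros((7, 3000))
    rec = run_trial(dec, stream, "elbow_flexion", 1000.0, cfg)
    assert rec.completed
    assert rec.selection_time == pytest.approx(0.0)
    assert rec.completion_time == pytest.approx(1.5, abs=0.011)
    assert rec.n_incorrect == 0
    assert rec.accuracy_fraction == 1.0


def test_never_correct_decoder_fails():
    cfg = OnlineConfig(debounce_steps=1, timeout=1.0)
    dec = _FixedDecoder(["shoulder_flexion"])
    rec = run_trial(dec, np.zeros((7, 5000)), "elbow_flexion", 1000.0, cfg)
    assert not rec.completed
    assert rec.completion_time is None
    assert rec.n_correct == 0


def test_selection_before_completion_and_count_bookkeeping():
    """Mixed predictions: selection <= completion; n+m = outputs in window."""
    seq = ["rest"] * 3 + ["shoulder_flexion"] * 2 + ["elbow_flexion"] * 400
    cfg = OnlineConfig(debounce_steps=2)
    dec = _FixedDecoder(seq)
    rec = run_trial(dec, np.zeros((7, 5000)), "elbow_flexion", 1000.0, cfg)
    assert rec.completed
    assert rec.selection_time <= rec.completion_time
    in_window = np.sum((rec.times >= rec.movement_onset_time - 1e-9)
                       & (rec.times <= rec.movement_onset_time
                          + rec.completion_time + 1e-9))
    assert rec.n_correct + rec.n_incorrect == in_window
    assert rec.n_incorrect == 2  # the two shoulder_flexion outputs


def test_debounce_filters_single_step_blips():
    """A 1-step wrong blip must not retarget the arm when debounce=3."""
    seq = (["elbow_flexion"] * 30 + ["shoulder_flexion"]
           + ["elbow_flexion"] * 400)
    rec_db = run_trial(_FixedDecoder(seq), np.zeros((7, 5000)),
                       "elbow_flexion", 1000.0,
                       OnlineConfig(debounce_steps=3))
    assert rec_db.completed
    # with debounce the blip costs nothing beyond its one wrong sample
    assert rec_db.n_incorrect == 1


def test_stepwise_ring_buffer_equivalence(train_env, truth):
    """Vectorized per-step features equal an explicit 100-sample ring buffer
    advanced 10 samples per step (causality by construction)."""
    feats = extract_emg_features(train_env)
    model = fit_elm(feats, n_hidden=30, seed=1)
    dec = OnlineDecoder(model, WindowSpec(), pathway="emg")
    stream = train_env.signal[:, :800]
    fast = dec.step_features(stream)
    spec = WindowSpec()
    slow = []
    for i in range(spec.n_windows(stream.shape[1])):
        buf = stream[:, i * spec.step: i * spec.step + spec.window]
        mavs = np.abs(buf).mean(axis=1)
        vars_ = (buf * buf).sum(axis=1) / (spec.window - 1)
        slow.append(np.concatenate([mavs, vars_]))
    np.testing.assert_allclose(fast, np.asarray(slow), atol=1e-12)


def test_testing_phase_record_bookkeeping(small_config, truth, test_session):
    """One record per motion trial, exactly reps_test per class, and
    selection <= completion for every completed trial."""
    train_env_local = envelope(test_session, mode="offline")  # any envelopes
    feats = extract_emg_features(train_env_local)
    model = fit_elm(feats, n_hidden=50, seed=2)
    dec = OnlineDecoder(model, WindowSpec(), pathway="emg")
    env = envelope(test_session, mode="causal")
    records = run_testing_phase(dec, env, OnlineConfig())
    assert len(records) == small_config.n_motion_classes * small_config.reps_test
    for label in small_config.motion_labels:
        assert sum(r.target_class == label for r in records) == small_config.reps_test
    for r in records:
        if r.completed and r.selection_time is not None:
            assert r.selection_time <= r.completion_time


def test_run_deterministic(test_session, truth):
    env = envelope(test_session, mode="causal")
    feats = extract_emg_features(envelope(test_session, mode="offline"))
    model = fit_elm(feats, n_hidden=20, seed=3)
    dec = OnlineDecoder(model, WindowSpec(), pathway="emg")
    r1 = run_testing_phase(dec, env, OnlineConfig())
    r2 = run_testing_phase(dec, env, OnlineConfig())
    for a, b in zip(r1, r2):
        assert (a.predictions == b.predictions).all()
        assert a.completion_time == b.completion_time


def test_testing_phase_requires_testing_session(train_session, truth):
    feats = extract_emg_features(envelope(train_session, mode="offline"))
    model = fit_elm(feats, n_hidden=10, seed=4)
    dec = OnlineDecoder(model, WindowSpec(), pathway="emg")
    with pytest.raises(ValueError):
        run_testing_phase(dec, train_session, OnlineConfig())
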