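"""Simulated real-time testing phase.

Causal envelopes are streamed through the decoder in 10 ms steps (a
100-sample ring buffer advanced 10 samples per step); each step produces a
class prediction that drives a virtual-arm state machine.  A prediction
must persist for a configurable number of consecutive steps (debouncing)
before it (re)targets a minimum-jerk transition of the arm; a trial is
complete once the arm sits at the commanded pose for the hold duration.

Per-trial records capture the full decoder output stream together with
movement onset, motion selection time (onset -> first correct prediction),
motion completion time (onset -> pose reached and held), and the
correct/incorrect sample counts that feed the online accuracy metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import elm as elm_mod
from .features import WindowSpec, _segment_windows
from .synergy import SynergyModel, project_online
from .synth import REST_LABEL, EmgSession

logger = logging.getLogger(__name__)


def minimum_jerk(t: float | np.ndarray) -> float | np.ndarray:
    """Minimum-jerk positional fraction: 10 t^3 - 15 t^4 + 6 t^5, t in [0, 1].

    The unique quintic with zero velocity and acceleration at both ends.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("t must lie in [0, 1]")
    out = t ** 3 * (10.0 - 15.0 * t + 6.0 * t ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class OnlineConfig:
    """Knobs of the simulated testing loop (times in seconds)."""

    debounce_steps: int = 5        # consecutive identical predictions to command
    transition_duration: float = 1.0
    hold_duration: float = 0.5
    timeout: float = 30.0
    rest_label: str = REST_LABEL


@dataclass
class VirtualArmState:
    """Pose state machine driven by debounced decoder commands."""

    current_pose: str = REST_LABEL
    in_transition: bool = False
    transition_target: str | None = None
    transition_progress: float = 0.0
    held_since: float | None = None

    def position_fraction(self) -> float:
        """Fractional position along the current transition (1 = settled)."""
        return minimum_jerk(min(self.transition_progress, 1.0)) \
            if self.in_transition else 1.0


@dataclass
class OnlineTrialRecord:
    """Decoder behavior over one commanded trial."""

    target_class: str
    times: np.ndarray              # decision times, s, relative to stream start
    predictions: np.ndarray        # decoder output per step
    movement_onset_time: float | None
    selection_time: float | None   # onset -> first target prediction
    completion_time: float | None  # onset -> pose settled at target + held
    completed: bool
    n_correct: int                 # n_i: correct outputs between onset and completion
    n_incorrect: int               # m_i

    @property
    def accuracy_fraction(self) -> float | None:
        tot = self.n_correct + self.n_incorrect
        return self.n_correct / tot if tot else None


class OnlineDecoder:
    """Streaming wrapper: envelope stream -> windowed features -> ELM class."""

    def __init__(self, model: elm_mod.ElmModel, spec: WindowSpec,
                 pathway: str = "emg",
                 synergy_model: SynergyModel | None = None):
        if pathway not in ("emg", "synergy"):
            raise ValueError(f"unknown pathway {pathway!r}")
        if pathway == "synergy" and synergy_model is None:
            raise ValueError("synergy pathway requires a SynergyModel")
        self.model = model
        self.spec = spec
        self.pathway = pathway
        self.synergy_model = synergy_model

    def step_features(self, stream: np.ndarray) -> np.ndarray:
        """Per-step feature vectors (n_steps x Z) for a (p x S) envelope stream.

        Step i uses exactly the samples in its 100-sample window (ending at
        sample ``window + i*step``), so the computation is causal.
        """
        spec = self.spec
        if stream.shape[1] < spec.window:
            return np.empty((0, self.model.hidden_weights.shape[1]))
        if self.pathway == "emg":
            wins = _segment_windows(stream, spec)  # p x n x window
            mavs = np.abs(wins).mean(axis=2)
            vars_ = (wins * wins).sum(axis=2) / (spec.window - 1)
            return np.vstack([mavs, vars_]).T
        coeffs = project_online(self.synergy_model, stream)  # k x S
        wins = _segment_windows(coeffs, spec)
        return wins.mean(axis=2).T

    def predict_stream(self, stream: np.ndarray, sample_rate: float
                       ) -> tuple[np.ndarray, np.ndarray]:
        """(decision times in s, predicted labels) for one stream."""
        feats = self.step_features(stream)
        n = feats.shape[0]
        times = (self.spec.window + self.spec.step * np.arange(n)) / sample_rate
        if n == 0:
            return times, np.empty(0, dtype=object)
        labels, _ = elm_mod.predict(self.model, feats)
        return times, labels


def run_trial(decoder: OnlineDecoder, stream: np.ndarray, target: str,
              sample_rate: float, config: OnlineConfig = OnlineConfig()
              ) -> OnlineTrialRecord:
    """Stream one commanded trial through the decoder and the virtual arm.

    ``stream`` is the causal envelope (channels x samples) from the trial
    start, including any trailing rest available before the next command.
    The arm starts at rest.  The trial completes when the arm's pose equals
    ``target`` continuously for the hold duration; it is abandoned at the
    timeout or when the stream ends.
    """
    times, preds = decoder.predict_stream(stream, sample_rate)
    dt = decoder.spec.step / sample_rate

    arm = VirtualArmState(current_pose=config.rest_label)
    cand: str | None = None
    cand_count = 0
    onset: float | None = None
    first_target: float | None = None
    completed = False
    completion_abs: float | None = None
    n_steps_used = len(times)

    for i, (t, pred) in enumerate(zip(times, preds)):
        if onset is None and pred != config.rest_label:
            onset = t
        if first_target is None and pred == target:
            first_target = t

        # debounce
        if pred == cand:
            cand_count += 1
        else:
            cand, cand_count = pred, 1
        commanded = cand if cand_count >= config.debounce_steps else None

        # advance any in-flight minimum-jerk transition
        if arm.in_transition:
            arm.transition_progress += dt / config.transition_duration
            if arm.transition_progress >= 1.0:
                arm.current_pose = arm.transition_target
                arm.in_transition = False
                arm.transition_target = None
                arm.transition_progress = 0.0
                arm.held_since = t

        # a sustained new command retargets the arm (progress restarts)
        if commanded is not None:
            goal = arm.transition_target if arm.in_transition else arm.current_pose
            if commanded != goal:
                arm.in_transition = True
                arm.transition_target = commanded
                arm.transition_progress = 0.0
                arm.held_since = None

        if (not arm.in_transition and arm.current_pose == target
                and arm.held_since is not None
                and t - arm.held_since >= config.hold_duration):
            completed = True
            completion_abs = t
            n_steps_used = i + 1
            break
        if t - times[0] > config.timeout:
            n_steps_used = i + 1
            break

    times = times[:n_steps_used]
    preds = preds[:n_steps_used]

    sel = None
    comp = None
    if onset is not None and first_target is not None:
        sel = first_target - onset
    if completed and onset is not None:
        comp = completion_abs - onset

    # correctness counts between onset and completion (or stream end)
    if onset is not None:
        hi = completion_abs if completed else times[-1] if len(times) else onset
        mask = (times >= onset) & (times <= hi)
        n_corr = int(np.sum(preds[mask] == target))
        n_inc = int(np.sum(mask)) - n_corr
    else:
        n_corr = n_inc = 0

    return OnlineTrialRecord(target_class=target, times=times,
                             predictions=preds, movement_onset_time=onset,
                             selection_time=sel, completion_time=comp,
                             completed=completed, n_correct=n_corr,
                             n_incorrect=n_inc)


def run_testing_phase(decoder: OnlineDecoder, session: EmgSession,
                      config: OnlineConfig = OnlineConfig()
                      ) -> list[OnlineTrialRecord]:
    """One OnlineTrialRecord per motion trial of a testing-phase session.

    ``session`` must already hold causal envelopes.  Each trial's stream
    runs from its start to the start of the next trial (motion plus the
    trailing rest period); the arm is reset to rest between trials, as each
    command starts from the rest pose.
    """
    if session.phase != "testing":
        raise ValueError(f"expected a testing-phase session, got {session.phase!r}")
    records = []
    trials = [t for t in session.trials if t.label != config.rest_label]
    for idx, trial in enumerate(trials):
        stop = trials[idx + 1].start if idx + 1 < len(trials) else session.n_samples
        stream = session.signal[:, trial.start:stop]
        records.append(run_trial(decoder, stream, trial.label,
                                 session.sample_rate, config))
    return records
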