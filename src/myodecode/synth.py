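"""Synthetic surface-EMG session generator with planted muscle-synergy structure.

The generator emulates a two-phase myoelectric decoding protocol: a training
phase in which each motion class (plus rest) is repeated in blocks, and a
testing phase in which motion classes are commanded in randomized order.
Multi-channel "raw" EMG is synthesized as a non-negative synergy mixture
(basis x class-specific activation time course) plus signed Gaussian noise,
so that the standard rectify-and-low-pass preprocessing stage remains
meaningful downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

logger = logging.getLogger(__name__)

#: Default motion-class labels: rest plus five shoulder/elbow motions.
DEFAULT_CLASS_LABELS = (
    "rest",
    "shoulder_flexion",
    "shoulder_protraction",
    "shoulder_retraction",
    "elbow_flexion",
    "elbow_extension",
)

REST_LABEL = "rest"


class ConfigurationError(ValueError):
    """Raised when a configuration or its pieces are mutually inconsistent."""


@dataclass(frozen=True)
class SynthConfig:
    """Session-generation parameters.

    Defaults mirror a standard upper-limb myoelectric protocol: 7 EMG
    channels sampled at 1 kHz, five motion classes plus rest, four underlying
    synergies, 3 s trials separated by 2 s of rest, 10 training and 20
    testing repetitions per motion class.
    """

    n_channels: int = 7
    sample_rate: float = 1000.0
    n_motion_classes: int = 5
    n_true_synergies: int = 4
    trial_duration: float = 3.0
    rest_duration: float = 2.0
    reps_train: int = 10
    reps_test: int = 20
    noise_sd: float = 0.05
    rep_variability: float = 0.1
    seed: int = 0
    class_labels: tuple[str, ...] = DEFAULT_CLASS_LABELS

    @property
    def n_classes(self) -> int:
        """Total number of classes, rest included."""
        return self.n_motion_classes + 1

    @property
    def motion_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.class_labels if l != REST_LABEL)

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_duration * self.sample_rate))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_duration * self.sample_rate))

    def validate(self) -> None:
        if self.n_true_synergies > self.n_channels:
            raise ConfigurationError(
                "n_true_synergies must not exceed n_channels "
                f"({self.n_true_synergies} > {self.n_channels})"
            )
        for name in ("n_channels", "sample_rate", "n_motion_classes",
                     "n_true_synergies", "trial_duration", "rest_duration",
                     "reps_train", "reps_test"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.noise_sd < 0 or self.rep_variability < 0:
            raise ConfigurationError("noise_sd and rep_variability must be >= 0")
        if len(self.class_labels) != self.n_classes:
            raise ConfigurationError(
                f"need {self.n_classes} class labels, got {len(self.class_labels)}"
            )
        if REST_LABEL not in self.class_labels:
            raise ConfigurationError(f"class_labels must include '{REST_LABEL}'")

    # rng streams: child 0 -> ground truth, 1 -> training, 2 -> testing
    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[stream])


@dataclass(frozen=True)
class GroundTruth:
    """Planted synergy structure used to synthesize a session.

    ``basis`` has unit-norm non-negative columns (channels x synergies);
    ``class_profiles`` maps each class label to a non-negative
    (synergies x trial-samples) activation time course.  The rest-class
    profile is all zeros; baseline noise is added at generation time.
    """

    basis: np.ndarray
    class_profiles: dict[str, np.ndarray]
    class_labels: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return self.basis.shape[0]

    @property
    def n_synergies(self) -> int:
        return self.basis.shape[1]

    def synergy_weights(self, label: str) -> np.ndarray:
        """Peak per-synergy activation amplitude for one class."""
        return self.class_profiles[label].max(axis=1)


@dataclass(frozen=True)
class Trial:
    """Half-open sample range [start, end) of one labeled repetition."""

    start: int
    end: int
    label: str
    rep: int


@dataclass
class EmgSession:
    """A labeled multi-channel EMG recording (channels x samples)."""

    signal: np.ndarray
    sample_rate: float
    trials: list[Trial]
    phase: str

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def trial_signal(self, trial: Trial) -> np.ndarray:
        return self.signal[:, trial.start:trial.end]

    def labels(self) -> list[str]:
        return [t.label for t in self.trials]

    def validate(self) -> None:
        prev_end = 0
        for t in self.trials:
            if not (0 <= t.start < t.end <= self.n_samples):
                raise ConfigurationError(f"trial {t} out of signal bounds")
            if t.start < prev_end:
                raise ConfigurationError(f"trial {t} overlaps its predecessor")
            prev_end = t.end

    # -- serialization ----------------------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (samples table, trials table) in the columnar layout."""
        t = np.arange(self.n_samples) / self.sample_rate
        cols = {"t": t}
        for i in range(self.n_channels):
            cols[f"ch{i + 1}"] = self.signal[i]
        samples = pd.DataFrame(cols)
        trials = pd.DataFrame(
            {
                "start": [tr.start for tr in self.trials],
                "end": [tr.end for tr in self.trials],
                "class": [tr.label for tr in self.trials],
                "rep": [tr.rep for tr in self.trials],
                "phase": self.phase,
            }
        )
        return samples, trials

    def save_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        samples, trials = self.to_frames()
        samples.to_csv(directory / "samples.csv", index=False)
        trials.to_csv(directory / "trials.csv", index=False)
        meta = {"sample_rate": self.sample_rate, "phase": self.phase,
                "n_channels": self.n_channels}
        (directory / "meta.json").write_text(json.dumps(meta, sort_keys=True))

    @classmethod
    def load_csv(cls, directory: str | Path) -> "EmgSession":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        samples = pd.read_csv(directory / "samples.csv")
        trials_df = pd.read_csv(directory / "trials.csv")
        chans = [c for c in samples.columns if c.startswith("ch")]
        signal = samples[chans].to_numpy().T
        trials = [
            Trial(int(r.start), int(r.end), str(r["class"]), int(r.rep))
            for _, r in trials_df.iterrows()
        ]
        return cls(signal=np.ascontiguousarray(signal),
                   sample_rate=float(meta["sample_rate"]),
                   trials=trials, phase=str(meta["phase"]))

    def save_hdf5(self, path: str | Path) -> None:
        """Lossless binary container (HDF5)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=self.signal)
            f.create_dataset("trial_start", data=[t.start for t in self.trials])
            f.create_dataset("trial_end", data=[t.end for t in self.trials])
            f.create_dataset("trial_rep", data=[t.rep for t in self.trials])
            f.create_dataset(
                "trial_class",
                data=np.array([t.label for t in self.trials], dtype="S64"),
            )
            f.attrs["sample_rate"] = self.sample_rate
            f.attrs["phase"] = self.phase

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "EmgSession":
        import h5py

        with h5py.File(path, "r") as f:
            signal = f["signal"][()]
            trials = [
                Trial(int(s), int(e), lbl.decode(), int(r))
                for s, e, lbl, r in zip(
                    f["trial_start"][()], f["trial_end"][()],
                    f["trial_class"][()], f["trial_rep"][()]
                )
            ]
            return cls(signal=signal, sample_rate=float(f.attrs["sample_rate"]),
                       trials=trials, phase=str(f.attrs["phase"]))


def _pattern_vectors(k: int, n_motion: int) -> np.ndarray:
    """Deterministic, mutually distinct non-negative unit vectors in R^k.

    The first k classes get one-hot codes; the (k+1)-th gets the uniform
    code (cosine 1/sqrt(k) with every one-hot, the best-separated fifth
    direction in the non-negative orthant); further classes get normalized
    sums of adjacent pairs, then triples, cycling as needed.
    """
    eye = np.eye(k)
    patterns = [eye[c] for c in range(min(k, n_motion))]
    if len(patterns) < n_motion:
        patterns.append(np.ones(k) / np.sqrt(k))
    width = 2
    while len(patterns) < n_motion:
        for c in range(k):
            if len(patterns) >= n_motion:
                break
            v = np.zeros(k)
            for j in range(width):
                v[(c + j) % k] = 1.0
            patterns.append(v / np.linalg.norm(v))
        width += 1
    return np.asarray(patterns[:n_motion])


def make_ground_truth(config: SynthConfig, separation: float = 0.85) -> GroundTruth:
    """Draw a random planted synergy basis and per-class activation profiles.

    ``separation`` in [0, 1] controls how far apart the per-class synergy
    weight vectors are: 0 makes every motion class share one activation
    pattern (chance-level decoding), values near 1 give near-orthogonal
    class codes.  Each motion class activates every synergy through a
    tapered-plateau (Tukey) time course spanning the trial, weighted by the
    class code, which resembles a sustained contraction with smooth onset
    and offset.
    """
    config.validate()
    if separation < 0:
        raise ConfigurationError("separation must be >= 0")
    rng = config._rng(0)
    p, k = config.n_channels, config.n_true_synergies

    # Group-sparse basis: each synergy recruits its own muscle group (round-
    # robin channel assignment) with strong random loadings there and a small
    # baseline loading elsewhere.  Dense all-positive columns would be nearly
    # collinear, which is neither physiological nor identifiable.
    groups: list[list[int]] = [[] for _ in range(k)]
    for ch in range(p):
        groups[ch % k].append(ch)
    basis = np.empty((p, k))
    for s in range(k):
        col = 0.05 * rng.uniform(0.0, 1.0, p)
        col[groups[s]] = rng.uniform(0.5, 1.0, len(groups[s]))
        basis[:, s] = col / np.linalg.norm(col)

    T = config.trial_samples
    envelope_shape = tukey(T, alpha=0.3)

    u = np.ones(k) / np.sqrt(k)
    patterns = _pattern_vectors(k, config.n_motion_classes)
    profiles: dict[str, np.ndarray] = {REST_LABEL: np.zeros((k, T))}
    for c, label in enumerate(config.motion_labels):
        w = (1.0 - separation) * u + separation * patterns[c]
        w = w / np.linalg.norm(w)
        profiles[label] = np.outer(w, envelope_shape)
    return GroundTruth(basis=basis, class_profiles=profiles,
                       class_labels=config.class_labels)


def _trial_order(config: SynthConfig, phase: str,
                 rng: np.random.Generator) -> list[tuple[str, int]]:
    if phase == "training":
        # blocked: all repetitions of a class are consecutive
        order = []
        for label in config.class_labels:
            order.extend((label, r) for r in range(config.reps_train))
        return order
    if phase == "testing":
        labels = np.repeat(config.motion_labels, config.reps_test)
        perm = rng.permutation(len(labels))
        labels = labels[perm]
        counts: dict[str, int] = {}
        order = []
        for label in labels:
            counts[label] = counts.get(label, 0)
            order.append((str(label), counts[label]))
            counts[label] += 1
        return order
    raise ConfigurationError(f"unknown phase {phase!r}")


def generate_session(config: SynthConfig, truth: GroundTruth,
                     phase: str) -> EmgSession:
    """Synthesize one labeled session for ``phase`` ("training"|"testing").

    Layout: an initial rest period, then each trial followed by a rest
    period.  Trial signal is ``basis @ (scale * profile)`` with a
    per-repetition amplitude scale ``1 + rep_variability * z``; zero-mean
    Gaussian noise with sd ``noise_sd`` is added everywhere, so rest periods
    carry baseline noise only.
    """
    config.validate()
    if truth.basis.shape != (config.n_channels, config.n_true_synergies):
        raise ConfigurationError(
            f"ground-truth basis shape {truth.basis.shape} does not match "
            f"config ({config.n_channels}, {config.n_true_synergies})"
        )
    for label, prof in truth.class_profiles.items():
        if prof.shape != (config.n_true_synergies, config.trial_samples):
            raise ConfigurationError(
                f"profile for class {label!r} has shape {prof.shape}, expected "
                f"({config.n_true_synergies}, {config.trial_samples})"
            )

    rng = config._rng(1 if phase == "training" else 2)
    order = _trial_order(config, phase, rng)

    T, R = config.trial_samples, config.rest_samples
    total = R + len(order) * (T + R)
    clean = np.zeros((config.n_channels, total))
    trials: list[Trial] = []
    pos = R
    for label, rep in order:
        scale = max(0.0, 1.0 + config.rep_variability * rng.standard_normal())
        clean[:, pos:pos + T] = truth.basis @ (scale * truth.class_profiles[label])
        trials.append(Trial(pos, pos + T, label, rep))
        pos += T + R

    signal = clean
    if config.noise_sd > 0:
        signal = clean + config.noise_sd * rng.standard_normal(clean.shape)

    session = EmgSession(signal=signal, sample_rate=config.sample_rate,
                         trials=trials, phase=phase)
    session.validate()
    return session
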