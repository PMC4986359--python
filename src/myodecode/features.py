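"""Sliding-window time-domain feature extraction.

Per 100-sample window (advanced 10 samples, i.e. 90-sample overlap, one
output every 10 ms at 1 kHz) and per channel, two features are computed:

* MAV, the mean absolute value ``(1/N) sum |x_n|``;
* VAR, the uncentered second moment ``(1/(N-1)) sum x_n^2``.

Note VAR is deliberately a mean-square without mean subtraction — for
rectified envelopes it acts as a signal-power feature.  With p channels the
feature vector is 2p-dimensional (all MAVs first, then all VARs, channel
order preserved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .synth import ConfigurationError, EmgSession

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in samples (100 ms window / 10 ms step at 1 kHz)."""

    window: int = 100
    step: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ConfigurationError(
                f"need 0 < step <= window, got step={self.step} window={self.window}"
            )

    def n_windows(self, n_samples: int) -> int:
        """Number of complete windows in a segment of ``n_samples``."""
        if n_samples < self.window:
            return 0
        return (n_samples - self.window) // self.step + 1


@dataclass
class FeatureMatrix:
    """Windowed feature vectors: ``values`` is (feature dim x n_windows)."""

    values: np.ndarray
    labels: np.ndarray
    window_times: np.ndarray  # absolute end-sample index of each window
    feature_kind: str  # {"emg", "synergy"}
    feature_names: list[str] = field(default_factory=list)
    #: index of the source trial per window; lets evaluation split at trial
    #: granularity so windows of one repetition never leak across the split
    trial_ids: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"f{i}" for i in range(self.dim)]
        df = pd.DataFrame(self.values.T, columns=names)
        df.insert(0, "window_end", self.window_times)
        df["label"] = self.labels
        return df

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def mav(window_values: np.ndarray) -> float:
    """Mean absolute value of one window."""
    x = np.asarray(window_values, dtype=float)
    if x.size == 0:
        raise ValueError("MAV of an empty window is undefined")
    return float(np.mean(np.abs(x)))


def var(window_values: np.ndarray) -> float:
    """Uncentered variance: sum of squares divided by N-1 (no mean subtraction)."""
    x = np.asarray(window_values, dtype=float)
    if x.size < 2:
        raise ValueError("VAR needs at least 2 samples")
    return float(np.sum(x * x) / (x.size - 1))


def _segment_windows(seg: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """(channels x n_windows x window) view of complete windows in a segment."""
    return sliding_window_view(seg, spec.window, axis=1)[:, ::spec.step, :]


def extract_emg_features(session: EmgSession, spec: WindowSpec = WindowSpec()
                         ) -> FeatureMatrix:
    """Per-window MAV and VAR for every channel of every labeled trial.

    Windows never straddle trial boundaries; a trial shorter than one
    window is skipped with a warning.  Feature layout: MAV of channels
    1..p, then VAR of channels 1..p.
    """
    p = session.n_channels
    blocks, labels, times, trial_ids = [], [], [], []
    for ti, trial in enumerate(session.trials):
        seg = session.trial_signal(trial)
        nw = spec.n_windows(seg.shape[1])
        if nw == 0:
            logger.warning("trial %s shorter than window (%d < %d), skipped",
                           trial, seg.shape[1], spec.window)
            continue
        wins = _segment_windows(seg, spec)  # p x nw x window
        mavs = np.abs(wins).mean(axis=2)
        vars_ = (wins * wins).sum(axis=2) / (spec.window - 1)
        blocks.append(np.vstack([mavs, vars_]))
        labels.extend([trial.label] * nw)
        times.extend(trial.start + spec.window + spec.step * np.arange(nw))
        trial_ids.extend([ti] * nw)
    if not blocks:
        raise ValueError("no trial long enough for a single window")
    names = [f"mav_ch{i + 1}" for i in range(p)] + [f"var_ch{i + 1}" for i in range(p)]
    return FeatureMatrix(values=np.hstack(blocks),
                         labels=np.asarray(labels),
                         window_times=np.asarray(times),
                         feature_kind="emg", feature_names=names,
                         trial_ids=np.asarray(trial_ids))
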