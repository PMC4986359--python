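"""EMG envelope extraction: full-wave rectification + 10 Hz low-pass.

Two variants are provided: ``offline`` (zero-phase forward-backward
filtering, used to prepare training data) and ``causal`` (single-pass,
usable sample-by-sample, used by the online simulator since a real-time
loop cannot be zero-phase).  Filter undershoot is clipped at zero so the
result is a valid non-negative envelope.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import signal as sps

from .synth import ConfigurationError, EmgSession

#: Alias: an EnvelopeSession is an EmgSession whose signal is non-negative.
EnvelopeSession = EmgSession

DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_ORDER = 4


def envelope_array(x: np.ndarray, sample_rate: float, mode: str = "offline",
                   cutoff: float = DEFAULT_CUTOFF_HZ,
                   order: int = DEFAULT_ORDER) -> np.ndarray:
    """Rectify then low-pass one (channels x samples) array."""
    if cutoff >= sample_rate / 2:
        raise ConfigurationError(
            f"cutoff {cutoff} Hz must be below Nyquist ({sample_rate / 2} Hz)"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    rectified = np.abs(x)
    if mode == "offline":
        filtered = sps.sosfiltfilt(sos, rectified, axis=-1)
    elif mode == "causal":
        filtered = sps.sosfilt(sos, rectified, axis=-1)
    else:
        raise ConfigurationError(f"unknown envelope mode {mode!r}")
    return np.clip(filtered, 0.0, None)


def envelope(session: EmgSession, mode: str = "offline",
             cutoff: float = DEFAULT_CUTOFF_HZ,
             order: int = DEFAULT_ORDER) -> EnvelopeSession:
    """Return a new session whose signal is the EMG envelope.

    The trial table and sample rate are preserved unchanged.
    """
    env = envelope_array(session.signal, session.sample_rate, mode=mode,
                         cutoff=cutoff, order=order)
    return EmgSession(signal=env, sample_rate=session.sample_rate,
                      trials=list(session.trials), phase=session.phase)
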