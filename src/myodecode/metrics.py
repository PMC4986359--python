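"""Offline and online decoder performance statistics.

* offline accuracy: percent of correctly classified held-out windows;
* per-class online accuracy: mean over *completed* trials of the per-trial
  fraction of decoder outputs (between movement onset and completion)
  matching the commanded class, in percent;
* motion selection / completion time summaries;
* learning trend: exponential fit ``y(x) = a e^{-bx} + c`` of completion
  time vs repetition number (positive b = completion times decaying, i.e.
  learning; the raw fitted b is reported and the sign convention is up to
  the caller's tabulation);
* variability: repetitions time-normalized and resampled to a common 200
  samples, per-channel per-time-point population standard deviation across
  repetitions, averaged over channels and time points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .online_sim import OnlineTrialRecord

logger = logging.getLogger(__name__)

RESAMPLE_POINTS = 200


def offline_accuracy(predicted: np.ndarray, actual: np.ndarray) -> float:
    """100 x correct / total."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.size == 0 or predicted.shape != actual.shape:
        raise ValueError("predicted and actual must be non-empty and equal length")
    return float(100.0 * np.mean(predicted == actual))


def online_accuracy(records: Sequence[OnlineTrialRecord],
                    target_class: str) -> float | None:
    """Mean per-trial correct-output fraction over completed trials, percent.

    Incomplete trials are excluded.  Returns None (reported as missing,
    never as 0) if the class has no completed trial with decoder output.
    """
    fracs = []
    for r in records:
        if r.target_class != target_class or not r.completed:
            continue
        f = r.accuracy_fraction
        if f is None:
            logger.warning("completed trial for %s has no decoder outputs "
                           "between onset and completion; excluded", target_class)
            continue
        fracs.append(f)
    if not fracs:
        return None
    return float(100.0 * np.mean(fracs))


def confusion_matrix(actual: np.ndarray, predicted: np.ndarray,
                     class_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Row-normalized confusion matrix in percent (rows = actual class)."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.size == 0:
        raise ValueError("empty input")
    if class_order is None:
        class_order = sorted(set(map(str, actual)) | set(map(str, predicted)))
    m = len(class_order)
    idx = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((m, m))
    for a, p in zip(actual, predicted):
        counts[idx[str(a)], idx[str(p)]] += 1
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row > 0, 100.0 * counts / row, np.nan)
    return pd.DataFrame(norm, index=list(class_order), columns=list(class_order))


@dataclass
class LearningTrend:
    """Fit of completion time vs repetition to ``a e^{-bx} + c``."""

    a: float
    b: float
    c: float
    residual_norm: float
    converged: bool
    degenerate: bool = False   # near-constant data: b unidentifiable
    message: str = ""


def fit_learning_trend(completion_times: np.ndarray,
                       x: np.ndarray | None = None) -> LearningTrend:
    """Nonlinear least-squares exponential-decay fit of completion times.

    Multi-start trust-region fit (3 fixed starts) with b bounded in
    [-5, 5]; the problem is ill-conditioned for near-constant data, in
    which case the fit is flagged degenerate rather than trusted.
    """
    y = np.asarray(completion_times, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 points to fit the trend")
    if x is None:
        x = np.arange(1, y.size + 1, dtype=float)
    x = np.asarray(x, dtype=float)

    spread = y.max() - y.min()
    if spread <= 1e-12 * max(1.0, abs(float(y.mean()))):
        return LearningTrend(a=0.0, b=0.0, c=float(y.mean()), residual_norm=0.0,
                             converged=True, degenerate=True,
                             message="constant data: b unidentifiable")

    def resid(p):
        a, b, c = p
        return a * np.exp(-b * x) + c - y

    best = None
    for b0 in (0.05, 0.5, 2.0):
        p0 = np.array([y[0] - y[-1] if abs(y[0] - y[-1]) > 1e-12 else spread,
                       b0, y[-1]])
        try:
            sol = least_squares(resid, p0,
                                bounds=([-np.inf, -5.0, -np.inf],
                                        [np.inf, 5.0, np.inf]),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as exc:  # pragma: no cover - optimizer failure path
            logger.warning("learning-trend start b0=%g failed: %s", b0, exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return LearningTrend(a=np.nan, b=np.nan, c=np.nan, residual_norm=np.nan,
                             converged=False, message="all starts failed")
    a, b, c = best.x
    rnorm = float(np.linalg.norm(resid(best.x)))
    degenerate = abs(a) < 1e-3 * max(spread, 1e-12)
    return LearningTrend(a=float(a), b=float(b), c=float(c),
                         residual_norm=rnorm, converged=bool(best.success),
                         degenerate=degenerate,
                         message="" if not degenerate else
                         "amplitude ~ 0: b poorly identified")


def resample_trace(trace: np.ndarray, n_points: int = RESAMPLE_POINTS
                   ) -> np.ndarray:
    """Linearly resample a (channels x T) trace onto normalized time [0, 1]."""
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    T = trace.shape[1]
    if T < 2:
        raise ValueError("trace needs at least 2 samples")
    src = np.linspace(0.0, 1.0, T)
    dst = np.linspace(0.0, 1.0, n_points)
    return np.vstack([np.interp(dst, src, ch) for ch in trace])


def variability(trial_envelopes: Sequence[np.ndarray],
                n_points: int = RESAMPLE_POINTS) -> float:
    """Mean across channels and time of the across-repetition SD.

    Each repetition's (channels x T_rep) envelope trace is time-normalized
    and resampled to ``n_points``; the standard deviation uses the
    population divisor (the number of repetitions).
    """
    if len(trial_envelopes) < 2:
        raise ValueError("variability needs at least 2 repetitions")
    stacked = np.stack([resample_trace(tr, n_points) for tr in trial_envelopes])
    sigma = stacked.std(axis=0, ddof=0)  # population form
    return float(sigma.mean())


def time_summary(records: Sequence[OnlineTrialRecord], target_class: str,
                 attr: str) -> tuple[float | None, float | None]:
    """(mean, sd) of a per-trial time over completed trials of one class."""
    vals = [getattr(r, attr) for r in records
            if r.target_class == target_class and r.completed
            and getattr(r, attr) is not None]
    if not vals:
        return None, None
    arr = np.asarray(vals, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


def completion_rate(records: Sequence[OnlineTrialRecord],
                    target_class: str | None = None) -> float:
    """Percent of trials (optionally of one class) that completed."""
    sel = [r for r in records
           if target_class is None or r.target_class == target_class]
    if not sel:
        raise ValueError("no trials")
    return float(100.0 * np.mean([r.completed for r in sel]))
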