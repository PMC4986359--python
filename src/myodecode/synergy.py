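"""Muscle-synergy extraction by non-negative matrix factorization.

Training-phase envelopes X (channels x samples) are factored as X = A Y + E
with A >= 0 the synergy basis and Y >= 0 the activation coefficients, via
alternating non-negative least squares (each factor update solves its
convex NNLS subproblem exactly, so the Frobenius objective is
non-increasing).  The number of synergies is chosen from the cumulative
explained-variance profile: the smallest k that explains at least 90 % of
the (uncentered) variance and beyond which the gain per added synergy drops
below 5 %.

At test time the per-sample synergy coefficients are obtained by the linear
projection ``pinv(A) @ x`` — the least-squares decoder of the fitted basis.
Projected coefficients are *not* clipped and may be slightly negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .features import FeatureMatrix, WindowSpec, _segment_windows
from .synth import EmgSession

logger = logging.getLogger(__name__)

_RIDGE = 1e-12  # conditioning ridge on the normal equations


# ---------------------------------------------------------------------------
# fast combinatorial NNLS (multiple right-hand sides sharing one left matrix)
# ---------------------------------------------------------------------------

def _cssls(CtC: np.ndarray, CtB: np.ndarray,
           passive: np.ndarray | None = None) -> np.ndarray:
    """Solve the normal equations restricted to per-column passive sets.

    Columns sharing the same passive set are solved together (combinatorial
    grouping), which is what makes the many-right-hand-side NNLS fast.
    """
    if passive is None:
        return np.linalg.solve(CtC, CtB)
    k, n = CtB.shape
    K = np.zeros((k, n))
    codes = (1 << np.arange(k)) @ passive
    for code in np.unique(codes):
        if code == 0:
            continue
        cols = np.nonzero(codes == code)[0]
        pset = passive[:, cols[0]]
        sub = np.linalg.solve(CtC[np.ix_(pset, pset)], CtB[np.ix_(pset, cols)])
        K[np.ix_(pset, cols)] = sub
    return K


def nnls_multi(C: np.ndarray, B: np.ndarray, ridge: float = _RIDGE) -> np.ndarray:
    """``argmin_K ||C K - B||_F  s.t.  K >= 0`` for many columns at once.

    Active-set NNLS with combinatorial column grouping; a tiny ridge keeps
    the grouped normal equations well conditioned.  Columns that fail to
    converge within the iteration cap (degenerate systems) fall back to a
    per-column dense NNLS solve.
    """
    C = np.asarray(C, dtype=float)
    B = np.asarray(B, dtype=float)
    k = C.shape[1]
    n = B.shape[1]
    CtC = C.T @ C + ridge * np.eye(k)
    CtB = C.T @ B

    tol = 1e-12 * max(1.0, float(np.abs(CtB).max()))
    K = _cssls(CtC, CtB)
    P = K > 0
    K[~P] = 0.0
    D = K.copy()
    Fcols = np.nonzero(~P.all(axis=0))[0]

    max_outer = 5 * k + 10
    outer = 0
    while Fcols.size and outer < max_outer:
        outer += 1
        K[:, Fcols] = _cssls(CtC, CtB[:, Fcols], P[:, Fcols])
        # inner loop: back off along the segment to the last feasible point
        inner = 0
        H = Fcols[np.any((K[:, Fcols] < -tol) & P[:, Fcols], axis=0)]
        while H.size and inner < 10 * k + 10:
            inner += 1
            Kh, Dh, Ph = K[:, H], D[:, H], P[:, H]
            neg = (Kh < -tol) & Ph
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = np.where(neg, Dh / (Dh - Kh), np.inf)
            alpha = ratios.min(axis=0)
            Kh = Dh + alpha[None, :] * (Kh - Dh)
            hit = ratios <= alpha[None, :] + 1e-12
            Ph = Ph & ~hit
            Kh[~Ph] = 0.0
            P[:, H], D[:, H] = Ph, Kh
            K[:, H] = _cssls(CtC, CtB[:, H], Ph)
            H = H[np.any((K[:, H] < -tol) & P[:, H], axis=0)]
        K[:, Fcols] = np.where(P[:, Fcols], K[:, Fcols], 0.0)
        D[:, Fcols] = np.maximum(K[:, Fcols], 0.0)
        # KKT check: any active variable with positive gradient re-enters
        W = CtB[:, Fcols] - CtC @ K[:, Fcols]
        W = np.where(P[:, Fcols], -np.inf, W)
        best = W.max(axis=0)
        not_opt = best > tol
        enter_cols = Fcols[not_opt]
        if enter_cols.size:
            enter_rows = W[:, not_opt].argmax(axis=0)
            P[enter_rows, enter_cols] = True
        Fcols = enter_cols

    if Fcols.size:  # rare: finish stubborn columns one at a time
        logger.debug("nnls_multi fallback for %d columns", Fcols.size)
        for j in Fcols:
            K[:, j] = _scipy_nnls(C, B[:, j])[0]
    return np.maximum(K, 0.0)


# ---------------------------------------------------------------------------
# NMF by alternating NNLS
# ---------------------------------------------------------------------------

class NmfResult(NamedTuple):
    basis: np.ndarray          # p x k, non-negative
    coefficients: np.ndarray   # k x q, non-negative
    residual_fro: float        # ||X - A Y||_F
    objective_history: np.ndarray  # squared Frobenius objective per iteration
    n_iter: int


def nmf_fit(X: np.ndarray, k: int, max_iter: int = 200, tol: float = 1e-5,
            seed: int = 0) -> NmfResult:
    """Factor non-negative ``X`` (p x q) into A (p x k) and Y (k x q).

    Alternating exact NNLS updates; stops when the relative decrease of the
    squared-Frobenius objective falls below ``tol`` or after ``max_iter``
    alternations.  Seeded random uniform initialization of A.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("NMF input must be non-negative")
    p, q = X.shape
    if not 1 <= k <= p:
        raise ValueError(f"need 1 <= k <= {p}, got k={k}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), np.finfo(float).tiny) / k)
    A = rng.uniform(0.1, 1.0, size=(p, k)) * scale

    history = []
    prev = np.inf
    it = 0
    Y = np.zeros((k, q))
    for it in range(1, max_iter + 1):
        Y = nnls_multi(A, X)
        A = nnls_multi(Y.T, X.T).T
        # guard collapsed synergies so the next NNLS stays well posed
        dead = ~A.any(axis=0)
        if dead.any():
            A[:, dead] = rng.uniform(0.1, 1.0, size=(p, int(dead.sum()))) * scale
        obj = float(np.linalg.norm(X - A @ Y, "fro") ** 2)
        history.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(prev, np.finfo(float).tiny):
            break
        prev = obj
    residual = float(np.linalg.norm(X - A @ Y, "fro"))
    return NmfResult(A, Y, residual, np.asarray(history), it)


def explained_variance_profile(X: np.ndarray, max_k: int | None = None,
                               seed: int = 0, centered: bool = False,
                               max_iter: int = 200, tol: float = 1e-5
                               ) -> np.ndarray:
    """Cumulative explained variance EV(k) = 1 - SSE(k)/SST for k = 1..p.

    SST is the uncentered total sum of squares ``||X||_F^2`` by default
    (NMF has no intercept and the data are non-negative); ``centered=True``
    uses row-mean-removed SST instead.  The profile is reported as a running
    maximum so it is non-decreasing even when an individual alternating fit
    lands in a slightly worse local optimum.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[0]
    max_k = p if max_k is None else min(max_k, p)
    if centered:
        sst = float(np.linalg.norm(X - X.mean(axis=1, keepdims=True), "fro") ** 2)
    else:
        sst = float(np.linalg.norm(X, "fro") ** 2)
    ev = np.empty(max_k)
    for i, k in enumerate(range(1, max_k + 1)):
        res = nmf_fit(X, k, max_iter=max_iter, tol=tol, seed=seed)
        ev[i] = 1.0 - res.residual_fro ** 2 / sst
    return np.maximum.accumulate(ev)


def select_num_synergies(X: np.ndarray, variance_threshold: float = 0.90,
                         slope_threshold: float = 0.05, seed: int = 0,
                         centered: bool = False, max_iter: int = 200,
                         tol: float = 1e-5) -> tuple[int, np.ndarray]:
    """Pick the synergy count from the explained-variance profile.

    chosen_k is the smallest k with EV(k) >= ``variance_threshold`` and
    EV(k+1) - EV(k) < ``slope_threshold`` (EV(p+1) treated as 1).
    """
    if not (0 < variance_threshold < 1 and 0 < slope_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    ev = explained_variance_profile(X, seed=seed, centered=centered,
                                    max_iter=max_iter, tol=tol)
    p = len(ev)
    for i, k in enumerate(range(1, p + 1)):
        ev_next = ev[i + 1] if i + 1 < p else 1.0
        if ev[i] >= variance_threshold and (ev_next - ev[i]) < slope_threshold:
            return k, ev
    return p, ev


# ---------------------------------------------------------------------------
# fitted model + online projection
# ---------------------------------------------------------------------------

@dataclass
class SynergyModel:
    """Fitted synergy basis with its least-squares projection operator."""

    basis: np.ndarray                    # p x k, unit-norm columns
    projector: np.ndarray                # k x p, pinv(basis)
    explained_variance_profile: np.ndarray
    chosen_k: int
    residual_r2: float                   # fraction of variance NOT explained
    seed: int = 0

    @classmethod
    def fit(cls, envelopes: np.ndarray, k: int | None = None,
            variance_threshold: float = 0.90, slope_threshold: float = 0.05,
            seed: int = 0, centered: bool = False, max_iter: int = 200,
            tol: float = 1e-5) -> "SynergyModel":
        """Fit on training envelopes (channels x samples); choose k if None.

        The returned basis has unit-norm columns (scale moved into the
        coefficients), which fixes the NMF scale indeterminacy.
        """
        X = np.asarray(envelopes, dtype=float)
        if k is None:
            chosen_k, profile = select_num_synergies(
                X, variance_threshold, slope_threshold, seed=seed,
                centered=centered, max_iter=max_iter, tol=tol)
        else:
            chosen_k = int(k)
            profile = explained_variance_profile(
                X, max_k=min(X.shape[0], chosen_k), seed=seed,
                centered=centered, max_iter=max_iter, tol=tol)
        res = nmf_fit(X, chosen_k, max_iter=max_iter, tol=tol, seed=seed)
        A = res.basis.copy()
        norms = np.linalg.norm(A, axis=0)
        norms[norms == 0] = 1.0
        A /= norms
        sst = float(np.linalg.norm(X, "fro") ** 2)
        r2_resid = res.residual_fro ** 2 / sst if sst > 0 else 0.0
        return cls(basis=A, projector=np.linalg.pinv(A),
                   explained_variance_profile=profile, chosen_k=chosen_k,
                   residual_r2=float(r2_resid), seed=seed)

    def save(self, path: str | Path) -> None:
        np.savez(path, basis=self.basis, projector=self.projector,
                 explained_variance_profile=self.explained_variance_profile,
                 chosen_k=self.chosen_k, residual_r2=self.residual_r2,
                 seed=self.seed)

    @classmethod
    def load(cls, path: str | Path) -> "SynergyModel":
        with np.load(path) as f:
            return cls(basis=f["basis"], projector=f["projector"],
                       explained_variance_profile=f["explained_variance_profile"],
                       chosen_k=int(f["chosen_k"]),
                       residual_r2=float(f["residual_r2"]),
                       seed=int(f["seed"]))


def project_online(model: SynergyModel, envelope_values: np.ndarray) -> np.ndarray:
    """Real-time synergy coefficients: ``pinv(A) @ x``.

    Accepts a single p-vector or a (p x q) matrix.  The map is linear and
    the output is intentionally not clipped to non-negative values.
    """
    x = np.asarray(envelope_values, dtype=float)
    p = model.basis.shape[0]
    if x.shape[0] != p:
        raise ValueError(f"expected {p} channels, got {x.shape[0]}")
    return model.projector @ x


def extract_synergy_features(session: EmgSession, model: SynergyModel,
                             spec: WindowSpec = WindowSpec(),
                             reduce: str = "mean") -> FeatureMatrix:
    """Window-level synergy features for every labeled trial.

    Envelope samples are projected to the k synergy coefficients and each
    window is summarized by its mean coefficient vector (``reduce="mean"``);
    ``reduce="passthrough"`` instead emits the per-sample coefficients at
    the window end.  Feature dimension equals ``model.chosen_k``.
    """
    if reduce not in ("mean", "passthrough"):
        raise ValueError(f"unknown reduce {reduce!r}")
    blocks, labels, times, trial_ids = [], [], [], []
    for ti, trial in enumerate(session.trials):
        seg = session.trial_signal(trial)
        nw = spec.n_windows(seg.shape[1])
        if nw == 0:
            logger.warning("trial %s shorter than window, skipped", trial)
            continue
        coeffs = project_online(model, seg)  # k x T
        if reduce == "mean":
            wins = _segment_windows(coeffs, spec)  # k x nw x window
            feats = wins.mean(axis=2)
        else:
            ends = spec.window - 1 + spec.step * np.arange(nw)
            feats = coeffs[:, ends]
        blocks.append(feats)
        labels.extend([trial.label] * nw)
        times.extend(trial.start + spec.window + spec.step * np.arange(nw))
        trial_ids.extend([ti] * nw)
    if not blocks:
        raise ValueError("no trial long enough for a single window")
    k = model.basis.shape[1]
    return FeatureMatrix(values=np.hstack(blocks), labels=np.asarray(labels),
                         window_times=np.asarray(times), feature_kind="synergy",
                         feature_names=[f"syn{i + 1}" for i in range(k)],
                         trial_ids=np.asarray(trial_ids))


def motion_envelope_matrix(session: EmgSession, rest_label: str = "rest"
                           ) -> np.ndarray:
    """Concatenated envelopes of all non-rest trials (the NMF input).

    Rest carries no synergy information and is excluded from the fit;
    rest windows are still classified downstream.
    """
    segs = [session.trial_signal(t) for t in session.trials
            if t.label != rest_label]
    if not segs:
        raise ValueError("session has no motion trials")
    return np.hstack(segs)
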