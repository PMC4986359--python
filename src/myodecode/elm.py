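"""Extreme Learning Machine multiclass classifier.

A single-hidden-layer feed-forward network whose hidden parameters are
drawn at random once and frozen; only the output weights are learned, in
closed form, as the ridge-regression solution

    w* = (H^T H + lambda I)^{-1} H^T O

where H is the hidden activation matrix and O the one-hot class targets.
The default activation is the triangular basis function
``tribas(v) = max(1 - |v|, 0)`` applied to the affine pre-activation
``x . r_j + b_j``; a Gaussian RBF node type (random centers and widths) and
a sigmoid are also available.  Because tribas has bounded support, inputs
are z-scored with training-set statistics stored in the model.

The equivalent C-parameterized constrained formulation (minimize
``||w||^2/2 + C/2 sum ||eps_i||^2``) is the same problem with
``lambda = 1/C``; only the lambda form is implemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg as sla
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 1e-3
#: Hidden-layer size grid spanning the range typical for this decoding task
#: (large grids are expensive; see cv_select_hidden).
DEFAULT_HIDDEN_GRID = (500, 1000, 2000, 3500, 5000)


def one_hot(labels: np.ndarray, class_order: list[str]) -> np.ndarray:
    """(n x m) one-hot targets in the given class order."""
    index = {c: i for i, c in enumerate(class_order)}
    O = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        O[i, index[lab]] = 1.0
    return O


@dataclass
class ElmModel:
    """A trained ELM: frozen random hidden layer + solved output weights."""

    hidden_weights: np.ndarray      # N x Z
    hidden_biases: np.ndarray       # N
    activation: str                 # {"tribas", "rbf", "sigmoid"}
    output_weights: np.ndarray      # N x m
    lam: float
    class_order: list[str]
    input_mean: np.ndarray          # Z
    input_scale: np.ndarray         # Z
    seed: int = 0
    rbf_gamma: np.ndarray | None = None  # N, only for activation="rbf"

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    @property
    def n_classes(self) -> int:
        return self.output_weights.shape[1]

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        extra = {}
        if self.rbf_gamma is not None:
            extra["rbf_gamma"] = self.rbf_gamma
        np.savez(path, hidden_weights=self.hidden_weights,
                 hidden_biases=self.hidden_biases,
                 activation=np.array(self.activation),
                 output_weights=self.output_weights, lam=self.lam,
                 class_order=np.array(self.class_order, dtype="U64"),
                 input_mean=self.input_mean, input_scale=self.input_scale,
                 seed=self.seed, **extra)

    @classmethod
    def load(cls, path: str | Path) -> "ElmModel":
        with np.load(path) as f:
            return cls(hidden_weights=f["hidden_weights"],
                       hidden_biases=f["hidden_biases"],
                       activation=str(f["activation"]),
                       output_weights=f["output_weights"],
                       lam=float(f["lam"]),
                       class_order=[str(c) for c in f["class_order"]],
                       input_mean=f["input_mean"], input_scale=f["input_scale"],
                       seed=int(f["seed"]),
                       rbf_gamma=f["rbf_gamma"] if "rbf_gamma" in f else None)


def _standardize(model: ElmModel, X: np.ndarray) -> np.ndarray:
    return (X - model.input_mean) / model.input_scale


def hidden_map(model: ElmModel, inputs: np.ndarray) -> np.ndarray:
    """Hidden activation matrix H (n x N) for raw (unstandardized) inputs."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != model.hidden_weights.shape[1]:
        raise ValueError(
            f"input dim {X.shape[1]} != model dim {model.hidden_weights.shape[1]}")
    Z = _standardize(model, X)
    if model.activation == "rbf":
        # exp(-gamma_j ||x - c_j||^2) with random centers c_j
        d2 = ((Z[:, None, :] - model.hidden_weights[None, :, :]) ** 2).sum(-1)
        return np.exp(-model.rbf_gamma[None, :] * d2)
    G = Z @ model.hidden_weights.T + model.hidden_biases
    if model.activation == "tribas":
        return np.maximum(1.0 - np.abs(G), 0.0)
    if model.activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-G))
    raise ValueError(f"unknown activation {model.activation!r}")


def _solve_output_weights(H: np.ndarray, O: np.ndarray, lam: float) -> np.ndarray:
    """Stable solve of (H^T H + lam I) w = H^T O (Cholesky, pinv fallback)."""
    N = H.shape[1]
    HtH = H.T @ H + lam * np.eye(N)
    HtO = H.T @ O
    try:
        c, low = sla.cho_factor(HtH, lower=True)
        return sla.cho_solve((c, low), HtO)
    except np.linalg.LinAlgError:
        logger.warning("normal equations singular (lambda=%g); "
                       "falling back to pseudoinverse", lam)
        return np.linalg.pinv(H) @ O


def fit(features: FeatureMatrix | np.ndarray, n_hidden: int,
        labels: np.ndarray | None = None, lam: float = DEFAULT_LAMBDA,
        activation: str = "tribas", seed: int = 0) -> ElmModel:
    """Train an ELM on a FeatureMatrix or an (n x Z) array + labels.

    Hidden weights and biases are i.i.d. uniform on [-1, 1] (the original
    ELM convention); for RBF nodes the rows are centers and widths are
    uniform on (0, 1].  Inputs are z-scored with training statistics.
    """
    if isinstance(features, FeatureMatrix):
        X = features.values.T
        y = np.asarray(features.labels)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if labels is None:
            raise ValueError("labels required when passing a raw array")
        y = np.asarray(labels)
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    class_order = sorted(set(map(str, y)))
    if len(class_order) < 2:
        raise ValueError("need at least 2 classes to train a classifier")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0

    rng = np.random.default_rng(seed)
    Z = X.shape[1]
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, Z))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    gamma = rng.uniform(0.0, 1.0, size=n_hidden) + 1e-6 if activation == "rbf" else None

    model = ElmModel(hidden_weights=W, hidden_biases=b, activation=activation,
                     output_weights=np.zeros((n_hidden, len(class_order))),
                     lam=lam, class_order=class_order, input_mean=mean,
                     input_scale=scale, seed=seed, rbf_gamma=gamma)
    H = hidden_map(model, X)
    O = one_hot(y, class_order)
    model.output_weights = _solve_output_weights(H, O, lam)
    return model


def predict(model: ElmModel, features: FeatureMatrix | np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Return (predicted labels, raw score matrix n x m).

    The predicted class is the argmax over output nodes; ties resolve to
    the lowest class index.  A single-output model uses the sign rule
    (score >= 0 -> second class in a two-label ordering is not applicable;
    the positive class is class_order[0]).
    """
    X = features.values.T if isinstance(features, FeatureMatrix) else features
    H = hidden_map(model, X)
    scores = H @ model.output_weights
    if scores.shape[1] == 1:  # binary, single output node: sign rule
        idx = (scores[:, 0] < 0).astype(int)
        labels = np.asarray(model.class_order)[np.minimum(idx, len(model.class_order) - 1)]
        return labels, scores
    idx = scores.argmax(axis=1)  # np.argmax takes the first (lowest) index on ties
    return np.asarray(model.class_order)[idx], scores


def accuracy(model: ElmModel, features: FeatureMatrix | np.ndarray,
             labels: np.ndarray | None = None) -> float:
    if isinstance(features, FeatureMatrix):
        labels = features.labels
    pred, _ = predict(model, features)
    return float(np.mean(pred == np.asarray(labels)))


def cv_select_hidden(features: FeatureMatrix | np.ndarray,
                     grid: tuple[int, ...] = DEFAULT_HIDDEN_GRID,
                     labels: np.ndarray | None = None,
                     lam: float = DEFAULT_LAMBDA, folds: int = 2,
                     activation: str = "tribas", seed: int = 0
                     ) -> tuple[int, dict[int, float]]:
    """Stratified k-fold (default 2-fold) selection of the hidden-layer size.

    Returns the grid value with the highest mean held-out accuracy (ties
    broken toward the smallest size) and the per-grid-point CV accuracy.
    """
    if isinstance(features, FeatureMatrix):
        X = features.values.T
        y = np.asarray(features.labels)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        y = np.asarray(labels)
    if not grid:
        raise ValueError("grid must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = {c: int(np.sum(y == c)) for c in set(y)}
    if min(counts.values()) < folds:
        raise ValueError(f"every class needs >= {folds} samples for "
                         f"stratified {folds}-fold CV; counts={counts}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=seed % (2 ** 31))
    splits = list(skf.split(X, y))
    grid_sorted = sorted(set(int(g) for g in grid))
    cv_acc: dict[int, float] = {}
    for g in grid_sorted:
        accs = []
        for train_idx, test_idx in splits:
            m = fit(X[train_idx], g, labels=y[train_idx], lam=lam,
                    activation=activation, seed=seed)
            accs.append(accuracy(m, X[test_idx], y[test_idx]))
        cv_acc[g] = float(np.mean(accs))
    best = max(grid_sorted, key=lambda g: (cv_acc[g], -g))
    return best, cv_acc
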