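"""A 7-6-4-2 feedforward network for two-class prediction: min-max scaling,
sigmoid hidden layers, softmax output, full-batch gradient-descent training,
ROC/AUC scoring, and k-fold cross-validation.

By default the scaler (and optional F-based feature selection) is fit inside
each training fold.  ``paper_mode=True`` instead fits both on the full
dataset before splitting, reproducing protocols that scale and select
features once on all samples (this leaks test information and typically
inflates the cross-validated AUC).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohortstats import f_rank_features

__all__ = [
    "Hyper",
    "ScalingParams",
    "ModelParams",
    "FoldResult",
    "CvResult",
    "minmax_scale",
    "apply_scaling",
    "ffnn_forward",
    "forward_batch",
    "train",
    "fit_final",
    "roc_auc",
    "roc_points",
    "cross_validate",
    "save_model",
    "load_model",
]

LAYER_SIZES = (7, 6, 4, 2)


@dataclass(frozen=True)
class Hyper:
    """Training hyperparameters for full-batch gradient descent."""

    lr: float = 0.05
    epochs: int = 2000
    seed: int = 0
    l2: float = 1e-4


@dataclass
class ScalingParams:
    """Per-feature min-max scaling parameters."""

    mins: np.ndarray
    maxs: np.ndarray
    constant: np.ndarray  # mask of degenerate (min == max) features


@dataclass
class ModelParams:
    """Weights, biases, feature order, and scaling of the trained network."""

    W1: np.ndarray  # (7, 6)
    B1: np.ndarray  # (6,)
    W2: np.ndarray  # (6, 4)
    B2: np.ndarray  # (4,)
    W3: np.ndarray  # (4, 2)
    B3: np.ndarray  # (2,)
    feature_names: list[str]
    scaling: ScalingParams | None = None

    def __post_init__(self) -> None:
        n_in, h1, h2, n_out = (
            len(self.feature_names),
            self.B1.size,
            self.B2.size,
            self.B3.size,
        )
        expected = {
            "W1": (n_in, h1),
            "W2": (h1, h2),
            "W3": (h2, n_out),
        }
        for name, shape in expected.items():
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, want {shape}")


@dataclass
class FoldResult:
    fold: int
    test_indices: np.ndarray
    scores: np.ndarray
    auc: float | None
    roc: np.ndarray  # (n_points, 2) of (FPR, TPR)


@dataclass
class CvResult:
    folds: list[FoldResult]
    seed: int
    mean_auc: float = field(init=False)

    def __post_init__(self) -> None:
        aucs = [f.auc for f in self.folds if f.auc is not None]
        self.mean_auc = float(np.mean(aucs)) if aucs else float("nan")

    @property
    def fold_aucs(self) -> list[float | None]:
        return [f.auc for f in self.folds]


def minmax_scale(X) -> tuple[np.ndarray, ScalingParams]:
    """Map each feature to (x - min) / (max - min) in [0, 1].

    Constant features map to 0 and are flagged in the returned params.
    """
    X = np.asarray(X, dtype=float)
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    constant = maxs == mins
    params = ScalingParams(mins=mins, maxs=maxs, constant=constant)
    return apply_scaling(X, params), params


def apply_scaling(X, params: ScalingParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    span = np.where(params.constant, 1.0, params.maxs - params.mins)
    scaled = (X - params.mins) / span
    scaled[:, params.constant] = 0.0
    return scaled


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def forward_batch(params: ModelParams, X: np.ndarray) -> np.ndarray:
    """Class-probability matrix (n, 2) for already-scaled inputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.W1.shape[0]:
        raise ValueError(f"input has {X.shape[1]} features, model wants {params.W1.shape[0]}")
    a1 = _sigmoid(X @ params.W1 + params.B1)
    a2 = _sigmoid(a1 @ params.W2 + params.B2)
    return _softmax(a2 @ params.W3 + params.B3)


def ffnn_forward(params: ModelParams, x) -> np.ndarray:
    """Probability vector (length 2) for one already-scaled input vector."""
    return forward_batch(params, np.asarray(x, dtype=float).reshape(1, -1))[0]


def _init_params(
    n_in: int, feature_names: Sequence[str], rng: np.random.Generator
) -> ModelParams:
    _, h1, h2, n_out = LAYER_SIZES
    return ModelParams(
        W1=rng.uniform(-0.5, 0.5, (n_in, h1)),
        B1=rng.uniform(-0.5, 0.5, h1),
        W2=rng.uniform(-0.5, 0.5, (h1, h2)),
        B2=rng.uniform(-0.5, 0.5, h2),
        W3=rng.uniform(-0.5, 0.5, (h2, n_out)),
        B3=rng.uniform(-0.5, 0.5, n_out),
        feature_names=list(feature_names),
    )


def train(
    X,
    y,
    hyper: Hyper = Hyper(),
    feature_names: Sequence[str] | None = None,
) -> ModelParams:
    """Full-batch gradient descent on mean cross-entropy with L2 penalty.

    ``X`` must already be scaled to [0, 1]; ``y`` is binary (class 1 =
    positive).  Deterministic given ``hyper.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    n, n_in = X.shape
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(n_in)]
    rng = np.random.default_rng(hyper.seed)
    p = _init_params(n_in, feature_names, rng)
    Y = np.zeros((n, 2))
    Y[np.arange(n), y] = 1.0
    for _ in range(hyper.epochs):
        z1 = X @ p.W1 + p.B1
        a1 = _sigmoid(z1)
        z2 = a1 @ p.W2 + p.B2
        a2 = _sigmoid(z2)
        probs = _softmax(a2 @ p.W3 + p.B3)
        d3 = (probs - Y) / n
        gW3 = a2.T @ d3 + 2.0 * hyper.l2 * p.W3
        gB3 = d3.sum(axis=0)
        d2 = (d3 @ p.W3.T) * a2 * (1.0 - a2)
        gW2 = a1.T @ d2 + 2.0 * hyper.l2 * p.W2
        gB2 = d2.sum(axis=0)
        d1 = (d2 @ p.W2.T) * a1 * (1.0 - a1)
        gW1 = X.T @ d1 + 2.0 * hyper.l2 * p.W1
        gB1 = d1.sum(axis=0)
        p.W1 -= hyper.lr * gW1
        p.B1 -= hyper.lr * gB1
        p.W2 -= hyper.lr * gW2
        p.B2 -= hyper.lr * gB2
        p.W3 -= hyper.lr * gW3
        p.B3 -= hyper.lr * gB3
    return p


def fit_final(
    X,
    y,
    hyper: Hyper = Hyper(),
    feature_names: Sequence[str] | None = None,
) -> ModelParams:
    """Train on the whole dataset (unscaled X); the fitted min-max scaling
    is stored in the returned params."""
    Xs, scaling = minmax_scale(X)
    params = train(Xs, y, hyper=hyper, feature_names=feature_names)
    params.scaling = scaling
    return params


def roc_auc(scores, labels) -> float:
    """AUC in the Mann-Whitney form: the probability that a random positive
    outscores a random negative, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    # Rank-based computation: O((n) log n) and exact for ties.
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)
    return float(auc)


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve as (FPR, TPR) rows from a threshold sweep over the scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # Collapse tied thresholds to their last occurrence.
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return np.column_stack([fpr, tpr])


def _make_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator, stratified: bool
) -> list[np.ndarray]:
    n = y.size
    if stratified:
        folds: list[list[int]] = [[] for _ in range(n_folds)]
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                folds[j % n_folds].append(int(i))
        return [np.sort(np.array(f, dtype=int)) for f in folds]
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def cross_validate(
    X,
    y,
    n_folds: int = 5,
    seed: int = 0,
    hyper: Hyper | None = None,
    stratified: bool = True,
    select_k: int | None = None,
    feature_names: Sequence[str] | None = None,
    paper_mode: bool = False,
) -> CvResult:
    """k-fold cross-validation of the network with per-fold ROC/AUC.

    Scaling (and feature selection when ``select_k`` is given) is fit on
    each training fold, unless ``paper_mode`` fits both once on the full
    dataset.  A test fold containing a single class has undefined AUC; it is
    recorded as missing and excluded from ``mean_auc`` with a warning.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    hyper = hyper if hyper is not None else Hyper(seed=seed)
    rng = np.random.default_rng(seed)
    folds = _make_folds(y, n_folds, rng, stratified)

    if paper_mode:
        cols = _select_columns(X, y, feature_names, select_k)
        X_glob, glob_scaling = minmax_scale(X[:, cols])

    results: list[FoldResult] = []
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(y.size), test_idx)
        if np.unique(y[train_idx]).size < 2:
            raise ValueError(f"training fold {k} contains a single class")
        if paper_mode:
            Xtr, Xte = X_glob[train_idx], X_glob[test_idx]
        else:
            cols = _select_columns(X[train_idx], y[train_idx], feature_names, select_k)
            Xtr, scaling = minmax_scale(X[np.ix_(train_idx, cols)])
            Xte = apply_scaling(X[np.ix_(test_idx, cols)], scaling)
        fold_hyper = Hyper(lr=hyper.lr, epochs=hyper.epochs, seed=hyper.seed + k, l2=hyper.l2)
        model = train(Xtr, y[train_idx], hyper=fold_hyper,
                      feature_names=[feature_names[c] for c in cols])
        scores = forward_batch(model, Xte)[:, 1]
        y_test = y[test_idx]
        if np.unique(y_test).size < 2:
            warnings.warn(f"fold {k}: single-class test set, AUC undefined", stacklevel=2)
            auc, roc = None, np.empty((0, 2))
        else:
            auc = roc_auc(scores, y_test)
            roc = roc_points(scores, y_test)
        results.append(FoldResult(fold=k, test_indices=test_idx, scores=scores, auc=auc, roc=roc))
    return CvResult(folds=results, seed=seed)


def _select_columns(X, y, feature_names, select_k) -> list[int]:
    if select_k is None:
        return list(range(X.shape[1]))
    frame = pd.DataFrame(X, columns=feature_names)
    chosen = [name for name, _ in f_rank_features(frame, y, select_k)]
    return [list(feature_names).index(name) for name in chosen]


def save_model(params: ModelParams, path: str | Path) -> None:
    """Serialize to a JSON text file."""
    payload = {
        "layer_sizes": [params.W1.shape[0], params.B1.size, params.B2.size, params.B3.size],
        "feature_names": params.feature_names,
        "W1": params.W1.tolist(),
        "B1": params.B1.tolist(),
        "W2": params.W2.tolist(),
        "B2": params.B2.tolist(),
        "W3": params.W3.tolist(),
        "B3": params.B3.tolist(),
    }
    if params.scaling is not None:
        payload["scaling"] = {
            "mins": params.scaling.mins.tolist(),
            "maxs": params.scaling.maxs.tolist(),
            "constant": params.scaling.constant.astype(bool).tolist(),
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> ModelParams:
    payload = json.loads(Path(path).read_text())
    scaling = None
    if "scaling" in payload:
        s = payload["scaling"]
        scaling = ScalingParams(
            mins=np.asarray(s["mins"], dtype=float),
            maxs=np.asarray(s["maxs"], dtype=float),
            constant=np.asarray(s["constant"], dtype=bool),
        )
    return ModelParams(
        W1=np.asarray(payload["W1"], dtype=float),
        B1=np.asarray(payload["B1"], dtype=float),
        W2=np.asarray(payload["W2"], dtype=float),
        B2=np.asarray(payload["B2"], dtype=float),
        W3=np.asarray(payload["W3"], dtype=float),
        B3=np.asarray(payload["B3"], dtype=float),
        feature_names=list(payload["feature_names"]),
        scaling=scaling,
    )
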