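"""Radial basis function network classifier, trained by least squares.

Topology: 5 input units (the wavelet-energy features), a hidden layer of
Gaussian units ``φ_j(x) = exp(−‖x − c_j‖² / (2σ_j²))`` whose input
connections are fixed at weight 1, and 3 linear output units (one-hot class
scores, argmax decision).  Training is classical and deterministic given a
seed: standardize features on the training split, place centers by seeded
k-means (or on every training sample), set widths from nearest-center
distances, then solve the regularized linear system for the output weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import cdist

from .errors import ConfigError

_N_FEATURES = 5
_N_CLASSES = 3


@dataclass
class TrainConfig:
    """Hidden-layer and solver settings.

    ``k`` Gaussian units; centers by seeded k-means (``n_restarts`` runs,
    best inertia) or one per training sample; widths = mean distance to the
    ``width_neighbors`` nearest other centers, scaled by ``width_scale``;
    ridge-regularized least squares for the output weights.
    """

    k: int = 12
    center_method: str = "kmeans"
    width_neighbors: int = 2
    width_scale: float = 1.0
    ridge: float = 1e-6
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.center_method not in ("kmeans", "all_samples"):
            raise ConfigError(f"unknown center_method {self.center_method!r}")
        if self.k < 1:
            raise ConfigError("k must be at least 1")
        if self.ridge < 0:
            raise ConfigError("ridge must be non-negative")


@dataclass
class RBFModel:
    """A trained network: centers, widths, output weights, feature scaler."""

    centers: np.ndarray          # (k, 5) in standardized feature space
    widths: np.ndarray           # (k,)
    output_weights: np.ndarray   # (k + 1, 3), last row is the bias
    class_labels: list[int]
    scaler_mean: np.ndarray      # (5,)
    scaler_std: np.ndarray       # (5,)

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def to_json(self, path: str) -> None:
        payload = dict(
            centers=self.centers.tolist(),
            widths=self.widths.tolist(),
            output_weights=self.output_weights.tolist(),
            class_labels=self.class_labels,
            scaler_mean=self.scaler_mean.tolist(),
            scaler_std=self.scaler_std.tolist(),
        )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "RBFModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            centers=np.array(p["centers"], dtype=float),
            widths=np.array(p["widths"], dtype=float),
            output_weights=np.array(p["output_weights"], dtype=float),
            class_labels=[int(c) for c in p["class_labels"]],
            scaler_mean=np.array(p["scaler_mean"], dtype=float),
            scaler_std=np.array(p["scaler_std"], dtype=float),
        )


def _design(X_std: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Gaussian activations plus a trailing bias column."""
    d2 = cdist(X_std, centers, metric="sqeuclidean")
    phi = np.exp(-d2 / (2.0 * widths[None, :] ** 2))
    return np.hstack([phi, np.ones((X_std.shape[0], 1))])


def _kmeans_centers(
    X_std: np.ndarray, k: int, n_restarts: int, seed: int
) -> np.ndarray:
    """Best-of-``n_restarts`` seeded k-means++ centers."""
    ss = np.random.SeedSequence([seed, 0x5BF])
    best_centers, best_inertia = None, np.inf
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-cluster warnings
            centers, assign = kmeans2(X_std, k, minit="++", rng=rng)
        inertia = float(np.sum((X_std - centers[assign]) ** 2))
        if inertia < best_inertia - 1e-12:
            best_inertia, best_centers = inertia, centers
    return best_centers


def _widths_from_centers(
    centers: np.ndarray, X_std: np.ndarray, neighbors: int, scale: float
) -> np.ndarray:
    k = centers.shape[0]
    if k == 1:
        d = np.linalg.norm(X_std - centers[0], axis=1)
        base = float(d.mean()) or 1.0
        widths = np.array([base])
    else:
        D = cdist(centers, centers)
        np.fill_diagonal(D, np.inf)
        p = min(neighbors, k - 1)
        widths = np.sort(D, axis=1)[:, :p].mean(axis=1)
        positive = widths[widths > 0]
        fallback = float(positive.mean()) if positive.size else 1.0
        widths = np.where(widths > 0, widths, fallback)
    return np.maximum(widths * scale, 1e-8)


def train(
    features: np.ndarray,
    labels: Sequence[int],
    config: TrainConfig | None = None,
) -> RBFModel:
    """Fit the network on a (n, 5) feature matrix and integer class labels.

    Output weights solve ``min_W ‖G W − Y‖² + ridge ‖W‖²`` with ``G`` the
    Gaussian design matrix (plus bias) and ``Y`` one-hot targets.  With
    ``ridge=0`` a singular system falls back to the pseudo-inverse with a
    warning.  Deterministic given ``config.seed``.
    """
    config = config or TrainConfig()
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != _N_FEATURES:
        raise ValueError(f"features must be (n, {_N_FEATURES}), got {X.shape}")
    y = np.asarray(labels)
    class_labels = sorted(int(c) for c in np.unique(y))
    if len(class_labels) > _N_CLASSES:
        raise ValueError(f"at most {_N_CLASSES} classes supported")
    n = X.shape[0]
    if config.center_method == "kmeans" and config.k > n:
        raise ConfigError(f"k={config.k} exceeds the {n} training samples")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (X - mean) / std

    if config.center_method == "all_samples":
        centers = Xs.copy()
    else:
        centers = _kmeans_centers(Xs, config.k, config.n_restarts, config.seed)
    widths = _widths_from_centers(centers, Xs, config.width_neighbors, config.width_scale)

    G = _design(Xs, centers, widths)
    Y = np.zeros((n, _N_CLASSES))
    label_pos = {c: i for i, c in enumerate(class_labels)}
    for i, lab in enumerate(y):
        Y[i, label_pos[int(lab)]] = 1.0

    if config.ridge > 0:
        A = G.T @ G + config.ridge * np.eye(G.shape[1])
        W = np.linalg.solve(A, G.T @ Y)
    else:
        if np.linalg.matrix_rank(G) < min(G.shape):
            warnings.warn(
                "singular design with ridge=0; using pseudo-inverse", stacklevel=2
            )
        W = np.linalg.lstsq(G, Y, rcond=None)[0]

    # pad label list to 3 entries so the output layer stays 3-wide even if a
    # class is absent from training (scores for it are then constant zero)
    padded = class_labels + [c for c in (1, 2, 3) if c not in class_labels]
    return RBFModel(
        centers=centers,
        widths=widths,
        output_weights=W,
        class_labels=padded[:_N_CLASSES],
        scaler_mean=mean,
        scaler_std=std,
    )


def predict_scores(model: RBFModel, features: np.ndarray) -> np.ndarray:
    """Raw class scores, shape (n, 3)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != _N_FEATURES:
        raise ValueError(f"features must have {_N_FEATURES} columns, got {X.shape[1]}")
    Xs = (X - model.scaler_mean) / model.scaler_std
    return _design(Xs, model.centers, model.widths) @ model.output_weights


def predict(model: RBFModel, features: np.ndarray) -> np.ndarray:
    """Predicted class labels; score ties resolve to the lowest class index."""
    scores = predict_scores(model, features)
    idx = np.argmax(scores, axis=1)  # argmax takes the first (lowest) on ties
    labels = np.array(model.class_labels)
    return labels[idx]


@dataclass
class RecognitionReport:
    """Per-cell recognition rates, per-class averages, confusion matrix."""

    cell_rates: pd.DataFrame        # class_id, batch_id, split, n, correct, rate_pct
    class_averages: dict[int, float]  # % averaged over that class's cells
    confusion: pd.DataFrame         # true class x predicted class counts
    overall_pct: float


def evaluate(
    model: RBFModel,
    features: np.ndarray,
    labels: Sequence[int],
    batches: Sequence[str],
    splits: Sequence[str] | None = None,
) -> RecognitionReport:
    """Score a labelled feature set cell by cell.

    A *cell* is one (class × batch × split) stratum; its recognition rate is
    ``100 · correct / total``.  Class averages are unweighted means over that
    class's non-empty cells.  Empty cells are simply absent from the table
    (a warning is emitted if a requested stratum combination never occurs).
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty evaluation set")
    y = np.asarray([int(v) for v in labels])
    pred = predict(model, X)
    frame = pd.DataFrame(
        dict(
            class_id=y,
            batch_id=list(batches),
            split=list(splits) if splits is not None else "all",
            correct=(pred == y).astype(int),
        )
    )
    grouped = (
        frame.groupby(["class_id", "batch_id", "split"], sort=True)["correct"]
        .agg(n="size", correct="sum")
        .reset_index()
    )
    grouped["rate_pct"] = 100.0 * grouped["correct"] / grouped["n"]
    class_averages = {
        int(c): float(g["rate_pct"].mean())
        for c, g in grouped.groupby("class_id")
    }
    all_labels = sorted(set(model.class_labels) | set(np.unique(y).tolist()))
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred, name="predicted")
    ).reindex(index=all_labels, columns=all_labels, fill_value=0)
    overall = 100.0 * float((pred == y).mean())
    return RecognitionReport(
        cell_rates=grouped,
        class_averages=class_averages,
        confusion=confusion,
        overall_pct=overall,
    )
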