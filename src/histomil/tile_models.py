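"""Tile-level supervised classifiers and the neoplastic gate.

Two instances of the same architecture serve two tasks: deciding whether a
tile lies in a neoplastic region (the *gate* used by the downstream slide
models) and classifying neoplastic tiles into tumor cells vs stroma.  The
architecture is a single-hidden-layer perceptron: input -> 128 hidden units
-> ReLU -> 1 logit -> sigmoid, trained with binary cross entropy.

:class:`TileClassifier` is a statsmodels-style model object built from data;
``fit()`` returns a :class:`TileClassifierResults` carrying the weights, the
loss trace and prediction methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np

from . import _nn
from .exceptions import (DegenerateDataError, ShapeMismatchError,
                         TrainingDivergedError)
from .tiling import FeatureMatrix

HIDDEN = 128


@dataclass
class TrainConfig:
    """Optimization settings shared by tile- and slide-level training."""

    lr: float = 1e-3
    max_epochs: int = 50
    batch_size: int = 256
    val_fraction: float = 0.10
    patience: int = 5
    seed: int = 0


def _init_mlp(d: int, rng: np.random.Generator) -> _nn.Params:
    p = _nn.affine_init(rng, d, HIDDEN, "l1")
    p.update(_nn.affine_init(rng, HIDDEN, 1, "l2"))
    return p


def _forward(params: _nn.Params, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    H = _nn.relu(X @ params["l1_W"] + params["l1_b"])
    logit = (H @ params["l2_W"]).ravel() + params["l2_b"][0]
    return _nn.sigmoid(logit), H


def _backward(params: _nn.Params, X: np.ndarray, H: np.ndarray,
              p: np.ndarray, y: np.ndarray) -> _nn.Params:
    n = len(y)
    dlogit = (p - y) / n                       # d(BCE)/d(logit)
    g = {"l2_W": (H.T @ dlogit)[:, None],
         "l2_b": np.array([dlogit.sum()])}
    dH = np.outer(dlogit, params["l2_W"].ravel())
    dH[H <= 0] = 0.0
    g["l1_W"] = X.T @ dH
    g["l1_b"] = dH.sum(axis=0)
    return g


class TileClassifier:
    """Binary tile classifier model (neoplastic-vs-not or tumor-vs-stroma).

    Parameters
    ----------
    features : (n, d) array or FeatureMatrix — tile features pooled over slides.
    labels : (n,) array of {0, 1}.
    task : informational tag, e.g. ``"neoplastic"`` or ``"cell_type"``.
    """

    def __init__(self, features: Union[np.ndarray, FeatureMatrix],
                 labels: np.ndarray, task: str = "neoplastic"):
        X = features.values if isinstance(features, FeatureMatrix) else features
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(labels, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ShapeMismatchError("features and labels disagree in length")
        self.task = task
        self.d = self.X.shape[1]

    def fit(self, cfg: Optional[TrainConfig] = None) -> "TileClassifierResults":
        """Minimize BCE with Adam; early stopping on a held-out split."""
        cfg = cfg or TrainConfig()
        classes = np.unique(self.y)
        if cfg.max_epochs > 0 and len(classes) < 2:
            raise DegenerateDataError(
                f"training labels contain a single class {classes}")
        rng = np.random.default_rng(cfg.seed)
        params = _init_mlp(self.d, rng)
        n = len(self.y)
        n_val = int(round(cfg.val_fraction * n)) if cfg.max_epochs > 0 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = self.X[tr_idx], self.y[tr_idx]
        Xval, yval = self.X[val_idx], self.y[val_idx]

        opt = _nn.Adam(params, lr=cfg.lr)
        train_trace, val_trace = [], []
        best_val, best_params, since_best = np.inf, None, 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(ytr))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                b = order[start:start + cfg.batch_size]
                p, H = _forward(params, Xtr[b])
                loss = _nn.bce_loss(p, ytr[b])
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}")
                opt.step(params, _backward(params, Xtr[b], H, p, ytr[b]))
                losses.append(loss)
            train_trace.append(float(np.mean(losses)))
            if n_val:
                pv, _ = _forward(params, Xval)
                vloss = _nn.bce_loss(pv, yval)
                val_trace.append(vloss)
                if vloss < best_val - 1e-6:
                    best_val, since_best = vloss, 0
                    best_params = {k: v.copy() for k, v in params.items()}
                else:
                    since_best += 1
                    if since_best >= cfg.patience:
                        break
        if best_params is not None:
            params = best_params
        return TileClassifierResults(model=self, params=params, config=cfg,
                                     train_loss=train_trace, val_loss=val_trace)


@dataclass
class TileClassifierResults:
    """Fitted tile classifier: weights, loss traces, prediction methods."""

    model: TileClassifier
    params: _nn.Params
    config: TrainConfig
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)

    def predict(self, features: Union[np.ndarray, FeatureMatrix]) -> np.ndarray:
        """Per-tile scores in (0,1); order-preserving with the input."""
        X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.model.d:
            raise ShapeMismatchError(
                f"feature dimension {X.shape[1]} != model dimension {self.model.d}")
        return _forward(self.params, X)[0]

    def summary(self) -> str:
        lines = [
            f"TileClassifier results  (task: {self.model.task})",
            f"  input dim:        {self.model.d}",
            f"  hidden units:     {HIDDEN}",
            f"  training tiles:   {len(self.model.y)}",
            f"  epochs run:       {len(self.train_loss)}",
        ]
        if self.train_loss:
            lines.append(f"  final train BCE:  {self.train_loss[-1]:.4f}")
        if self.val_loss:
            lines.append(f"  best val BCE:     {min(self.val_loss):.4f}")
        return "\n".join(lines)

    # serialization -------------------------------------------------------
    def save(self, path) -> None:
        import json
        meta = dict(kind="tile_classifier", task=self.model.task,
                    d=self.model.d, hidden=HIDDEN, seed=self.config.seed)
        np.savez(path, __meta__=np.array([json.dumps(meta)]),
                 train_loss=np.array(self.train_loss),
                 val_loss=np.array(self.val_loss), **self.params)

    @staticmethod
    def load(path) -> "TileClassifierResults":
        import json
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"][0]))
            params = {k: z[k] for k in z.files
                      if k not in ("__meta__", "train_loss", "val_loss")}
            model = TileClassifier(np.zeros((0, meta["d"])), np.zeros(0),
                                   task=meta["task"])
            return TileClassifierResults(
                model=model, params=params, config=TrainConfig(seed=meta["seed"]),
                train_loss=list(z["train_loss"]), val_loss=list(z["val_loss"]))


def select_neoplastic(features: Union[np.ndarray, FeatureMatrix],
                      neo_scores: np.ndarray, threshold: float = 0.5,
                      ) -> Tuple[Union[np.ndarray, FeatureMatrix], np.ndarray]:
    """Keep tiles whose neoplastic score is strictly greater than ``threshold``.

    Returns the gated features and the original tile indices kept.  An empty
    selection is legal and only warns.
    """
    scores = np.asarray(neo_scores, dtype=float).ravel()
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.shape[0] != scores.shape[0]:
        raise ShapeMismatchError("scores not aligned with features")
    keep = np.flatnonzero(scores > threshold)
    if keep.size == 0:
        warnings.warn("neoplastic gate kept zero tiles", stacklevel=2)
    if isinstance(features, FeatureMatrix):
        return FeatureMatrix(features.slide_id, X[keep]), keep
    return X[keep], keep
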