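"""Slide-level weakly supervised models.

Two multiple-instance-learning architectures consume bags of (neoplastic-
gated) tile features with patient-level labels inherited by each slide:

* :class:`AttentionMILClassifier` — a gated-attention classifier for the
  binary basal-like (1) vs classical (0) molecular class.  A linear layer
  embeds each tile into 128 dimensions; a gated attention mechanism
  (tanh branch ⊙ sigmoid branch, linear to one logit per tile, softmax
  across tiles) produces normalized weights; the attention-pooled embedding
  passes through a 128 → 64 → 1 ReLU head with a final sigmoid.  Trained
  with binary cross entropy.

* :class:`WeldonRegressor` — a top/bottom-R pooled regressor for the four
  continuous molecular components (classical, basal-like, stroma-active,
  stroma-inactive).  An MLP (128 hidden units, ReLU) scores every tile with
  four values; per component, the R largest and R smallest tile scores are
  averaged into the slide output.  Trained with mean squared error.

During training at most ``max_tiles`` (default 8000) tiles are uniformly
resampled from each slide per epoch; at inference all tiles are used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _nn
from .containers import COMPONENT_NAMES, SlideBag
from .exceptions import (DegenerateDataError, ShapeMismatchError,
                         TrainingDivergedError)
from .tile_models import TrainConfig
from .tiling import FeatureMatrix

MAX_TILES_DEFAULT = 8000
R_DEFAULT = 100
EMBED = 128
ATT_HIDDEN = 128
HEAD = (128, 64)
WELDON_HIDDEN = 128


def _as_array(bag) -> np.ndarray:
    if isinstance(bag, SlideBag):
        return bag.features
    if isinstance(bag, FeatureMatrix):
        return bag.values
    return np.asarray(bag, dtype=float)


def subsample_tiles(features, max_tiles: int = MAX_TILES_DEFAULT,
                    seed: Union[int, np.random.Generator] = 0):
    """Uniform without-replacement tile subsample, capped at ``max_tiles``.

    Bags with at most ``max_tiles`` tiles are returned unchanged (same
    object).  Selected indices are kept in original order.
    """
    if max_tiles < 1:
        raise ValueError("max_tiles must be >= 1")
    X = _as_array(features)
    n = X.shape[0]
    if n <= max_tiles:
        return features
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=max_tiles, replace=False))
    if isinstance(features, SlideBag):
        return features.subset(idx)
    if isinstance(features, FeatureMatrix):
        return FeatureMatrix(features.slide_id, X[idx])
    return X[idx]


def weldon_pool(tile_scores: np.ndarray, R: int = R_DEFAULT) -> np.ndarray:
    """Average of the R largest and R smallest scores, per component.

    With ``R' = min(R, n)`` the pooled value is the mean of the 2R'-element
    multiset of the R' top and R' bottom scores; for n < 2R' the two sets
    overlap and values count twice, so the statistic degenerates continuously
    to the plain mean.  A 1-D input yields a scalar; an (n, k) input a
    k-vector.
    """
    s = np.asarray(tile_scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score vector")
    if R < 1:
        raise ValueError("R must be >= 1")
    squeeze = s.ndim == 1
    if squeeze:
        s = s[:, None]
    n = s.shape[0]
    r = min(R, n)
    srt = np.sort(s, axis=0)
    pooled = (srt[:r].sum(axis=0) + srt[n - r:].sum(axis=0)) / (2 * r)
    return float(pooled[0]) if squeeze else pooled


def _weldon_grad_weights(scores_col: np.ndarray, R: int) -> np.ndarray:
    """d(pooled)/d(score_i): multiplicity of each tile in the 2R' multiset."""
    n = len(scores_col)
    r = min(R, n)
    order = np.argsort(scores_col, kind="stable")
    w = np.zeros(n)
    np.add.at(w, order[:r], 1.0)
    np.add.at(w, order[n - r:], 1.0)
    return w / (2 * r)


# --------------------------------------------------------------------------
# Gated-attention MIL classifier
# --------------------------------------------------------------------------

def _mil_init(d: int, rng: np.random.Generator) -> _nn.Params:
    p = _nn.affine_init(rng, d, EMBED, "emb")
    p.update(_nn.affine_init(rng, EMBED, ATT_HIDDEN, "att_v"))
    p.update(_nn.affine_init(rng, EMBED, ATT_HIDDEN, "att_u"))
    p["att_w"] = _nn.glorot(rng, ATT_HIDDEN, 1).ravel()
    p.update(_nn.affine_init(rng, EMBED, HEAD[0], "h1"))
    p.update(_nn.affine_init(rng, HEAD[0], HEAD[1], "h2"))
    p.update(_nn.affine_init(rng, HEAD[1], 1, "h3"))
    return p


def _mil_forward(params: _nn.Params, X: np.ndarray):
    """Forward pass on one bag; returns (score, attention weights, cache)."""
    H = X @ params["emb_W"] + params["emb_b"]
    At = np.tanh(H @ params["att_v_W"] + params["att_v_b"])
    As = _nn.sigmoid(H @ params["att_u_W"] + params["att_u_b"])
    G = At * As
    raw = G @ params["att_w"]
    alpha = _nn.softmax(raw)
    z = alpha @ H
    h1 = _nn.relu(z @ params["h1_W"] + params["h1_b"])
    h2 = _nn.relu(h1 @ params["h2_W"] + params["h2_b"])
    logit = float(h2 @ params["h3_W"].ravel() + params["h3_b"][0])
    p = float(_nn.sigmoid(np.array([logit]))[0])
    cache = (X, H, At, As, G, alpha, z, h1, h2)
    return p, alpha, cache


def _mil_backward(params: _nn.Params, cache, p: float, y: float) -> _nn.Params:
    X, H, At, As, G, alpha, z, h1, h2 = cache
    dlogit = p - y
    g = {"h3_W": (h2 * dlogit)[:, None], "h3_b": np.array([dlogit])}
    dh2 = params["h3_W"].ravel() * dlogit
    dh2[h2 <= 0] = 0.0
    g["h2_W"] = np.outer(h1, dh2)
    g["h2_b"] = dh2
    dh1 = params["h2_W"] @ dh2
    dh1[h1 <= 0] = 0.0
    g["h1_W"] = np.outer(z, dh1)
    g["h1_b"] = dh1
    dz = params["h1_W"] @ dh1
    dalpha = H @ dz
    dH = np.outer(alpha, dz)
    draw = alpha * (dalpha - float(alpha @ dalpha))   # softmax backward
    g["att_w"] = G.T @ draw
    dG = np.outer(draw, params["att_w"])
    dpre_t = dG * As * (1.0 - At ** 2)
    dpre_s = dG * At * As * (1.0 - As)
    g["att_v_W"] = H.T @ dpre_t
    g["att_v_b"] = dpre_t.sum(axis=0)
    g["att_u_W"] = H.T @ dpre_s
    g["att_u_b"] = dpre_s.sum(axis=0)
    dH += dpre_t @ params["att_v_W"].T + dpre_s @ params["att_u_W"].T
    g["emb_W"] = X.T @ dH
    g["emb_b"] = dH.sum(axis=0)
    return g


class AttentionMILClassifier:
    """Gated-attention MIL model for the binary basal-like/classical class.

    Parameters
    ----------
    bags : sequence of SlideBag / FeatureMatrix / (n_i, d) arrays, already
        gated to neoplastic tiles.
    labels : (n_slides,) array of {0 classical, 1 basal-like}, the patient
        label inherited by each of the patient's slides.
    max_tiles : per-slide training subsample cap (re-drawn every epoch).
    """

    def __init__(self, bags: Sequence, labels: np.ndarray,
                 max_tiles: int = MAX_TILES_DEFAULT):
        self.bags = [_as_array(b) for b in bags]
        self.labels = np.asarray(labels, dtype=float).ravel()
        if len(self.bags) != len(self.labels):
            raise ShapeMismatchError("bags and labels disagree in length")
        keep, skipped = [], 0
        for i, b in enumerate(self.bags):
            if b.shape[0] == 0:
                skipped += 1
            else:
                keep.append(i)
        if skipped:
            warnings.warn(f"skipping {skipped} slides with zero gated tiles",
                          stacklevel=2)
        if not keep:
            raise DegenerateDataError("all slides have zero gated tiles")
        self.bags = [self.bags[i] for i in keep]
        self.labels = self.labels[keep]
        self.max_tiles = max_tiles
        self.d = self.bags[0].shape[1]

    def fit(self, cfg: Optional[TrainConfig] = None,
            bag_batch: int = 8) -> "AttentionMILResults":
        cfg = cfg or TrainConfig()
        if cfg.max_epochs > 0:
            if len(self.bags) < 2:
                raise DegenerateDataError("need at least 2 slides to train")
            if len(np.unique(self.labels)) < 2:
                raise DegenerateDataError("both classes must be present")
        rng = np.random.default_rng(cfg.seed)
        params = _mil_init(self.d, rng)
        n = len(self.bags)
        n_val = int(round(cfg.val_fraction * n)) if cfg.max_epochs > 0 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        opt = _nn.Adam(params, lr=cfg.lr)
        train_trace, val_trace = [], []
        best_val, best_params, since_best = np.inf, None, 0
        for epoch in range(cfg.max_epochs):
            order = tr_idx[rng.permutation(len(tr_idx))]
            losses = []
            for start in range(0, len(order), bag_batch):
                batch = order[start:start + bag_batch]
                grads = None
                bloss = 0.0
                for i in batch:
                    X = subsample_tiles(self.bags[i], self.max_tiles, rng)
                    p, _, cache = _mil_forward(params, X)
                    y = self.labels[i]
                    bloss += _nn.bce_loss(np.array([p]), np.array([y]))
                    gi = _mil_backward(params, cache, p, y)
                    if grads is None:
                        grads = gi
                    else:
                        for k in grads:
                            grads[k] += gi[k]
                m = len(batch)
                for k in grads:
                    grads[k] /= m
                bloss /= m
                if not np.isfinite(bloss):
                    raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
                opt.step(params, grads)
                losses.append(bloss)
            train_trace.append(float(np.mean(losses)))
            if n_val:
                vlosses = [_nn.bce_loss(np.array([_mil_forward(params, self.bags[i])[0]]),
                                        np.array([self.labels[i]]))
                           for i in val_idx]
                vloss = float(np.mean(vlosses))
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
        return AttentionMILResults(model=self, params=params, config=cfg,
                                   train_loss=train_trace, val_loss=val_trace)


@dataclass
class AttentionMILResults:
    """Fitted gated-attention MIL classifier."""

    model: Optional[AttentionMILClassifier]
    params: _nn.Params
    config: TrainConfig
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.params["emb_W"].shape[0]

    def predict(self, bag) -> Tuple[float, np.ndarray]:
        """Slide score in (0,1) and normalized attention weights per tile.

        All tiles of the bag are used; the weights sum to 1.
        """
        X = _as_array(bag)
        if X.shape[0] == 0:
            raise ValueError("empty slide")
        if X.shape[1] != self.d:
            raise ShapeMismatchError(
                f"feature dim {X.shape[1]} != model dim {self.d}")
        p, alpha, _ = _mil_forward(self.params, X)
        return p, alpha

    def predict_many(self, bags: Sequence) -> np.ndarray:
        return np.array([self.predict(b)[0] for b in bags])

    def summary(self) -> str:
        lines = ["AttentionMILClassifier results",
                 f"  input dim:       {self.d}",
                 f"  embed/attention: {EMBED}/{ATT_HIDDEN} units, head {HEAD}",
                 f"  slides trained:  {len(self.model.bags) if self.model else 'n/a'}",
                 f"  epochs run:      {len(self.train_loss)}"]
        if self.train_loss:
            lines.append(f"  final train BCE: {self.train_loss[-1]:.4f}")
        if self.val_loss:
            lines.append(f"  best val BCE:    {min(self.val_loss):.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        import json
        meta = dict(kind="attention_mil", d=self.d, seed=self.config.seed)
        np.savez(path, __meta__=np.array([json.dumps(meta)]),
                 train_loss=np.array(self.train_loss),
                 val_loss=np.array(self.val_loss), **self.params)

    @staticmethod
    def load(path) -> "AttentionMILResults":
        import json
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"][0]))
            params = {k: z[k] for k in z.files
                      if k not in ("__meta__", "train_loss", "val_loss")}
            return AttentionMILResults(
                model=None, params=params, config=TrainConfig(seed=meta["seed"]),
                train_loss=list(z["train_loss"]), val_loss=list(z["val_loss"]))


# --------------------------------------------------------------------------
# WELDON top/bottom-R regressor
# --------------------------------------------------------------------------

def _weldon_init(d: int, rng: np.random.Generator) -> _nn.Params:
    p = _nn.affine_init(rng, d, WELDON_HIDDEN, "l1")
    p.update(_nn.affine_init(rng, WELDON_HIDDEN, 4, "l2"))
    return p


def _weldon_forward(params: _nn.Params, X: np.ndarray):
    H = _nn.relu(X @ params["l1_W"] + params["l1_b"])
    S = H @ params["l2_W"] + params["l2_b"]
    return S, H


class WeldonRegressor:
    """Top/bottom-R pooled regressor for the four molecular components.

    ``labels`` is an (n_slides, 4) array in the canonical component order
    (classical, basal, stroma_active, stroma_inactive), the patient scores
    inherited by each slide.
    """

    def __init__(self, bags: Sequence, labels: np.ndarray,
                 R: int = R_DEFAULT, max_tiles: int = MAX_TILES_DEFAULT):
        self.bags = [_as_array(b) for b in bags]
        self.labels = np.asarray(labels, dtype=float)
        if self.labels.ndim != 2 or self.labels.shape[1] != 4:
            raise ShapeMismatchError("labels must be (n_slides, 4)")
        if len(self.bags) != len(self.labels):
            raise ShapeMismatchError("bags and labels disagree in length")
        keep = [i for i, b in enumerate(self.bags) if b.shape[0] > 0]
        if len(keep) < len(self.bags):
            warnings.warn(f"skipping {len(self.bags) - len(keep)} slides with "
                          "zero gated tiles", stacklevel=2)
        if not keep:
            raise DegenerateDataError("all slides have zero gated tiles")
        self.bags = [self.bags[i] for i in keep]
        self.labels = self.labels[keep]
        self.R = R
        self.max_tiles = max_tiles
        self.d = self.bags[0].shape[1]

    def fit(self, cfg: Optional[TrainConfig] = None,
            bag_batch: int = 8) -> "WeldonResults":
        cfg = cfg or TrainConfig()
        if cfg.max_epochs > 0 and len(self.bags) < 2:
            raise DegenerateDataError("need at least 2 slides to train")
        rng = np.random.default_rng(cfg.seed)
        params = _weldon_init(self.d, rng)
        n = len(self.bags)
        n_val = int(round(cfg.val_fraction * n)) if cfg.max_epochs > 0 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        opt = _nn.Adam(params, lr=cfg.lr)
        train_trace, val_trace = [], []
        best_val, best_params, since_best = np.inf, None, 0

        def bag_loss_grad(i, X, params, want_grad=True):
            S, H = _weldon_forward(params, X)
            pooled = weldon_pool(S, self.R)
            resid = pooled - self.labels[i]
            loss = float(np.sum(resid ** 2))
            if not want_grad:
                return loss, None
            dS = np.empty_like(S)
            for c in range(4):
                dS[:, c] = 2.0 * resid[c] * _weldon_grad_weights(S[:, c], self.R)
            g = {"l2_W": H.T @ dS, "l2_b": dS.sum(axis=0)}
            dH = dS @ params["l2_W"].T
            dH[H <= 0] = 0.0
            g["l1_W"] = X.T @ dH
            g["l1_b"] = dH.sum(axis=0)
            return loss, g

        for epoch in range(cfg.max_epochs):
            order = tr_idx[rng.permutation(len(tr_idx))]
            losses = []
            for start in range(0, len(order), bag_batch):
                batch = order[start:start + bag_batch]
                grads, bloss = None, 0.0
                for i in batch:
                    X = subsample_tiles(self.bags[i], self.max_tiles, rng)
                    loss, gi = bag_loss_grad(i, X, params)
                    bloss += loss
                    if grads is None:
                        grads = gi
                    else:
                        for k in grads:
                            grads[k] += gi[k]
                m = len(batch)
                for k in grads:
                    grads[k] /= m
                bloss /= m
                if not np.isfinite(bloss):
                    raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
                opt.step(params, grads)
                losses.append(bloss)
            train_trace.append(float(np.mean(losses)))
            if n_val:
                vloss = float(np.mean([bag_loss_grad(i, self.bags[i], params,
                                                     want_grad=False)[0]
                                       for i in val_idx]))
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
        return WeldonResults(model=self, params=params, config=cfg, R=self.R,
                             train_loss=train_trace, val_loss=val_trace)


@dataclass
class WeldonResults:
    """Fitted WELDON regressor: per-tile scoring and pooled slide prediction."""

    model: Optional[WeldonRegressor]
    params: _nn.Params
    config: TrainConfig
    R: int = R_DEFAULT
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.params["l1_W"].shape[0]

    def score_tiles(self, bag) -> np.ndarray:
        """(n_tiles, 4) score matrix, rows in the bag's tile order."""
        X = _as_array(bag)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.d:
            raise ShapeMismatchError(
                f"feature dim {X.shape[1]} != model dim {self.d}")
        return _weldon_forward(self.params, X)[0]

    def predict(self, bag) -> np.ndarray:
        """Slide-level 4-vector: top/bottom-R pooling of the tile scores."""
        X = _as_array(bag)
        if X.shape[0] == 0:
            raise ValueError("empty slide")
        return weldon_pool(self.score_tiles(X), self.R)

    def predict_many(self, bags: Sequence) -> np.ndarray:
        return np.vstack([self.predict(b) for b in bags])

    def summary(self) -> str:
        lines = ["WeldonRegressor results",
                 f"  input dim:      {self.d}",
                 f"  hidden units:   {WELDON_HIDDEN}; R = {self.R}",
                 f"  components:     {', '.join(COMPONENT_NAMES)}",
                 f"  epochs run:     {len(self.train_loss)}"]
        if self.train_loss:
            lines.append(f"  final train MSE: {self.train_loss[-1]:.4f}")
        if self.val_loss:
            lines.append(f"  best val MSE:    {min(self.val_loss):.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        import json
        meta = dict(kind="weldon", d=self.d, R=self.R, seed=self.config.seed)
        np.savez(path, __meta__=np.array([json.dumps(meta)]),
                 train_loss=np.array(self.train_loss),
                 val_loss=np.array(self.val_loss), **self.params)

    @staticmethod
    def load(path) -> "WeldonResults":
        import json
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"][0]))
            params = {k: z[k] for k in z.files
                      if k not in ("__meta__", "train_loss", "val_loss")}
            return WeldonResults(model=None, params=params,
                                 config=TrainConfig(seed=meta["seed"]),
                                 R=meta["R"],
                                 train_loss=list(z["train_loss"]),
                                 val_loss=list(z["val_loss"]))


def patient_scores(slide_scores: np.ndarray, patient_ids: Sequence[str],
                   rule: str = "mean"):
    """Aggregate per-slide scores to patients (mean by default, or max)."""
    import pandas as pd
    df = pd.DataFrame({"patient_id": list(patient_ids)})
    s = np.asarray(slide_scores)
    if s.ndim == 1:
        df["score"] = s
        agg = df.groupby("patient_id", sort=True)["score"]
        return (agg.mean() if rule == "mean" else agg.max())
    for j in range(s.shape[1]):
        df[f"c{j}"] = s[:, j]
    g = df.groupby("patient_id", sort=True)
    return g.mean() if rule == "mean" else g.max()
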