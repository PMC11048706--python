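"""SGD training of the classification heads.

Optimisation protocol: plain SGD with momentum 0.1, 100 epochs, learning
rate starting at 0.1 and divided by 10 every 10 epochs.  Binary
(histopathology) targets use single-output binary cross-entropy; LN-RADS
targets use the per-bit thermometer BCE, the standard cumulative-ordinal
objective matching the per-bit sigmoid outputs.

Features are standardised with training-split statistics before the heads
see them.  All randomness (parameter init, per-epoch shuffling) derives
from ``TrainConfig.seed``, so runs are bitwise reproducible on one device.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .coding import N_BITS, encode_levels
from .cohort import N_FEATURES
from .model import HeadSpec, sigmoid
from .metrics import confusion_from_predictions, metrics_from_cm, roc_and_auc, select_threshold

logger = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    lr0: float = 0.1
    decay_every: int = 10
    decay_factor: float = 10.0
    momentum: float = 0.1
    batch_size: int = 32
    seed: int = 0
    min_lr: float = 0.0  # 0 keeps the literal schedule (lr underflows late)
    weight_decay: float = 0.0

    def __post_init__(self):
        if self.epochs <= 0 or self.lr0 <= 0 or self.decay_factor <= 1:
            raise ValueError("epochs > 0, lr0 > 0 and decay_factor > 1 required")


@dataclass
class EpochCurves:
    """Per-epoch evaluation-split accuracy and AUC trajectories."""

    acc: np.ndarray
    auc: np.ndarray

    def __post_init__(self):
        self.acc = np.asarray(self.acc, float)
        self.auc = np.asarray(self.auc, float)
        if self.acc.shape != self.auc.shape:
            raise ValueError("curve lengths differ")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Step schedule: lr0 / decay_factor^floor(epoch / decay_every), floored."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return max(cfg.min_lr, cfg.lr0 * cfg.decay_factor ** (-(epoch // cfg.decay_every)))


def thermometer_bce_loss(y, code) -> float:
    """Sum over the five bits of binary cross-entropy against a thermometer code.

    Probabilities are clamped to [1e-7, 1 - 1e-7]; a perfect (clamped)
    prediction therefore yields a loss near zero, and uniform 0.5 outputs
    yield 5 ln 2 regardless of the code.
    """
    y = np.clip(np.asarray(y, float), _EPS, 1 - _EPS)
    c = np.asarray(code, float)
    return float(-(c * np.log(y) + (1 - c) * np.log(1 - y)).sum())


def _binary_bce(p, t) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())


# --------------------------------------------------------------------------
# Trainable heads (forward + analytic gradients)
# --------------------------------------------------------------------------


def init_params(spec: HeadSpec, rng: np.random.Generator) -> dict:
    s = 0.1
    if spec.variant == "binary_narrow":
        return {"w": s * rng.standard_normal(N_FEATURES), "w0": 0.0}
    if spec.variant == "binary_wide":
        k = spec.intermediate_width
        return {
            "a": s * rng.standard_normal(N_FEATURES),
            "b": np.zeros(k),
            "v": s * rng.standard_normal(k),
            "v0": 0.0,
        }
    if spec.variant == "lnrads_mlr":
        return {"a": s * rng.standard_normal(N_FEATURES), "b": np.zeros(N_BITS)}
    if spec.variant == "lnrads_fc":
        return {"W": s * rng.standard_normal((N_BITS, N_FEATURES)), "c": np.zeros(N_BITS)}
    raise ValueError(spec.variant)


def forward_score(spec: HeadSpec, params: dict, X: np.ndarray) -> np.ndarray:
    """Malignancy score in [0,1] for a batch of feature vectors."""
    if spec.variant == "binary_narrow":
        return sigmoid(X @ params["w"] + params["w0"])
    if spec.variant == "binary_wide":
        y = sigmoid(X @ params["a"][:, None] + params["b"])
        return sigmoid(y @ params["v"] + params["v0"])
    if spec.variant == "lnrads_mlr":
        return sigmoid(X @ params["a"][:, None] + params["b"]).mean(axis=1)
    if spec.variant == "lnrads_fc":
        return sigmoid(X @ params["W"].T + params["c"]).mean(axis=1)
    raise ValueError(spec.variant)


def loss_and_grads(spec: HeadSpec, params: dict, X: np.ndarray, T: np.ndarray):
    """Mean batch loss and analytic parameter gradients.

    For the ordinal (shared-weight) head the gradient of ``a`` is by
    construction the sum over bits of the per-bit gradients, which is what
    keeps the weights shared through training.
    """
    n = X.shape[0]
    if spec.variant == "binary_narrow":
        p = sigmoid(X @ params["w"] + params["w0"])
        d = (p - T) / n
        return _binary_bce(p, T), {"w": X.T @ d, "w0": d.sum()}
    if spec.variant == "binary_wide":
        y = sigmoid(X @ params["a"][:, None] + params["b"])
        p = sigmoid(y @ params["v"] + params["v0"])
        d = (p - T) / n
        dz = (d[:, None] * params["v"]) * y * (1 - y)
        return _binary_bce(p, T), {
            "a": X.T @ dz.sum(axis=1),
            "b": dz.sum(axis=0),
            "v": y.T @ d,
            "v0": d.sum(),
        }
    # thermometer targets: T is (n, 5); loss = mean over samples of summed BCE
    if spec.variant == "lnrads_mlr":
        Y = sigmoid(X @ params["a"][:, None] + params["b"])
        D = (Y - T) / n
        return _thermo_batch_loss(Y, T), {"a": X.T @ D.sum(axis=1), "b": D.sum(axis=0)}
    if spec.variant == "lnrads_fc":
        Y = sigmoid(X @ params["W"].T + params["c"])
        D = (Y - T) / n
        return _thermo_batch_loss(Y, T), {"W": D.T @ X, "c": D.sum(axis=0)}
    raise ValueError(spec.variant)


def _thermo_batch_loss(Y: np.ndarray, T: np.ndarray) -> float:
    """Mean over samples of the summed per-bit BCE (vectorised)."""
    Yc = np.clip(Y, _EPS, 1 - _EPS)
    return float(-(T * np.log(Yc) + (1 - T) * np.log(1 - Yc)).sum(axis=1).mean())


@dataclass
class TrainedHead:
    """A trained head plus its feature standardiser and decision threshold."""

    spec: HeadSpec
    params: dict
    feat_mean: np.ndarray
    feat_std: np.ndarray
    threshold: float = 0.5

    def scores(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.feat_mean) / self.feat_std
        return forward_score(self.spec, self.params, Z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.scores(X) > self.threshold

    def save(self, path) -> None:
        """Checkpoint: .npz parameters with a JSON sidecar describing the head."""
        path = str(path)
        np.savez(path, feat_mean=self.feat_mean, feat_std=self.feat_std,
                 **{k: np.asarray(v) for k, v in self.params.items()})
        with open(path + ".json", "w") as fh:
            json.dump({"variant": self.spec.variant,
                       "intermediate_width": self.spec.intermediate_width,
                       "threshold": self.threshold}, fh)

    @classmethod
    def load(cls, path) -> "TrainedHead":
        path = str(path)
        with open(path + ".json") as fh:
            meta = json.load(fh)
        npz = np.load(path if path.endswith(".npz") else path + ".npz")
        params = {k: npz[k] for k in npz.files if k not in ("feat_mean", "feat_std")}
        params = {k: (float(v) if v.ndim == 0 else v) for k, v in params.items()}
        return cls(HeadSpec(meta["variant"], meta["intermediate_width"]), params,
                   npz["feat_mean"], npz["feat_std"], meta["threshold"])


def train(
    spec: HeadSpec,
    X_train: np.ndarray,
    malignant_train: np.ndarray,
    cfg: TrainConfig,
    levels_train=None,
    X_eval: np.ndarray | None = None,
    malignant_eval: np.ndarray | None = None,
    target: str = "auto",
    threshold_from_eval: bool = False,
) -> tuple[TrainedHead, EpochCurves | None, list[float]]:
    """Train one head with SGD + momentum under the step schedule.

    ``target`` is "binary" (histopathology label) or "lnrads" (thermometer
    codes from ``levels_train``); "auto" picks it from the variant.  When an
    evaluation split is given, per-epoch accuracy and AUC are computed on it
    with the decision threshold selected on the training split (the
    leakage-free reading; ``threshold_from_eval`` reproduces the alternative
    reading in which the threshold comes from the evaluation split itself).

    Returns the trained head, the epoch curves (or None without an
    evaluation split) and the per-epoch mean training losses.
    """
    X_train = np.asarray(X_train, float)
    mal = np.asarray(malignant_train).astype(float)
    if X_train.shape[0] == 0:
        raise ValueError("empty training split")
    if target == "auto":
        target = "lnrads" if spec.variant.startswith("lnrads") else "binary"
    if target == "lnrads":
        if levels_train is None:
            raise ValueError("lnrads target requires levels_train")
        T = encode_levels(levels_train).astype(float)
    else:
        T = mal
    if len(np.unique(mal)) < 2:
        raise ValueError("single-class training split: threshold selection undefined")

    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0) + 1e-8
    Z = (X_train - mean) / std
    Z_eval = None if X_eval is None else (np.asarray(X_eval, float) - mean) / std

    rng = np.random.default_rng(cfg.seed)
    params = init_params(spec, rng)
    velocity = {k: np.zeros_like(np.asarray(v, float)) for k, v in params.items()}
    n = Z.shape[0]
    acc_curve, auc_curve, losses = [], [], []

    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = loss_and_grads(spec, params, Z[idx], T[idx])
            epoch_losses.append(loss)
            for k in params:
                g = grads[k]
                if cfg.weight_decay and np.ndim(params[k]) > 0:
                    g = g + cfg.weight_decay * params[k]
                velocity[k] = cfg.momentum * velocity[k] - lr * g
                params[k] = params[k] + velocity[k]
        losses.append(float(np.mean(epoch_losses)))

        if Z_eval is not None:
            s_train = forward_score(spec, params, Z)
            thr_scores, thr_labels = (
                (forward_score(spec, params, Z_eval), malignant_eval)
                if threshold_from_eval
                else (s_train, mal)
            )
            thr = select_threshold(thr_scores, thr_labels)
            s_eval = forward_score(spec, params, Z_eval)
            cm = confusion_from_predictions(s_eval > thr, malignant_eval)
            acc_curve.append(metrics_from_cm(cm).accuracy)
            _, auc = roc_and_auc(s_eval, malignant_eval)
            auc_curve.append(auc)
            logger.debug(
                "epoch=%d lr=%.3g loss=%.4f eval_acc=%.4f eval_auc=%.4f",
                epoch, lr, losses[-1], acc_curve[-1], auc_curve[-1],
            )

    head = TrainedHead(spec, params, mean, std)
    # final operating threshold
    thr_scores = head.scores(X_eval) if (threshold_from_eval and X_eval is not None) else head.scores(X_train)
    thr_labels = malignant_eval if (threshold_from_eval and X_eval is not None) else mal
    head.threshold = select_threshold(thr_scores, thr_labels)
    curves = EpochCurves(acc_curve, auc_curve) if Z_eval is not None else None
    return head, curves, losses


def write_curves(curves: EpochCurves, path) -> None:
    """Write per-epoch curves as delimited text (epoch, acc, auc)."""
    import pandas as pd

    pd.DataFrame(
        {"epoch": np.arange(len(curves.acc)), "acc": curves.acc, "auc": curves.auc}
    ).to_csv(path, index=False)
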