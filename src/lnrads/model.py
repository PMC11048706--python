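"""Classification heads over 10-d image features, and a small CNN backbone.

Four head variants are compared:

* ``binary_narrow`` — a single sigmoid unit on the 10 features (plain
  logistic regression), trained on the binary histopathology label.
* ``binary_wide``  — a shared-weight sigmoid intermediate layer of width 5
  (or 6) between the features and the final sigmoid, for parameter-count
  comparability with the ordinal heads.
* ``lnrads_fc``    — five independent sigmoid outputs y_i = sigmoid(W_i.x + c_i),
  one per thermometer bit (a fully connected bit layer).
* ``lnrads_mlr``   — the proportional-odds-style ordinal head: all five bits
  share one linear predictor and differ only in their intercept,

      y_i = sigmoid(a1 x1 + ... + a10 x10 + b_i),

  so the bit probabilities are ordered whenever the biases are, and the
  score s = mean(y_1..y_5) is strictly monotone in the shared predictor a.x.

The score (mean of the bit probabilities) is the malignancy score that gets
thresholded downstream for every LN-RADS variant.

The backbone contract maps a grayscale image to 10 raw features (no output
nonlinearity, since the heads consume them linearly).  The backbone shipped
here is a small frozen convolutional network (conv-pool blocks followed by a
10-unit linear map) with seeded random weights; per-image standardisation is
the documented input normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import N_FEATURES
from .coding import N_BITS

HEAD_VARIANTS = ("binary_narrow", "binary_wide", "lnrads_fc", "lnrads_mlr")


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass(frozen=True)
class HeadSpec:
    """Which head variant to build, and the wide head's intermediate width."""

    variant: str
    intermediate_width: int = 5

    def __post_init__(self):
        if self.variant not in HEAD_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.intermediate_width not in (5, 6):
            raise ValueError("intermediate_width must be 5 or 6")


@dataclass
class OrdinalHeadParams:
    """Shared weights a (10,) and per-bit biases b (5,) of the ordinal head."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, float)
        self.b = np.asarray(self.b, float)
        if self.a.shape != (N_FEATURES,) or self.b.shape != (N_BITS,):
            raise ValueError("OrdinalHeadParams shapes must be (10,) and (5,)")


def mlr_head(x, params: OrdinalHeadParams) -> np.ndarray:
    """Bit probabilities y_i = sigmoid(a.x + b_i); x is (10,) or (n, 10)."""
    x = np.asarray(x, float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite features")
    return sigmoid(x @ params.a[..., None] + params.b) if x.ndim == 2 else sigmoid(
        x @ params.a + params.b
    )


def fc_head(x, W, c) -> np.ndarray:
    """Independent-bit head y_i = sigmoid(W_i.x + c_i); W is (5, 10)."""
    x = np.asarray(x, float)
    W = np.asarray(W, float)
    c = np.asarray(c, float)
    if W.shape != (N_BITS, N_FEATURES) or c.shape != (N_BITS,):
        raise ValueError("fc_head expects W (5,10) and c (5,)")
    if not np.isfinite(x).all():
        raise ValueError("non-finite features")
    return sigmoid(x @ W.T + c)


def score(y) -> np.ndarray | float:
    """Malignancy score: the arithmetic mean of the five bit probabilities."""
    y = np.asarray(y, float)
    return y.mean(axis=-1)


def binary_heads(x, spec: HeadSpec, params: dict) -> np.ndarray | float:
    """Malignancy probability for the binary (histopathology-target) heads.

    ``binary_narrow``: sigmoid(w.x + w0) with params ``{"w": (10,), "w0": float}``.
    ``binary_wide``: a shared-weight sigmoid intermediate of width 5 or 6
    (keys ``a`` (10,), ``b`` (width,)) followed by sigmoid(v.y + v0).
    """
    x = np.asarray(x, float)
    if spec.variant == "binary_narrow":
        return sigmoid(x @ params["w"] + params["w0"])
    if spec.variant == "binary_wide":
        b = np.asarray(params["b"], float)
        if b.shape[0] != spec.intermediate_width:
            raise ValueError("intermediate bias width does not match spec")
        y = sigmoid(x @ np.asarray(params["a"], float)[..., None] + b) if x.ndim == 2 \
            else sigmoid(x @ params["a"] + b)
        return sigmoid(y @ params["v"] + params["v0"])
    raise ValueError(f"{spec.variant} is not a binary head")


def parameter_count(spec: HeadSpec) -> int:
    """Number of trainable head parameters for a variant."""
    if spec.variant == "binary_narrow":
        return N_FEATURES + 1
    if spec.variant == "binary_wide":
        k = spec.intermediate_width
        return N_FEATURES + k + k + 1  # a, b, v, v0
    if spec.variant == "lnrads_mlr":
        return N_FEATURES + N_BITS
    if spec.variant == "lnrads_fc":
        return N_FEATURES * N_BITS + N_BITS
    raise ValueError(spec.variant)


# --------------------------------------------------------------------------
# Backbone: frozen small CNN feature extractor
# --------------------------------------------------------------------------


class SmallCNNBackbone:
    """A frozen, seeded convolutional feature extractor for desk-scale use.

    Two conv(3x3)-ReLU-avgpool(2x2) blocks followed by global average
    pooling and a linear map to 10 raw features (no activation).  Weights
    are He-initialised from ``seed`` and never trained; only the heads
    learn.  Input: a single grayscale image of exactly ``image_size``,
    standardised per image (zero mean, unit variance) unless
    ``normalize=False``.
    """

    def __init__(self, image_size=(64, 64), seed: int = 0,
                 channels=(8, 16), zero_final: bool = False):
        self.image_size = tuple(image_size)
        rng = np.random.default_rng([seed, 0xC11])
        c_prev = 1
        self.kernels = []
        for c in channels:
            k = rng.standard_normal((c, c_prev, 3, 3)) * np.sqrt(2.0 / (9 * c_prev))
            self.kernels.append(k)
            c_prev = c
        self.final_w = (
            np.zeros((c_prev, N_FEATURES))
            if zero_final
            else rng.standard_normal((c_prev, N_FEATURES)) * np.sqrt(1.0 / c_prev)
        )
        self.final_b = np.zeros(N_FEATURES)

    @staticmethod
    def _conv(feat: np.ndarray, kernels: np.ndarray) -> np.ndarray:
        # feat (C, H, W), kernels (C_out, C, 3, 3); 'same' zero padding
        c_in, h, w = feat.shape
        padded = np.pad(feat, ((0, 0), (1, 1), (1, 1)))
        windows = np.lib.stride_tricks.sliding_window_view(padded, (3, 3), axis=(1, 2))
        # windows: (C, H, W, 3, 3) -> output (C_out, H, W)
        return np.tensordot(kernels, windows, axes=([1, 2, 3], [0, 3, 4]))

    @staticmethod
    def _pool(feat: np.ndarray) -> np.ndarray:
        c, h, w = feat.shape
        return feat[:, : h - h % 2, : w - w % 2].reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))

    def features(self, image: np.ndarray, normalize: bool = True) -> np.ndarray:
        """Map one grayscale image to a 10-d feature vector."""
        img = np.asarray(image, float)
        if img.shape != self.image_size:
            raise ValueError(f"expected image of size {self.image_size}, got {img.shape}")
        if normalize:
            img = (img - img.mean()) / (img.std() + 1e-8)
        feat = img[None]
        for k in self.kernels:
            feat = np.maximum(self._conv(feat, k), 0.0)
            feat = self._pool(feat)
        pooled = feat.mean(axis=(1, 2))
        return pooled @ self.final_w + self.final_b

    def features_batch(self, images, normalize: bool = True) -> np.ndarray:
        return np.stack([self.features(im, normalize) for im in images])
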