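"""The expression classifier: frozen convolutional features, trainable FC head.

The architecture mirrors transfer learning with a frozen pre-trained
backbone: convolutional filters are fixed throughout training and only a
three-layer fully connected head (FC1, FC2, FC3 with 7 output units, one
per expression) is optimized.  The default backbone is a small stack of
three frozen random-filter convolution + ReLU + max-pool stages; because
its filters never change, backbone features are computed once per image
and cached (`features`), and training touches only the head.

Dropout (inverted, default proportion 0.1) is applied before FC1 and FC2
in training mode only.  FC weights are He-initialized: zero-mean normal
with sd sqrt(2 / fan_in), biases zero.

A full-scale pre-trained backbone (e.g. AlexNet's conv stack) can be
plugged in from a weights file; none is bundled and nothing is downloaded.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .au import EXPRESSIONS, N_EXPRESSIONS


@dataclass(frozen=True)
class NetConfig:
    backbone: str = "small-frozen-conv"
    backbone_seed: int = 0
    fc_sizes: tuple[int, int, int] = (128, 128, 7)
    dropout: float = 0.1
    input_size: int = 64
    init_seed: int = 0
    backbone_weights: str | None = None
    channels: tuple[int, ...] = (8, 16, 32)

    def __post_init__(self):
        if self.fc_sizes[-1] != N_EXPRESSIONS:
            raise ValueError(f"final FC layer must have exactly {N_EXPRESSIONS} units")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout proportion must be in [0, 1)")
        if self.backbone == "alexnet-conv" and self.backbone_weights is None:
            raise ValueError(
                "alexnet-conv backbone requested without a weights file; "
                "provide backbone_weights explicitly (no silent download)"
            )
        if self.backbone not in ("small-frozen-conv", "alexnet-conv"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.input_size % 2 ** len(self.channels):
            raise ValueError("input size must be divisible by the total pooling factor")


def _conv2d(x: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 2-D convolution. x: (N,C,H,W), filters: (F,C,3,3)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    return np.einsum("nchwij,fcij->nfhw", win, filters, optimize=True)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).max(axis=(3, 5))


class ExpressionNet:
    """Network state: frozen backbone filters plus trainable FC parameters."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(config.backbone_seed))
        self.filters: list[np.ndarray] = []
        c_in = 1
        for c_out in config.channels:
            f = rng.normal(0.0, np.sqrt(2.0 / (c_in * 9)), size=(c_out, c_in, 3, 3))
            self.filters.append(f)
            c_in = c_out
        side = config.input_size // 2 ** len(config.channels)
        self.feature_dim = side * side * config.channels[-1]
        self.W1 = self.b1 = self.W2 = self.b2 = self.W3 = self.b3 = None
        self.init_fc_weights(config.init_seed)

    # -- initialization ----------------------------------------------------

    def init_fc_weights(self, seed: int) -> "ExpressionNet":
        """He-initialize the FC head: W ~ N(0, sqrt(2/fan_in)), biases 0."""
        n1, n2, n3 = self.config.fc_sizes
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        d = self.feature_dim
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, n1))
        self.b1 = np.zeros(n1)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / n1), size=(n1, n2))
        self.b2 = np.zeros(n2)
        self.W3 = rng.normal(0.0, np.sqrt(2.0 / n2), size=(n2, n3))
        self.b3 = np.zeros(n3)
        return self

    # -- backbone ----------------------------------------------------------

    def features(self, images: np.ndarray) -> np.ndarray:
        """Frozen-backbone features for a batch of grayscale images.

        `images` is (N, H, W) or (H, W) uint8/float in [0, 255]; returns
        (N, feature_dim) float64.
        """
        x = np.asarray(images, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1] != self.config.input_size or x.shape[2] != self.config.input_size:
            raise ValueError(
                f"image size {x.shape[1:]} does not match network input "
                f"{self.config.input_size}"
            )
        x = (x / 255.0 - 0.5)[:, None]  # (N,1,H,W)
        for f in self.filters:
            x = np.maximum(_conv2d(x, f), 0.0)
            x = _maxpool2(x)
        return x.reshape(x.shape[0], -1)

    def backbone_checksum(self) -> str:
        h = hashlib.sha256()
        for f in self.filters:
            h.update(np.ascontiguousarray(f).tobytes())
        return h.hexdigest()

    def fc_checksum(self) -> str:
        h = hashlib.sha256()
        for p in (self.W1, self.b1, self.W2, self.b2, self.W3, self.b3):
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # -- head --------------------------------------------------------------

    def head_forward(
        self,
        feats: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """FC head on backbone features -> (raw scores, softmax probabilities).

        Inverted dropout before FC1 and FC2 is active only with
        ``train=True`` (which then requires `dropout_rng`).
        """
        p = self.config.dropout
        cache = {}
        x0 = feats
        if train and p > 0:
            m0 = (dropout_rng.random(x0.shape) >= p) / (1.0 - p)
            x0 = x0 * m0
            cache["m0"] = m0
        z1 = x0 @ self.W1 + self.b1
        h1 = np.maximum(z1, 0.0)
        x1 = h1
        if train and p > 0:
            m1 = (dropout_rng.random(x1.shape) >= p) / (1.0 - p)
            x1 = x1 * m1
            cache["m1"] = m1
        z2 = x1 @ self.W2 + self.b2
        h2 = np.maximum(z2, 0.0)
        scores = h2 @ self.W3 + self.b3
        probs = softmax(scores)
        if return_cache:
            cache.update(x0=x0, z1=z1, x1=x1, z2=z2, h2=h2, probs=probs)
            return scores, probs, cache
        return scores, probs

    def forward(self, images: np.ndarray, mode: str = "eval",
                dropout_rng: np.random.Generator | None = None):
        """Full forward pass from raw images: (raw scores, probabilities)."""
        if mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        feats = self.features(images)
        return self.head_forward(feats, train=(mode == "train"), dropout_rng=dropout_rng)

    def predict_label(self, image: np.ndarray) -> str:
        """Argmax expression label; ties resolve to the first label in order."""
        scores, _ = self.forward(image)
        return EXPRESSIONS[int(np.argmax(scores[0]))]

    def fc_params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def set_fc_params(self, params: list[np.ndarray]) -> None:
        self.W1, self.b1, self.W2, self.b2, self.W3, self.b3 = [p.copy() for p in params]


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_network(config: NetConfig) -> ExpressionNet:
    """Construct the classifier from its configuration (deterministic per seeds)."""
    return ExpressionNet(config)
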