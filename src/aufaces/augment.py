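"""Deterministic augmentation: scale/position jitter and horizontal reflection.

Each preprocessed image is expanded into ``len(scales) * len(offsets) *
len(reflections)`` variants in fixed lexicographic order (scale, then
offset, then reflection) — 5 x 5 x 2 = 50 with the full-protocol defaults —
and sized to the square network input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, resize, warp

from .faces import LabeledImage


def _default_scales() -> tuple[float, ...]:
    return (0.90, 0.95, 1.00, 1.05, 1.10)


def _default_offsets(step: float = 0.05) -> tuple[tuple[float, float], ...]:
    # offsets as fractions of image width: centered, then +-step on each axis
    return ((0.0, 0.0), (-step, 0.0), (step, 0.0), (0.0, -step), (0.0, step))


@dataclass(frozen=True)
class AugmentConfig:
    """Factor lists for the augmentation grid.

    Offsets are (dx, dy) fractions of the image width; reflections is a
    subset of {False, True} where True means left-right mirrored.
    """

    scales: tuple[float, ...] = field(default_factory=_default_scales)
    offsets: tuple[tuple[float, float], ...] = field(default_factory=_default_offsets)
    reflections: tuple[bool, ...] = (False, True)
    input_size: int = 224

    def __post_init__(self):
        if not (self.scales and self.offsets and self.reflections):
            raise ValueError("scales, offsets and reflections must be non-empty")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        if self.input_size < 32:
            raise ValueError("input size must be >= 32")

    @property
    def n_variants(self) -> int:
        return len(self.scales) * len(self.offsets) * len(self.reflections)


def desk_augment_config(input_size: int = 64) -> AugmentConfig:
    """Reduced 3 x 3 x 2 = 18-variant grid for desk-scale runs."""
    return AugmentConfig(
        scales=(0.95, 1.00, 1.05),
        offsets=((0.0, 0.0), (-0.04, 0.0), (0.04, 0.0)),
        reflections=(False, True),
        input_size=input_size,
    )


def resize_to_input(image: np.ndarray, size: int, background: int = 128) -> np.ndarray:
    """Resize to size x size, preserving aspect by centered background padding."""
    if size < 32:
        raise ValueError("size must be >= 32")
    H, W = image.shape
    if H == W == size:
        return image.copy()
    scale = size / max(H, W)
    h, w = int(round(H * scale)), int(round(W * scale))
    scaled = resize(image.astype(float), (h, w), order=1, anti_aliasing=False, preserve_range=True)
    out = np.full((size, size), float(background))
    top, left = (size - h) // 2, (size - w) // 2
    out[top:top + h, left:left + w] = scaled
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _jitter(image: np.ndarray, s: float, dx: float, dy: float, background: int) -> np.ndarray:
    H, W = image.shape
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    # scale about the image center, then translate by pixel offsets
    tf = (
        AffineTransform(translation=(-cx, -cy))
        + AffineTransform(scale=(s, s))
        + AffineTransform(translation=(cx + dx * W, cy + dy * W))
    )
    out = warp(image.astype(float), tf.inverse, order=1, cval=float(background), preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def make_variants(image: np.ndarray, config: AugmentConfig, background: int = 128) -> list[np.ndarray]:
    """All augmentation variants of one image, in deterministic order.

    Order is lexicographic over (scale, offset, reflection).  An offset
    moving the face crop more than a quarter of the frame is rejected with
    the index of the offending variant.
    """
    H, W = image.shape
    variants = []
    idx = 0
    for s in config.scales:
        for dx, dy in config.offsets:
            if abs(dx) > 0.25 or abs(dy) > 0.25:
                raise ValueError(f"variant {idx}: offset ({dx}, {dy}) exceeds the image margin")
            moved = _jitter(image, s, dx, dy, background)
            for refl in config.reflections:
                v = np.fliplr(moved) if refl else moved
                variants.append(resize_to_input(v, config.input_size, background))
                idx += 1
    return variants


def augment_labeled(image: LabeledImage, config: AugmentConfig, background: int = 128) -> list[LabeledImage]:
    """make_variants with the label/identity/database metadata propagated."""
    return [
        LabeledImage(v, image.label, image.identity, image.database)
        for v in make_variants(image.pixels, config, background)
    ]
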