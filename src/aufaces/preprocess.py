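"""Image standardization: grayscale, face crop, histogram adjustment, oval mask.

The pipeline order is fixed: grayscale -> crop -> histogram adjustment ->
oval mask.  The histogram step remaps each image affinely so the facial
region has mean 128 and standard deviation 32; the mask replaces
everything outside a centered oval with a flat background, blending
linearly across a soft transition band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PreprocessConfig:
    target_mean: float = 128.0
    target_sd: float = 32.0
    oval_semi_x: float = 0.40   # fraction of crop width
    oval_semi_y: float = 0.48   # fraction of crop height
    boundary_softness: float = 0.05  # transition band, fraction of crop height
    background: int = 128

    def __post_init__(self):
        if self.target_sd <= 0:
            raise ValueError("target sd must be > 0")
        if not (0 < self.oval_semi_x <= 1 and 0 < self.oval_semi_y <= 1):
            raise ValueError("oval semi-axes must be in (0, 1]")
        if not (0 <= self.background <= 255):
            raise ValueError("background must be in [0, 255]")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to grayscale; 2-D input is returned unchanged.

    Uses the standard luminance weights (0.299, 0.587, 0.114), rounded to
    the nearest integer gray level.
    """
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        gray = image.astype(float) @ _LUMA
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"expected a 2-D grayscale or H x W x 3 RGB raster, got shape {image.shape}")


def crop_face(image: np.ndarray, bbox: tuple[int, int, int, int]) -> np.ndarray:
    """Extract the face region given a bounding box (x0, y0, width, height)."""
    x0, y0, w, h = bbox
    H, W = image.shape[:2]
    if w <= 0 or h <= 0 or x0 < 0 or y0 < 0 or x0 + w > W or y0 + h > H:
        raise ValueError(f"bbox {bbox} out of bounds for image of shape {(H, W)}")
    return image[y0:y0 + h, x0:x0 + w]


def histogram_adjust(
    image: np.ndarray, config: PreprocessConfig | None = None, clip: bool = True
) -> np.ndarray:
    """Affinely remap pixel intensities to mean 128 and sd 32.

    v' = (v - mean) / sd * target_sd + target_mean, using the population
    standard deviation.  With ``clip=True`` (default) the result is clipped
    to [0, 255]; pass ``clip=False`` to inspect the pre-clipping values,
    whose mean and sd hit the targets to machine precision.

    Raises on a constant image (degenerate histogram, sd = 0).
    """
    config = config or PreprocessConfig()
    v = image.astype(float)
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate histogram: image is constant (sd = 0)")
    out = (v - v.mean()) / sd * config.target_sd + config.target_mean
    if clip:
        out = np.clip(out, 0.0, 255.0)
    return out


def apply_oval_mask(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Replace pixels outside a centered oval with the background value.

    Inside the oval the image is untouched; beyond the oval plus the
    transition band it equals the background; within the band the pixel is
    a linear blend of the two, weighted by normalized radial distance.
    """
    config = config or PreprocessConfig()
    H, W = image.shape
    y, x = np.mgrid[0:H, 0:W]
    xn = (x + 0.5) / W - 0.5
    yn = (y + 0.5) / H - 0.5
    r = np.sqrt((xn / config.oval_semi_x) ** 2 + (yn / config.oval_semi_y) ** 2)
    band = max(config.boundary_softness, 1e-9)
    inside_weight = np.clip((1.0 + band - r) / band, 0.0, 1.0)
    out = image.astype(float) * inside_weight + config.background * (1.0 - inside_weight)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def preprocess_image(
    image: np.ndarray,
    bbox: tuple[int, int, int, int] | None = None,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Full standardization pipeline: grayscale -> crop -> histogram -> mask."""
    config = config or PreprocessConfig()
    gray = to_grayscale(image)
    if bbox is not None:
        gray = crop_face(gray, bbox)
    adjusted = histogram_adjust(gray, config)
    quantized = np.clip(np.rint(adjusted), 0, 255).astype(np.uint8)
    return apply_oval_mask(quantized, config)
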