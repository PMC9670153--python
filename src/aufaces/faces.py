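"""Parametric grayscale face synthesis under action-unit deformations.

A procedural 2-D renderer draws a frontal template face (oval, brows,
eyes, nose, mouth) from geometric primitives whose control points are
displaced by the 20 AU intensities.  Each AU maps to a documented,
linear-in-intensity displacement of the relevant control points, so
deformation magnitude grows monotonically with intensity and rendering
is fully deterministic.  The renderer stands in for posed photograph
databases and for 3-D morphable-model stimulus generators: it is not
photorealistic, but it plants a controlled, recoverable AU signal.

AU → geometry mapping (all displacements linear in intensity t):

====  =========================================================
AU    effect on the template
====  =========================================================
1     inner brow endpoints raised
2     outer brow endpoints raised
4     brow endpoints lowered and pulled together; glabella lines
5     upper eyelid raised (taller upper eye aperture)
6     lower lid raised, cheek arcs darkened
7     both lids tightened (shorter eye aperture)
9     nose shortened, bridge wrinkles darkened
10    upper lip outer edge raised
11    nasolabial furrows darkened
12    mouth corners pulled up and outward
15    mouth corners pulled down
16    lower lip depressed
17    lower lip pushed up, chin crease darkened
20    mouth stretched horizontally, corners flattened
22    lips funneled: narrower, thicker, darker, slightly parted
23    lips tightened: thinner
24    lips pressed: thinner and aperture suppressed
25    lips parted slightly
26    jaw dropped: moderate aperture, lower lip lowered
27    mouth stretched open: large aperture, slightly narrower
====  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .au import AU_IDS, EXPRESSIONS, AUVector

# Gray levels (0 = black, 1 = white) of the template's parts.
_BACKGROUND = 0.45
_SKIN = 0.78
_SCLERA = 0.92
_IRIS = 0.22
_BROW = 0.15
_LINE = 0.33
_LIP = 0.35
_MOUTH_OPEN = 0.10


@dataclass(frozen=True)
class FaceIdentity:
    """Geometry offsets and a texture seed identifying one synthetic poser.

    Offsets are small perturbations (fractions of the image side) of the
    template control points; they are bounded at sampling time so every
    feature stays inside the face oval.  The all-zero identity is the
    "average face" used as the probe template.
    """

    id: str
    eye_dx: float = 0.0        # eye-spacing offset
    eye_size: float = 0.0      # multiplicative eye-size offset
    brow_y: float = 0.0        # brow-height offset
    mouth_w: float = 0.0       # multiplicative mouth-width offset
    mouth_y: float = 0.0       # mouth-height offset
    face_aspect: float = 0.0   # multiplicative face-oval width offset
    texture_seed: int = 0
    texture_amp: float = 1.0   # 0 disables the identity shading field

    @classmethod
    def average(cls) -> "FaceIdentity":
        """The template face: all offsets zero, no identity texture."""
        return cls(id="average", texture_amp=0.0)

    @classmethod
    def sample(cls, ident: str, rng: np.random.Generator) -> "FaceIdentity":
        """Draw a random identity with bounded geometry offsets."""
        return cls(
            id=ident,
            eye_dx=rng.uniform(-0.012, 0.012),
            eye_size=rng.uniform(-0.12, 0.12),
            brow_y=rng.uniform(-0.012, 0.012),
            mouth_w=rng.uniform(-0.12, 0.12),
            mouth_y=rng.uniform(-0.012, 0.012),
            face_aspect=rng.uniform(-0.05, 0.05),
            texture_seed=int(rng.integers(0, 2**31)),
        )


@dataclass(frozen=True)
class CultureMap:
    """Per-expression distributions over AU intensities for one "culture".

    For each of the 7 expression labels, maps AU id -> (mean, sd) of a
    truncated-normal intensity on [0, 1].  AUs absent from a label's map
    are off (mean 0, sd 0).  The neutral label must have all means 0.
    """

    mapping: dict[str, dict[int, tuple[float, float]]]

    def __post_init__(self):
        missing = set(EXPRESSIONS) - set(self.mapping)
        if missing:
            raise ValueError(f"culture map missing labels: {sorted(missing)}")
        for label, aus in self.mapping.items():
            for au, (mean, sd) in aus.items():
                if au not in AU_IDS:
                    raise KeyError(f"unknown action unit AU#{au} in label {label!r}")
                if not (0.0 <= mean <= 1.0):
                    raise ValueError(f"mean {mean} for AU#{au}/{label!r} outside [0, 1]")
                if sd < 0:
                    raise ValueError(f"negative sd for AU#{au}/{label!r}")
        for au, (mean, _) in self.mapping["neutral"].items():
            if mean != 0.0:
                raise ValueError(f"neutral must map all AUs to mean 0 (AU#{au} has {mean})")

    @classmethod
    def from_means(cls, means: dict[str, dict[int, float]], sd: float = 0.1) -> "CultureMap":
        """Build a map from label -> {AU: mean}, applying `sd` to every active AU."""
        mapping = {
            label: {au: (m, sd if m > 0 else 0.0) for au, m in aus.items()}
            for label, aus in means.items()
        }
        for label in EXPRESSIONS:
            mapping.setdefault(label, {})
        return cls(mapping)

    def means(self, label: str) -> AUVector:
        return AUVector({au: m for au, (m, _) in self.mapping[label].items()})


@dataclass(frozen=True)
class DatabaseSpec:
    """Recipe for one synthetic expression database (one "culture")."""

    name: str
    culture: CultureMap
    n_identities: int = 60
    noise_sd: float = 0.1
    seed: int = 0
    image_size: int = 64

    def __post_init__(self):
        if self.n_identities < 12:
            raise ValueError("n_identities must be >= 12 to support a 40/8/12-proportioned split")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.image_size < 32:
            raise ValueError("image size must be >= 32")


@dataclass(frozen=True)
class LabeledImage:
    """One grayscale face raster with its expression/identity/database tags."""

    pixels: np.ndarray  # uint8, H x W
    label: str
    identity: str
    database: str

    def __post_init__(self):
        if self.label not in EXPRESSIONS:
            raise ValueError(f"unknown expression label {self.label!r}")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8 in [0, 255]")


@dataclass(frozen=True)
class ProbeStimulusSet:
    """The AU probe battery: 20 series x 11 intensities on the average face.

    The intensity-0.0 image of every series is bit-identical to the null
    image (no AU active anywhere).
    """

    null_image: np.ndarray
    series: dict[int, list[np.ndarray]]
    intensities: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 11))

    def __post_init__(self):
        if set(self.series) != set(AU_IDS):
            raise ValueError("probe set must contain exactly the 20 analyzed AUs")
        for au, imgs in self.series.items():
            if len(imgs) != len(self.intensities):
                raise ValueError(f"AU#{au} series must have {len(self.intensities)} images")
            if not np.array_equal(imgs[0], self.null_image):
                raise ValueError(f"AU#{au} intensity-0 image differs from the null image")


# ---------------------------------------------------------------------------
# rasterization helpers (normalized coordinates, y increasing downward)

def _grid(size: int):
    y, x = np.mgrid[0:size, 0:size]
    return (x + 0.5) / size, (y + 0.5) / size


def _blend(canvas, mask, color):
    return canvas * (1.0 - mask) + color * mask


def _ellipse_mask(X, Y, cx, cy, a, b, soft=0.008):
    r = np.sqrt(((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2)
    return np.clip((1.0 - r) / soft + 1.0, 0.0, 1.0)


def _segment_mask(X, Y, p0, p1, thickness, soft=0.004):
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    L2 = dx * dx + dy * dy
    t = np.clip(((X - p0[0]) * dx + (Y - p0[1]) * dy) / max(L2, 1e-12), 0.0, 1.0)
    d = np.hypot(X - (p0[0] + t * dx), Y - (p0[1] + t * dy))
    return np.clip((thickness - d) / soft + 1.0, 0.0, 1.0)


def _parabola(s, center_y, corner_y):
    """Column profile through the mouth: corner value at |s|=1, center at s=0."""
    return corner_y + (center_y - corner_y) * (1.0 - s * s)


def _texture(X, Y, seed: int, amp: float):
    """Smooth per-identity shading: a few low-frequency cosine products."""
    if amp == 0.0:
        return 0.0
    rng = np.random.default_rng(seed)
    f = rng.uniform(1.0, 3.0, size=(3, 2))
    ph = rng.uniform(0, 2 * np.pi, size=(3, 2))
    w = rng.normal(0, 1, size=3)
    tex = sum(
        w[k] * np.cos(2 * np.pi * f[k, 0] * X + ph[k, 0]) * np.cos(2 * np.pi * f[k, 1] * Y + ph[k, 1])
        for k in range(3)
    )
    return 0.018 * amp * tex


def render_face(identity: FaceIdentity, aus: AUVector, size: int = 64) -> np.ndarray:
    """Render `identity` displaying the AU pattern `aus` as a uint8 raster.

    Deterministic in (identity, aus, size); every AU displaces its control
    points linearly in intensity (see module docstring for the mapping).
    Rendered at 2x resolution and mean-pooled down, so edge coverage — and
    with it the pixel distance to the neutral render — varies smoothly and
    monotonically with AU intensity.
    """
    if not isinstance(aus, AUVector):
        aus = AUVector(aus)
    if size < 32:
        raise ValueError("size must be >= 32")
    canvas = _render_canvas(identity, aus, 2 * size)
    canvas = canvas.reshape(size, 2, size, 2).mean(axis=(1, 3))
    return np.clip(np.rint(canvas * 255.0), 0, 255).astype(np.uint8)


def _render_canvas(identity: FaceIdentity, aus: AUVector, size: int) -> np.ndarray:
    t = {a: aus[a] for a in AU_IDS}
    X, Y = _grid(size)
    canvas = np.full((size, size), _BACKGROUND)

    # face oval with identity shading
    ax = 0.34 * (1.0 + identity.face_aspect)
    face = _ellipse_mask(X, Y, 0.5, 0.52, ax, 0.45)
    skin = _SKIN + _texture(X, Y, identity.texture_seed, identity.texture_amp)
    canvas = canvas * (1.0 - face) + skin * face

    # --- brows -------------------------------------------------------------
    by = 0.315 + identity.brow_y
    by_in = by - 0.014 * t[1] + 0.014 * t[4]
    by_out = by - 0.014 * t[2] + 0.007 * t[4]
    bx_in = 0.065 - 0.008 * t[4]
    bx_out = 0.225
    for side in (-1, 1):
        p_in = (0.5 + side * bx_in, by_in)
        p_out = (0.5 + side * bx_out, by_out)
        canvas = _blend(canvas, _segment_mask(X, Y, p_in, p_out, 0.011), _BROW)
    # glabella lines (AU#4)
    if t[4] > 0:
        for side in (-1, 1):
            m = _segment_mask(X, Y, (0.5 + side * 0.018, 0.30), (0.5 + side * 0.018, 0.35), 0.004)
            canvas = _blend(canvas, 0.6 * t[4] * m, _LINE)

    # --- eyes --------------------------------------------------------------
    ey = 0.40
    edx = 0.15 + identity.eye_dx
    ea = 0.065 * (1.0 + identity.eye_size)
    b_up = 0.032 * (1.0 + identity.eye_size) * (1.0 + 1.10 * t[5] - 0.45 * t[7])
    b_lo = 0.032 * (1.0 + identity.eye_size) * (1.0 - 0.35 * t[6] - 0.45 * t[7])
    for side in (-1, 1):
        ex = 0.5 + side * edx
        upper = _ellipse_mask(X, Y, ex, ey, ea, max(b_up, 1e-3)) * (Y <= ey)
        lower = _ellipse_mask(X, Y, ex, ey, ea, max(b_lo, 1e-3)) * (Y > ey)
        eye = np.maximum(upper, lower)
        canvas = _blend(canvas, eye, _SCLERA)
        iris = _ellipse_mask(X, Y, ex, ey, 0.021, 0.021) * (eye > 0.5)
        canvas = _blend(canvas, iris, _IRIS)
        # cheek arc (AU#6)
        if t[6] > 0:
            m = _segment_mask(X, Y, (ex - 0.05, ey + 0.075), (ex + 0.05, ey + 0.075), 0.004)
            canvas = _blend(canvas, 0.8 * t[6] * m, _LINE)

    # --- nose --------------------------------------------------------------
    nose_top = 0.45 + 0.050 * t[9]
    canvas = _blend(canvas, _segment_mask(X, Y, (0.5, nose_top), (0.5, 0.585), 0.007), _LINE)
    for side in (-1, 1):
        canvas = _blend(canvas, _ellipse_mask(X, Y, 0.5 + side * 0.025, 0.59, 0.009, 0.007), _LINE)
    if t[9] > 0:  # bridge wrinkles
        for yy in (0.425, 0.445):
            m = _segment_mask(X, Y, (0.46, yy), (0.54, yy), 0.005)
            canvas = _blend(canvas, 0.9 * t[9] * m, _LINE)

    # --- mouth -------------------------------------------------------------
    cy = 0.72 + identity.mouth_y
    w = 0.13 * (1.0 + identity.mouth_w)
    w_eff = w * (1.0 + 0.35 * t[12] + 0.50 * t[20] - 0.25 * t[22])
    corner_y = cy + 0.080 * t[15] - 0.100 * t[12] + 0.010 * t[20]
    # jaw AUs open the mouth downward only: the upper lip stays fixed
    gap = (0.030 * t[26] + 0.048 * t[27] + 0.024 * t[22]) * (1.0 - 0.8 * t[24])
    g_up = 0.0
    g_lo = max(gap - 0.014 * t[17], 0.0)
    thin = (1.0 - 0.80 * t[23]) * (1.0 - 0.45 * t[24])
    # lips thick enough (>2 px at the default size) that their two band
    # edges never alias within one pixel as the mouth deforms
    t_up = (0.022 + 0.012 * t[22]) * thin
    t_lo = (0.030 + 0.012 * t[22]) * thin
    up_out_c = cy - (g_up + t_up + 0.024 * t[10])
    up_in_c = cy - g_up
    lo_in_c = cy + g_lo
    # AU#16 stretches the lower lip downward (outer edge only, nothing vacated)
    lo_out_c = cy + g_lo + t_lo + 0.032 * t[16] + 0.012 * t[26] - 0.012 * t[17]

    s = np.clip((X - 0.5) / w_eff, -1.0, 1.0)
    soft = 1.5 / size  # ~1.5 px anti-aliased band edges keep L1(t) monotone
    inside = np.clip((w_eff - np.abs(X - 0.5)) / soft + 1.0, 0.0, 1.0)
    yu_out = _parabola(s, up_out_c, corner_y)
    yu_in = _parabola(s, up_in_c, corner_y)
    yl_in = _parabola(s, lo_in_c, corner_y)
    yl_out = _parabola(s, lo_out_c, corner_y)

    px = 1.0 / size

    def _band(top, bottom):
        # exact box-filter coverage of [top, bottom] within each pixel row,
        # so adjacent bands hand pixels over without transient transparency
        cover = (np.minimum(bottom, Y + 0.5 * px) - np.maximum(top, Y - 0.5 * px)) / px
        return inside * np.clip(cover, 0.0, 1.0)

    lip_color = _LIP - 0.10 * t[22] - 0.07 * t[25] + 0.16 * t[24]
    lips = np.maximum(_band(yu_out, yu_in), _band(yl_in, yl_out))
    canvas = _blend(canvas, lips, lip_color)
    if gap > 0:
        canvas = _blend(canvas, _band(yu_in, yl_in), _MOUTH_OPEN)
    # lips part (AU#25): a dark seam widening in place, lips themselves fixed
    if t[25] > 0:
        half = 0.003 + 0.009 * t[25] * (1.0 - 0.8 * t[24])
        seam = _band(_parabola(s, cy - half, corner_y - half),
                     _parabola(s, cy + half, corner_y + half))
        canvas = _blend(canvas, seam, _MOUTH_OPEN)
    # downturned corner creases (AU#15)
    if t[15] > 0:
        for side in (-1, 1):
            cx_c = 0.5 + side * w_eff
            m = _segment_mask(X, Y, (cx_c, corner_y), (cx_c + side * 0.02, corner_y + 0.025), 0.004)
            canvas = _blend(canvas, 0.7 * t[15] * m, _LINE)

    # nasolabial furrows (AU#11)
    if t[11] > 0:
        for side in (-1, 1):
            m = _segment_mask(
                X, Y, (0.5 + side * 0.03, 0.60), (0.5 + side * (w_eff + 0.01), corner_y - 0.01), 0.004
            )
            canvas = _blend(canvas, 0.85 * t[11] * m, _LINE)
    # chin crease (AU#17)
    if t[17] > 0:
        m = _segment_mask(X, Y, (0.5 - 0.05, cy + 0.085), (0.5 + 0.05, cy + 0.085), 0.004)
        canvas = _blend(canvas, 0.85 * t[17] * m, _LINE)

    return canvas


def face_bbox(identity: FaceIdentity, size: int) -> tuple[int, int, int, int]:
    """Bounding box (x0, y0, width, height) enclosing the face oval, in pixels."""
    ax = 0.34 * (1.0 + identity.face_aspect) + 0.02
    bx = 0.45 + 0.02
    x0 = max(int(np.floor((0.5 - ax) * size)), 0)
    x1 = min(int(np.ceil((0.5 + ax) * size)), size)
    y0 = max(int(np.floor((0.52 - bx) * size)), 0)
    y1 = min(int(np.ceil((0.52 + bx) * size)), size)
    return x0, y0, x1 - x0, y1 - y0


# ---------------------------------------------------------------------------
# sampling and database generation

def sample_expression_aus(culture: CultureMap, label: str, rng: np.random.Generator | int) -> AUVector:
    """Draw an AU pattern for `label`: truncated-normal per AU, clipped to [0, 1].

    With sd = 0 the culture means are returned exactly.
    """
    if label not in EXPRESSIONS:
        raise ValueError(f"unknown expression label {label!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = {}
    for au, (mean, sd) in culture.mapping[label].items():
        if sd == 0:
            out[au] = mean
        else:
            a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
            out[au] = float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    return AUVector(out)


def generate_database(spec: DatabaseSpec) -> list[LabeledImage]:
    """Generate `n_identities` x 7 labeled face images, one per (identity, label).

    Deterministic in `spec.seed`; identities and their AU noise draws are
    derived from independent child streams of the spec seed.
    """
    id_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    images = []
    for i in range(spec.n_identities):
        ident = FaceIdentity.sample(f"{spec.name}-{i:03d}", id_rng)
        for j, label in enumerate(EXPRESSIONS):
            # independent stream per (identity, label): cultures that agree
            # on a label produce bit-identical images for it under one seed
            au_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1, i, j)))
            aus = sample_expression_aus(spec.culture, label, au_rng)
            pixels = render_face(ident, aus, spec.image_size)
            images.append(LabeledImage(pixels, label, ident.id, spec.name))
    return images


def generate_probe_set(
    template: FaceIdentity | None = None, size: int = 64, steps: int = 11
) -> ProbeStimulusSet:
    """Render the 20 x `steps` AU probe battery on the average face.

    One AU is swept from 0.0 to 1.0 while all others stay off; the
    intensity-0 render is shared (bit-identical) across all series.
    """
    template = FaceIdentity.average() if template is None else template
    intensities = np.linspace(0.0, 1.0, steps)
    null = render_face(template, AUVector.zeros(), size)
    series = {}
    for au in AU_IDS:
        imgs = [null if k == 0 else render_face(template, AUVector.single(au, v), size)
                for k, v in enumerate(intensities)]
        series[au] = imgs
    return ProbeStimulusSet(null_image=null, series=series, intensities=intensities)
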