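"""Synthetic orchard scenes and eye-tracker gaze streams.

Stands in for field recordings: cluttered green/brown canopies carrying a
handful of red apples of roughly 30 px diameter at 960x544, an optional blue
sky band and blue tree-label patch, and a gaze stream that dwells near each
apple centroid.  The gaze is corrupted the way a head-mounted eye-tracker is:
a constant per-stream calibration shift (tens of pixels, up to ~169 px) plus
small per-sample jitter, with scattered saccade samples between fixations.

Every stage is deterministic given the seeds carried by the specs, so the
whole annotation pipeline can be scored against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom as _zoom
from skimage.draw import disk as _draw_disk, ellipse as _draw_ellipse

from .gaze import GazeSample

__all__ = [
    "SceneSpec",
    "GazeSpec",
    "SceneTruth",
    "FixationTruth",
    "generate_scene",
    "generate_gaze",
    "DEFAULT_APPLE_COLORS",
    "DEFAULT_BACKGROUND_PALETTE",
]

# Shades of red/orange apples; the study's orchard had no green apples.
DEFAULT_APPLE_COLORS: tuple[tuple[int, int, int], ...] = (
    (178, 34, 34),
    (200, 55, 40),
    (205, 92, 50),
    (190, 40, 60),
    (210, 110, 55),
)

# Foliage: the canopy seen from 1.5 m is dominantly green, light to dark.
DEFAULT_BACKGROUND_PALETTE: tuple[tuple[int, int, int], ...] = (
    (34, 85, 34),
    (60, 110, 45),
    (88, 132, 60),
    (45, 70, 35),
    (70, 120, 55),
    (52, 92, 40),
)

# Wood: dark browns/grays of branches and trunk, drawn as thin elongated
# strokes through the foliage.
DEFAULT_WOOD_PALETTE: tuple[tuple[int, int, int], ...] = (
    (62, 45, 28),
    (78, 58, 36),
    (70, 66, 60),
)

SKY_COLOR = (135, 206, 235)
LABEL_COLOR = (30, 60, 200)

MAX_CALIBRATION_SHIFT = 169.0  # largest gaze-to-object offset the pipeline assumes


@dataclass
class SceneSpec:
    """Full parameterization of one synthetic orchard frame.

    ``center_bias_sd_frac`` controls how strongly apples concentrate toward
    the frame center (standard deviation of the truncated-normal placement,
    as a fraction of the smaller frame dimension).  Egocentric recordings
    frame the tree being inspected, so objects of interest cluster centrally;
    this is also the premise of the center-prior annotation strategy.
    """

    width: int = 960
    height: int = 544
    n_apples: int = 5
    apple_radius_mean: float = 15.0
    apple_radius_sd: float = 2.0
    apple_colors: tuple[tuple[int, int, int], ...] = DEFAULT_APPLE_COLORS
    apple_color_sd: float = 12.0
    background_palette: tuple[tuple[int, int, int], ...] = DEFAULT_BACKGROUND_PALETTE
    wood_palette: tuple[tuple[int, int, int], ...] = DEFAULT_WOOD_PALETTE
    n_branches: int = 8
    clutter_density: float = 0.3
    sky_band_height: int = 60
    label_patch: tuple[int, int, int, int] | None = None  # (x0, y0, w, h)
    label_color: tuple[int, int, int] = LABEL_COLOR
    occlusion_fraction: float = 0.0
    center_bias_sd_frac: float = 0.22
    min_separation: float = 6.0  # gap between apple rims, px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.n_apples < 0:
            raise ValueError("n_apples must be >= 0")
        if not (0.0 <= self.occlusion_fraction < 1.0):
            raise ValueError("occlusion_fraction must be in [0, 1)")
        if self.apple_radius_mean <= 0:
            raise ValueError("apple_radius_mean must be positive")
        if self.sky_band_height < 0 or self.sky_band_height >= self.height:
            raise ValueError("sky_band_height must be in [0, height)")


@dataclass
class GazeSpec:
    """Statistical description of a synthetic gaze stream.

    ``calibration_shift`` is the constant offset every fixation shares within
    one stream (imperfect tracker calibration); ``jitter_sd`` is the isotropic
    per-sample noise on top of it.  ``saccade_samples`` scattered samples are
    emitted between consecutive fixations.
    """

    fps: float = 25.0
    fixation_duration_mean: float = 275.0
    fixation_duration_sd: float = 25.0
    calibration_shift: tuple[float, float] = (0.0, 0.0)
    jitter_sd: float = 2.0
    saccade_samples: int = 4
    max_shift: float = MAX_CALIBRATION_SHIFT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.fixation_duration_mean <= 0:
            raise ValueError("fixation_duration_mean must be positive")
        if math.hypot(*self.calibration_shift) > self.max_shift:
            raise ValueError(
                f"calibration shift {self.calibration_shift} exceeds max {self.max_shift}"
            )


@dataclass(frozen=True)
class FixationTruth:
    """Where the simulated viewer's recorded gaze actually dwelt.

    ``centroid`` is the apple centroid displaced by the calibration shift —
    the position an ideal fixation detector should recover from the stream.
    """

    centroid: tuple[float, float]
    duration_ms: float
    apple_index: int


@dataclass
class SceneTruth:
    """A rendered scene plus everything needed to score annotations of it."""

    image: np.ndarray  # uint8, (h, w, 3)
    gt_mask: np.ndarray  # bool, (h, w); visible apple pixels only
    apple_centroids: list[tuple[float, float]]  # geometric disk centers (x, y)
    apple_radii: list[float]
    spec: SceneSpec
    fixation_truth: list[FixationTruth] = field(default_factory=list)

    @property
    def frame_size(self) -> tuple[int, int]:
        return (self.image.shape[1], self.image.shape[0])


def _paint_background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    palette = np.asarray(spec.background_palette, dtype=float)

    # Leaf-scale color field: palette colors sampled on a grid finer than a
    # superpixel (~900 px) and bilinearly blended, so foliage color varies at
    # the scale of individual leaves, not of large uniform patches.
    cell = 16
    gh, gw = max(2, math.ceil(h / cell)), max(2, math.ceil(w / cell))
    coarse = palette[rng.integers(0, len(palette), size=(gh, gw))]
    img = np.stack(
        [_zoom(coarse[..., c], (h / gh, w / gw), order=1) for c in range(3)], axis=-1
    )
    img = img[:h, :w]

    # Branches/trunk: thin elongated dark strokes through the foliage.
    wood = np.asarray(spec.wood_palette, dtype=float)
    for _ in range(spec.n_branches):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(60, 220)  # semi-major: long
        b = rng.uniform(1.5, 4.0)  # semi-minor: twig-thin
        rot = rng.uniform(0, math.pi)
        color = wood[rng.integers(0, len(wood))] + rng.normal(0, 8, 3)
        rr, cc = _draw_ellipse(cy, cx, b, a, shape=(h, w), rotation=rot)
        img[rr, cc] = color

    # Leaf-like elliptical clutter, mostly foliage greens with occasional
    # dark wood fragments.
    mean_ellipse_area = 350.0
    n_ellipses = int(spec.clutter_density * w * h / mean_ellipse_area)
    for _ in range(n_ellipses):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(6, 18)  # semi-major
        b = rng.uniform(3, 9)
        rot = rng.uniform(0, math.pi)
        if rng.uniform() < 0.05:
            color = wood[rng.integers(0, len(wood))] + rng.normal(0, 8, 3)
        else:
            color = palette[rng.integers(0, len(palette))] + rng.normal(0, 15, 3)
        rr, cc = _draw_ellipse(cy, cx, b, a, shape=(h, w), rotation=rot)
        img[rr, cc] = color

    # Smooth sun/shade illumination across the canopy: strong frame-scale
    # contrast, but varying slowly enough to be nearly constant inside one
    # attention area.  Plus high-frequency speckle.
    gain = _zoom(rng.uniform(0.8, 1.2, size=(2, 2)), (h / 2, w / 2), order=1)
    img *= gain[:h, :w, None]
    img += rng.normal(0.0, 7.0, size=img.shape)

    if spec.sky_band_height > 0:
        band = np.asarray(SKY_COLOR, float) + rng.normal(
            0.0, 4.0, size=(spec.sky_band_height, w, 3)
        )
        img[: spec.sky_band_height] = band

    if spec.label_patch is not None:
        x0, y0, pw, ph = spec.label_patch
        img[y0 : y0 + ph, x0 : x0 + pw] = np.asarray(spec.label_color, float)

    return img


def _place_apples(
    spec: SceneSpec, rng: np.random.Generator
) -> tuple[list[tuple[float, float]], list[float]]:
    h, w = spec.height, spec.width
    sd = spec.center_bias_sd_frac * min(w, h)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for i in range(spec.n_apples):
        r = float(max(4.0, rng.normal(spec.apple_radius_mean, spec.apple_radius_sd)))
        y_lo = max(r, spec.sky_band_height + r)
        y_hi = h - 1 - r
        x_lo, x_hi = r, w - 1 - r
        if y_lo >= y_hi or x_lo >= x_hi:
            raise RuntimeError(
                f"image {w}x{h} too small to place apple of radius {r:.1f}"
            )
        placed = False
        for _ in range(500):
            cx = float(np.clip(rng.normal(w / 2.0, sd), x_lo, x_hi))
            cy = float(np.clip(rng.normal(h / 2.0, sd), y_lo, y_hi))
            ok = all(
                math.hypot(cx - px, cy - py) >= r + pr + spec.min_separation
                for (px, py), pr in zip(centers, radii)
            )
            if ok:
                centers.append((cx, cy))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place apple {i + 1}/{spec.n_apples} after 500 attempts; "
                f"image {w}x{h} too crowded"
            )
    return centers, radii


def _render_apple(
    img: np.ndarray,
    mask: np.ndarray,
    center: tuple[float, float],
    radius: float,
    color: np.ndarray,
    rng: np.random.Generator,
) -> None:
    h, w = mask.shape
    cx, cy = center
    rr, cc = _draw_disk((cy, cx), radius, shape=(h, w))
    rho = np.hypot(rr - cy, cc - cx) / radius
    # Radial shading so apples are not flat-colored; small specular highlight
    # offset toward the upper-left.
    shade = 0.72 + 0.28 * np.sqrt(np.clip(1.0 - rho**2, 0.0, 1.0))
    hx, hy = cx - 0.35 * radius, cy - 0.35 * radius
    gloss = 45.0 * np.exp(-((rr - hy) ** 2 + (cc - hx) ** 2) / (0.4 * radius) ** 2)
    img[rr, cc] = color[None, :] * shade[:, None] + gloss[:, None]
    img[rr, cc] += rng.normal(0.0, 3.0, size=(len(rr), 3))
    mask[rr, cc] = True


def _occlude(
    img: np.ndarray,
    apple_mask: np.ndarray,
    center: tuple[float, float],
    radius: float,
    spec: SceneSpec,
    rng: np.random.Generator,
) -> None:
    """Draw a foreground leaf over part of one apple (bounded coverage)."""
    h, w = apple_mask.shape
    area = int(apple_mask.sum())
    if area == 0:
        return
    palette = np.asarray(spec.background_palette, dtype=float)
    for _ in range(10):
        theta = rng.uniform(0, 2 * math.pi)
        ecy = center[1] + radius * 0.9 * math.sin(theta)
        ecx = center[0] + radius * 0.9 * math.cos(theta)
        a = radius * rng.uniform(0.5, 0.9)
        b = radius * rng.uniform(0.3, 0.6)
        rr, cc = _draw_ellipse(ecy, ecx, b, a, shape=(h, w), rotation=rng.uniform(0, math.pi))
        leaf = np.zeros_like(apple_mask)
        leaf[rr, cc] = True
        covered = (leaf & apple_mask).sum() / area
        if covered <= spec.occlusion_fraction:
            color = palette[rng.integers(0, len(palette))] + rng.normal(0, 10, 3)
            img[rr, cc] = color
            apple_mask &= ~leaf
            return


def generate_scene(spec: SceneSpec) -> SceneTruth:
    """Render one orchard-like frame with exact ground truth.

    Deterministic given ``spec.seed``.  Raises ``RuntimeError`` when the
    requested apples cannot be placed without touching (frame too small or
    too crowded).
    """
    rng = np.random.default_rng(spec.seed)
    img = _paint_background(spec, rng)
    centers, radii = _place_apples(spec, rng)

    apple_colors = np.asarray(spec.apple_colors, dtype=float)
    gt = np.zeros((spec.height, spec.width), dtype=bool)
    for center, radius in zip(centers, radii):
        base = apple_colors[rng.integers(0, len(apple_colors))]
        color = base + rng.normal(0.0, spec.apple_color_sd, 3)
        one = np.zeros_like(gt)
        _render_apple(img, one, center, radius, color, rng)
        if spec.occlusion_fraction > 0:
            _occlude(img, one, center, radius, spec, rng)
        gt |= one

    image = np.clip(img, 0, 255).astype(np.uint8)
    return SceneTruth(
        image=image,
        gt_mask=gt,
        apple_centroids=list(centers),
        apple_radii=list(radii),
        spec=spec,
    )


def generate_gaze(scene: SceneTruth, gspec: GazeSpec) -> list[GazeSample]:
    """Simulate the eye-tracker stream of a viewer finding every apple.

    The viewer fixates each apple once, in random order.  Each fixation emits
    ``round(fps * duration / 1000)`` consecutive samples at the apple centroid
    plus the calibration shift plus isotropic jitter; ``saccade_samples``
    scattered samples precede each fixation.  Samples are clamped to frame
    bounds and carry strictly increasing frame indices.

    Side effect: fills ``scene.fixation_truth`` with the intended (shifted)
    fixation centroids, one per apple, in visit order.
    """
    rng = np.random.default_rng(gspec.seed)
    w, h = scene.frame_size
    sx, sy = gspec.calibration_shift
    samples: list[GazeSample] = []
    scene.fixation_truth = []
    frame = 0

    def emit(x: float, y: float) -> None:
        nonlocal frame
        samples.append(
            GazeSample(
                frame_index=frame,
                t_ms=frame * 1000.0 / gspec.fps,
                x=float(np.clip(x, 0, w - 1)),
                y=float(np.clip(y, 0, h - 1)),
                valid=True,
            )
        )
        frame += 1

    order = rng.permutation(len(scene.apple_centroids))
    for apple_idx in order:
        for _ in range(gspec.saccade_samples):
            emit(rng.uniform(0, w - 1), rng.uniform(0, h - 1))
        cx, cy = scene.apple_centroids[apple_idx]
        tx, ty = cx + sx, cy + sy
        duration = gspec.fixation_duration_mean
        if gspec.fixation_duration_sd > 0:
            duration = max(40.0, rng.normal(duration, gspec.fixation_duration_sd))
        n = max(1, round(gspec.fps * duration / 1000.0))
        for _ in range(n):
            jx, jy = (
                rng.normal(0.0, gspec.jitter_sd, 2) if gspec.jitter_sd > 0 else (0.0, 0.0)
            )
            emit(tx + jx, ty + jy)
        scene.fixation_truth.append(
            FixationTruth(
                centroid=(tx, ty), duration_ms=duration, apple_index=int(apple_idx)
            )
        )
    return samples
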