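"""Non-supervised apple segmentation inside attention areas.

The pipeline core: each attention area is partitioned into SLIC superpixels
whose number N = round(A / S) scales with the area size A so that one
superpixel stays about the size S of an average apple (900 px).  Blueish
superpixels (sky, blue tree labels) are removed by a relational color rule,
the rest are clustered with K-means (K = 2) on per-superpixel mean
(R, G, B, H, S) features, and the cluster occupying the smaller pixel area is
taken as the apples — the background is assumed to dominate the area.
Selected superpixels are mapped back to frame coordinates and unioned into a
per-frame binary mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.segmentation import slic
from skimage.util import img_as_float
from sklearn.cluster import KMeans

from .gaze import AttentionArea

__all__ = [
    "SegmentationParams",
    "SuperpixelPatch",
    "BinaryMask",
    "superpixel_count",
    "segment_superpixels",
    "remove_blue",
    "cluster_select",
    "assemble_mask",
    "annotate_frame",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the superpixel + clustering stage.

    apple_size : int
        S, the pixel area of an average apple (30 px diameter -> ~900 px);
        sets the superpixel scale via N = round(A / S).
    k_clusters : int
        K for K-means; 2 separates apples from background when blue parts
        are removed first and no green apples are present.
    blue_margin : int
        8-bit margin of the blue-removal rule: a superpixel is discarded
        when its mean blue exceeds both mean red and mean green by more
        than this margin.
    hue_wrap : bool
        Encode hue as (cos, sin) instead of the raw [0, 1] value, avoiding
        the red wrap-around discontinuity.  Off by default.
    """

    apple_size: int = 900
    k_clusters: int = 2
    blue_margin: int = 10
    slic_compactness: float = 20.0
    kmeans_restarts: int = 10
    hue_wrap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.apple_size <= 0:
            raise ValueError("apple_size must be positive")
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")


@dataclass
class SuperpixelPatch:
    """A superpixel partition of one attention area with per-segment features.

    ``labels`` is an integer raster over the patch with values 0..n-1;
    ``features`` holds one row per superpixel (mean R, G, B, H, S in [0, 1],
    or 6 columns with hue encoded as cos/sin); ``excluded`` flags superpixels
    removed as blue (sky / tree label).  ``degenerate`` marks an all-constant
    patch that SLIC collapsed to a single segment.
    """

    labels: np.ndarray
    n_superpixels: int
    features: np.ndarray
    pixel_counts: np.ndarray
    excluded: np.ndarray
    blue_fraction: np.ndarray | None = None  # per-superpixel share of blue pixels
    degenerate: bool = False

    @property
    def mean_rgb255(self) -> np.ndarray:
        """Per-superpixel mean (R, G, B) on the 8-bit scale."""
        return self.features[:, :3] * 255.0


@dataclass
class BinaryMask:
    """A predicted apple mask at frame resolution with its provenance."""

    raster: np.ndarray  # bool, (h, w)
    areas: list[AttentionArea]

    @property
    def frame_size(self) -> tuple[int, int]:
        return (self.raster.shape[1], self.raster.shape[0])


def superpixel_count(area_pixels: int, apple_size: int = 900) -> int:
    """Number of superpixels N = A / S, rounded, clamped to at least 2.

    Keeping N proportional to the area keeps the superpixel size close to
    one average apple regardless of the attention strategy.
    """
    if area_pixels <= 0 or apple_size <= 0:
        raise ValueError("area_pixels and apple_size must be positive")
    return max(2, round(area_pixels / apple_size))


def _patch_features(
    patch: np.ndarray, labels: np.ndarray, n: int, hue_wrap: bool, blue_margin: float = 10.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rgb = img_as_float(patch)
    hsv = rgb2hsv(rgb)
    idx = np.arange(n)
    chans = [rgb[..., 0], rgb[..., 1], rgb[..., 2]]
    if hue_wrap:
        hue = hsv[..., 0] * 2 * np.pi
        chans += [0.5 * (np.cos(hue) + 1), 0.5 * (np.sin(hue) + 1)]
    else:
        chans.append(hsv[..., 0])
    chans.append(hsv[..., 1])
    feats = np.column_stack(
        [ndimage.mean(c, labels=labels, index=idx) for c in chans]
    )
    counts = np.bincount(labels.ravel(), minlength=n).astype(np.int64)
    m = blue_margin / 255.0
    blue_px = (rgb[..., 2] > rgb[..., 0] + m) & (rgb[..., 2] > rgb[..., 1] + m)
    blue_frac = ndimage.mean(blue_px.astype(float), labels=labels, index=idx)
    return feats, counts, np.asarray(blue_frac)


def segment_superpixels(
    patch_image: np.ndarray, n_segments: int, params: SegmentationParams
) -> SuperpixelPatch:
    """SLIC-partition an attention-area crop into about ``n_segments`` pieces.

    SLIC runs on CIELab with the configured compactness; the achieved count
    can deviate from the request (SLIC merges tiny segments).  A constant
    patch collapses to a single segment and is flagged ``degenerate``.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    patch = np.ascontiguousarray(patch_image)
    if np.ptp(patch) == 0:  # constant patch: SLIC has no gradients to follow
        labels = np.zeros(patch.shape[:2], dtype=int)
        feats, counts, bfrac = _patch_features(
            patch, labels, 1, params.hue_wrap, params.blue_margin
        )
        return SuperpixelPatch(
            labels=labels,
            n_superpixels=1,
            features=feats,
            pixel_counts=counts,
            excluded=np.zeros(1, dtype=bool),
            blue_fraction=bfrac,
            degenerate=True,
        )
    labels = slic(
        patch,
        n_segments=n_segments,
        compactness=params.slic_compactness,
        start_label=0,
        convert2lab=True,
        enforce_connectivity=True,
        # keep segments down to ~1/4 of the nominal superpixel size: objects
        # somewhat smaller than an average apple must not be absorbed into a
        # background superpixel by the connectivity post-merge, while frag-
        # ments well below object scale (twigs, single leaves) still merge
        min_size_factor=0.25,
    )
    # Relabel densely in case SLIC skipped ids.
    uniq, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(patch.shape[:2])
    n = len(uniq)
    feats, counts, bfrac = _patch_features(
        patch, labels, n, params.hue_wrap, params.blue_margin
    )
    return SuperpixelPatch(
        labels=labels,
        n_superpixels=n,
        features=feats,
        pixel_counts=counts,
        excluded=np.zeros(n, dtype=bool),
        blue_fraction=bfrac,
        degenerate=(n == 1),
    )


def remove_blue(patch: SuperpixelPatch, blue_margin: int = 10) -> SuperpixelPatch:
    """Flag blueish superpixels (sky, blue tree labels) as excluded.

    Relational rule on 8-bit mean colors: excluded when
    B > R + margin and B > G + margin.  Superpixels straddling a sky/canopy
    boundary can have a green-looking mean despite being half sky, so a
    superpixel is also excluded when at least half of its individual pixels
    satisfy the same relational rule.  Excluded superpixels never enter
    clustering and never contribute to the apple mask.
    """
    rgb = patch.mean_rgb255
    blue = (rgb[:, 2] > rgb[:, 0] + blue_margin) & (rgb[:, 2] > rgb[:, 1] + blue_margin)
    if patch.blue_fraction is not None:
        blue |= patch.blue_fraction >= 0.5
    patch.excluded = patch.excluded | blue
    return patch


def cluster_select(patch: SuperpixelPatch, params: SegmentationParams) -> set[int]:
    """K-means the non-excluded superpixels and keep the smaller cluster.

    Features are clustered with K clusters (squared-Euclidean, k-means++
    init, ``kmeans_restarts`` restarts, fixed seed); the cluster with the
    smallest *total pixel area* is returned as the apple superpixels, on the
    assumption that background occupies most of the attention area.  Ties go
    to the cluster with the higher mean saturation (apples are saturated).
    Fewer than 2 candidate superpixels yield an empty selection.
    """
    keep = np.flatnonzero(~patch.excluded)
    if len(keep) < params.k_clusters:
        warnings.warn(
            f"only {len(keep)} non-excluded superpixels; skipping clustering",
            stacklevel=2,
        )
        return set()
    feats = patch.features[keep]
    km = KMeans(
        n_clusters=params.k_clusters,
        n_init=max(1, params.kmeans_restarts),
        random_state=params.seed,
    )
    assign = km.fit_predict(feats)
    counts = patch.pixel_counts[keep]
    areas = np.array(
        [counts[assign == k].sum() for k in range(params.k_clusters)], dtype=np.int64
    )
    smallest = areas.min()
    tied = np.flatnonzero(areas == smallest)
    if len(tied) == 1:
        pick = tied[0]
    else:
        sat_col = patch.features.shape[1] - 1  # saturation is the last feature
        mean_sat = [patch.features[keep[assign == k], sat_col].mean() for k in tied]
        pick = tied[int(np.argmax(mean_sat))]
    return {int(s) for s in keep[assign == pick]}


def assemble_mask(
    areas: list[AttentionArea],
    patches: list[SuperpixelPatch],
    selections: list[set[int]],
    frame_size: tuple[int, int],
) -> BinaryMask:
    """Union the selected superpixels of every area into one frame mask.

    Overlapping areas combine by logical OR; excluded superpixels never set
    a pixel.
    """
    if not (len(areas) == len(patches) == len(selections)):
        raise ValueError("areas, patches and selections must align")
    w, h = frame_size
    raster = np.zeros((h, w), dtype=bool)
    for area, patch, selected in zip(areas, patches, selections):
        if not selected:
            continue
        x0, y0, x1, y1 = area.box
        picked = np.isin(patch.labels, sorted(selected))
        raster[y0:y1, x0:x1] |= picked
    return BinaryMask(raster=raster, areas=list(areas))


def annotate_frame(
    image: np.ndarray,
    areas: list[AttentionArea],
    params: SegmentationParams | None = None,
) -> tuple[BinaryMask, list[SuperpixelPatch], list[set[int]]]:
    """Run the full segmentation stage over one frame's attention areas.

    Returns the assembled frame mask plus the per-area superpixel patches
    and selections for debugging/inspection.
    """
    params = params or SegmentationParams()
    h, w = image.shape[:2]
    patches: list[SuperpixelPatch] = []
    selections: list[set[int]] = []
    for area in areas:
        crop = area.crop(image)
        n = superpixel_count(area.area_pixels, params.apple_size)
        patch = segment_superpixels(crop, n, params)
        patch = remove_blue(patch, params.blue_margin)
        if patch.degenerate:
            selections.append(set())
            patches.append(patch)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selections.append(cluster_select(patch, params))
        patches.append(patch)
    mask = assemble_mask(areas, patches, selections, (w, h))
    return mask, patches, selections
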