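"""Attention-area strategies that do not need an eye-tracker.

Three baselines under the same ``AttentionArea`` contract as the gaze-driven
strategy: the whole frame, a fixed square at the frame center (the egocentric
prior: objects of interest tend to sit where the wearer points the camera),
and bottom-up color saliency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab
from skimage.filters import gaussian
from skimage.util import img_as_float

from .gaze import AttentionArea, build_attention_area

__all__ = [
    "SaliencyParams",
    "full_frame_area",
    "center_prior_area",
    "compute_saliency",
    "saliency_areas",
]


@dataclass(frozen=True)
class SaliencyParams:
    blur_sigma: float = 5.0
    threshold_factor: float = 2.0  # multiplier on the mean saliency
    min_component_area: int = 100
    side: int = 180

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")
        if self.min_component_area < 1:
            raise ValueError("min_component_area must be >= 1")


def full_frame_area(frame_size: tuple[int, int]) -> AttentionArea:
    """The degenerate strategy: the whole frame is the attention area."""
    w, h = frame_size
    return AttentionArea(
        center=(w / 2.0, h / 2.0), box=(0, 0, w, h), source="full_frame", side=None
    )


def center_prior_area(frame_size: tuple[int, int], side: int = 180) -> AttentionArea:
    """One fixed square at the frame center (egocentric center prior)."""
    w, h = frame_size
    return build_attention_area(
        (w // 2, h // 2), frame_size, side=side, source="center_prior"
    )


def compute_saliency(image: np.ndarray, blur_sigma: float = 5.0) -> np.ndarray:
    """Frequency-tuned color saliency in [0, 1].

    Per-pixel Euclidean distance, in CIELab, between the image's global mean
    color and the Gaussian-blurred pixel color.  Regions whose color stands
    out against the global appearance score high; a constant image scores
    zero everywhere.
    """
    lab = rgb2lab(img_as_float(image))
    mean = lab.reshape(-1, 3).mean(axis=0)
    blurred = gaussian(lab, sigma=blur_sigma, channel_axis=-1)
    sal = np.sqrt(((blurred - mean[None, None, :]) ** 2).sum(axis=-1))
    peak = sal.max()
    if peak > 1e-8:  # a constant image has no salient contrast at all
        sal = sal / peak
    else:
        sal = np.zeros_like(sal)
    return sal


def saliency_areas(image: np.ndarray, params: SaliencyParams) -> list[AttentionArea]:
    """Fixed-size areas centered on salient blobs.

    The saliency map is thresholded at ``threshold_factor`` times its mean,
    components below ``min_component_area`` are dropped, and each surviving
    component yields one ``side x side`` area at its centroid (clamped to the
    frame).  An empty list is a valid outcome (nothing salient).
    """
    h, w = image.shape[:2]
    sal = compute_saliency(image, blur_sigma=params.blur_sigma)
    binary = sal > params.threshold_factor * sal.mean()
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    areas: list[AttentionArea] = []
    if n == 0:
        return areas
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    centroids = ndimage.center_of_mass(binary, labels, index=np.arange(1, n + 1))
    for size, (cy, cx) in zip(sizes, centroids):
        if size < params.min_component_area:
            continue
        areas.append(
            build_attention_area((cx, cy), (w, h), side=params.side, source="saliency")
        )
    return areas
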