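"""Gaze-stream processing: fixation detection and attention-area construction.

A head-mounted eye-tracker emits a per-frame stream of gaze coordinates.
Samples that rest on one spot for long enough form a *fixation*; the frame
interval a fixation must span is ``floor(fps * duration / 1000)`` (25 fps and
a 275 ms visual-search fixation give 6 frames).  Around each fixation
centroid a fixed-size square *attention area* is cut out of the frame; the
area is deliberately larger than the gazed object so that the systematic
calibration shift of the tracker does not push the object outside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GazeSample",
    "FixationParams",
    "Fixation",
    "AttentionArea",
    "fixation_frame_interval",
    "detect_fixations",
    "build_attention_area",
    "areas_from_gaze",
    "fixation_heatmap",
    "read_gaze_csv",
    "write_gaze_csv",
]

GAZE_CSV_COLUMNS = ["frame", "t_ms", "x", "y", "valid"]


@dataclass(frozen=True)
class GazeSample:
    """One raw gaze coordinate tied to a video frame.

    ``x`` is the column and ``y`` the row, 0-based, in frame pixels.
    """

    frame_index: int
    t_ms: float
    x: float
    y: float
    valid: bool = True


@dataclass(frozen=True)
class FixationParams:
    """Parameters of the fixation-detection rule.

    fps : float
        Frame rate of the stream (head-mounted tracker: 25, screen-based: 60).
    fixation_duration_ms : float
        Minimum dwell time for a fixation; 275 ms is the mean fixation
        duration in visual-search tasks.
    dispersion_radius : float
        Grouping tolerance in pixels: a sample extends the current run when
        it lies within this radius of the running centroid.  Default 15 px,
        half the mean apple diameter.
    """

    fps: float = 25.0
    fixation_duration_ms: float = 275.0
    dispersion_radius: float = 15.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.fixation_duration_ms <= 0:
            raise ValueError(
                f"fixation_duration_ms must be positive, got {self.fixation_duration_ms}"
            )
        if self.dispersion_radius < 0:
            raise ValueError("dispersion_radius must be non-negative")


@dataclass(frozen=True)
class Fixation:
    """A detected fixation: centroid of a stable run of gaze samples."""

    centroid: tuple[float, float]
    start_frame: int
    end_frame: int
    n_samples: int


@dataclass(frozen=True)
class AttentionArea:
    """A rectangular region of interest in frame coordinates.

    ``box`` is half-open, ``(x0, y0, x1, y1)`` with ``x`` = column and
    ``y`` = row; the box always lies fully inside the frame.  ``source``
    records the strategy that produced the area.
    """

    center: tuple[float, float]
    box: tuple[int, int, int, int]
    source: str = "gaze"
    side: int | None = None

    @property
    def width(self) -> int:
        return self.box[2] - self.box[0]

    @property
    def height(self) -> int:
        return self.box[3] - self.box[1]

    @property
    def area_pixels(self) -> int:
        """Area A of the region, the numerator of the superpixel-count rule."""
        return self.width * self.height

    def crop(self, image: np.ndarray) -> np.ndarray:
        x0, y0, x1, y1 = self.box
        return image[y0:y1, x0:x1]

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.box
        return x0 <= x < x1 and y0 <= y < y1


def fixation_frame_interval(params: FixationParams) -> int:
    """Number of consecutive frames a fixation must span, f_i = Fps * f_d.

    The product is floored (25 fps x 275 ms -> 6 frames) and clamped to at
    least one frame.
    """
    f_i = math.floor(params.fps * params.fixation_duration_ms / 1000.0)
    return max(1, f_i)


def detect_fixations(
    samples: Sequence[GazeSample], params: FixationParams
) -> list[Fixation]:
    """Group a gaze stream into fixations by dispersion-based run growing.

    Valid samples are scanned in order; a sample within ``dispersion_radius``
    of the running centroid extends the current run, otherwise the run is
    closed and a new one starts.  Runs of at least ``fixation_frame_interval``
    samples become fixations; shorter runs (saccades, tracker noise) are
    discarded.  Invalid samples are ignored entirely.
    """
    f_i = fixation_frame_interval(params)
    fixations: list[Fixation] = []

    run_x: list[float] = []
    run_y: list[float] = []
    run_frames: list[int] = []

    def close_run() -> None:
        if len(run_x) >= f_i:
            fixations.append(
                Fixation(
                    centroid=(float(np.mean(run_x)), float(np.mean(run_y))),
                    start_frame=run_frames[0],
                    end_frame=run_frames[-1],
                    n_samples=len(run_x),
                )
            )
        run_x.clear()
        run_y.clear()
        run_frames.clear()

    for s in samples:
        if not s.valid:
            continue
        if run_x:
            cx = sum(run_x) / len(run_x)
            cy = sum(run_y) / len(run_y)
            if math.hypot(s.x - cx, s.y - cy) > params.dispersion_radius:
                close_run()
        run_x.append(s.x)
        run_y.append(s.y)
        run_frames.append(s.frame_index)
    close_run()
    return fixations


def build_attention_area(
    center: tuple[float, float],
    frame_size: tuple[int, int],
    side: int = 180,
    source: str = "gaze",
) -> AttentionArea:
    """Cut a ``side``-by-``side`` square around ``center``.

    When the centered square would overflow the frame it is translated back
    inside rather than shrunk, so every area has the same pixel count and the
    superpixel scale stays constant across areas.
    """
    w, h = frame_size
    if side > w or side > h:
        raise ValueError(f"side {side} exceeds frame size {frame_size}")
    if side <= 0:
        raise ValueError("side must be positive")
    cx, cy = center
    x0 = int(round(cx - side / 2.0))
    y0 = int(round(cy - side / 2.0))
    x0 = min(max(x0, 0), w - side)
    y0 = min(max(y0, 0), h - side)
    return AttentionArea(
        center=(float(cx), float(cy)),
        box=(x0, y0, x0 + side, y0 + side),
        source=source,
        side=side,
    )


def areas_from_gaze(
    samples: Sequence[GazeSample],
    params: FixationParams,
    frame_size: tuple[int, int],
    side: int = 180,
    source: str = "gaze",
) -> list[AttentionArea]:
    """Detect fixations and build one attention area per fixation centroid."""
    return [
        build_attention_area(fx.centroid, frame_size, side, source=source)
        for fx in detect_fixations(samples, params)
    ]


def fixation_heatmap(
    fixations: Sequence[Fixation],
    frame_size: tuple[int, int],
    sigma: float = 20.0,
) -> np.ndarray:
    """Accumulated Gaussian splat per fixation, weighted by sample count.

    Returns a float raster in [0, 1] (all-zero when there are no fixations),
    the usual visualisation of where the viewer's attention dwelt.
    """
    from scipy.ndimage import gaussian_filter

    w, h = frame_size
    acc = np.zeros((h, w), dtype=float)
    for fx in fixations:
        x = min(max(int(round(fx.centroid[0])), 0), w - 1)
        y = min(max(int(round(fx.centroid[1])), 0), h - 1)
        acc[y, x] += fx.n_samples
    if acc.any():
        acc = gaussian_filter(acc, sigma=sigma)
        acc /= acc.max()
    return acc


def write_gaze_csv(samples: Sequence[GazeSample], path) -> None:
    """Write a gaze stream as CSV with header ``frame,t_ms,x,y,valid``."""
    df = pd.DataFrame(
        {
            "frame": [s.frame_index for s in samples],
            "t_ms": [s.t_ms for s in samples],
            "x": [s.x for s in samples],
            "y": [s.y for s in samples],
            "valid": [int(s.valid) for s in samples],
        }
    )
    df.to_csv(path, index=False)


def read_gaze_csv(path) -> list[GazeSample]:
    df = pd.read_csv(path)
    missing = [c for c in GAZE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze CSV {path} missing columns {missing}")
    return [
        GazeSample(
            frame_index=int(r.frame),
            t_ms=float(r.t_ms),
            x=float(r.x),
            y=float(r.y),
            valid=bool(r.valid),
        )
        for r in df.itertuples(index=False)
    ]
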