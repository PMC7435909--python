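"""Scoring of predicted apple masks against ground truth.

Three families of statistics, all at frame resolution:

* segmentation — Dice ``2|X∩Y|/(|X|+|Y|)`` and Jaccard ``|X∩Y|/|X∪Y|``
  between the predicted mask X and the ground-truth mask Y;
* counting — connected components of X are matched to components of Y; a
  predicted object is a true positive when its overlap fraction with its
  best ground-truth partner reaches the threshold (default 75%), giving the
  probability of good detection PD = TP/(TP+FN) and the true-negative rate
  TNR = TN/(TN+FP);
* localization — the mean Euclidean distance between centroids of matched
  predicted and ground-truth objects (the shift error), restricted to pairs
  above the same 75% overlap.

True negatives are not well defined for object detection; here an attention
area that contains no ground-truth pixels and contributes no predicted
component counts as one TN, and every report flags this convention.
Ground-truth objects never covered by any attention area were never gazed
at; they are excluded from FN and reported separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .gaze import AttentionArea
from .segmentation import BinaryMask

__all__ = [
    "MatchParams",
    "ObjectMatch",
    "MatchResult",
    "MetricsReport",
    "dice",
    "jaccard",
    "match_objects",
    "counting_metrics",
    "shift_error",
    "evaluate_run",
]

_STRUCT8 = np.ones((3, 3), dtype=int)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def _as_bool(mask) -> np.ndarray:
    raster = mask.raster if isinstance(mask, BinaryMask) else np.asarray(mask)
    return raster.astype(bool)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")


@dataclass(frozen=True)
class MatchParams:
    """Object-matching rules.

    ``overlap_mode`` picks the denominator of the overlap fraction:
    ``pred`` (|X∩Y|/|X| — how much of the predicted object is real apple),
    ``gt``, ``min`` or ``iou``.  ``connectivity`` is 4 or 8 for component
    extraction.
    """

    overlap_threshold: float = 0.75
    overlap_mode: str = "pred"
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_threshold <= 1.0):
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.overlap_mode not in {"pred", "gt", "min", "iou"}:
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def structure(self) -> np.ndarray:
        return _STRUCT8 if self.connectivity == 8 else _STRUCT4


@dataclass(frozen=True)
class ObjectMatch:
    """One predicted component paired with its best ground-truth component."""

    pred_id: int
    gt_id: int | None
    overlap_fraction: float
    pred_centroid: tuple[float, float]  # (x, y)
    gt_centroid: tuple[float, float] | None
    distance: float | None
    matched: bool  # overlap_fraction >= threshold


@dataclass
class MatchResult:
    matches: list[ObjectMatch]
    tp: int
    fp: int
    fn: int
    tn: int
    excluded_gt: int  # ground-truth objects never covered by an attention area


def dice(x, y) -> float:
    """Dice coefficient 2|X∩Y| / (|X|+|Y|); 1 when both masks are empty."""
    xb, yb = _as_bool(x), _as_bool(y)
    _check_shapes(xb, yb)
    nx, ny = int(xb.sum()), int(yb.sum())
    if nx + ny == 0:
        return 1.0
    inter = int((xb & yb).sum())
    return 2.0 * inter / (nx + ny)


def jaccard(x, y) -> float:
    """Jaccard index |X∩Y| / |X∪Y|; 1 when both masks are empty."""
    xb, yb = _as_bool(x), _as_bool(y)
    _check_shapes(xb, yb)
    union = int((xb | yb).sum())
    if union == 0:
        return 1.0
    inter = int((xb & yb).sum())
    return inter / union


def _centroid(labels: np.ndarray, index: int) -> tuple[float, float]:
    ys, xs = np.nonzero(labels == index)
    return (float(xs.sum()) / len(xs), float(ys.sum()) / len(ys))


def _area_union(
    areas: Sequence[AttentionArea] | None, shape: tuple[int, int]
) -> np.ndarray:
    union = np.zeros(shape, dtype=bool)
    if areas is None:
        union[:] = True
        return union
    for a in areas:
        x0, y0, x1, y1 = a.box
        union[y0:y1, x0:x1] = True
    return union


def match_objects(
    pred,
    gt,
    attention_areas: Sequence[AttentionArea] | None = None,
    params: MatchParams | None = None,
) -> MatchResult:
    """Component-level matching of a predicted mask against ground truth.

    Each predicted component is paired with the ground-truth component of
    maximum intersection (ties broken toward the lower component id); the
    pair is a TP when the overlap fraction reaches the threshold, otherwise
    the predicted component is an FP.  Ground-truth components covered by
    the attention areas (at least half their pixels) but with no TP partner
    are FN; ground truth outside every area is excluded and only counted in
    ``excluded_gt``.  Each attention area containing neither ground truth
    nor prediction contributes one TN.  ``attention_areas=None`` treats the
    whole frame as a single area.
    """
    params = params or MatchParams()
    predb, gtb = _as_bool(pred), _as_bool(gt)
    _check_shapes(predb, gtb)

    pred_lab, n_pred = ndimage.label(predb, structure=params.structure)
    gt_lab, n_gt = ndimage.label(gtb, structure=params.structure)

    matches: list[ObjectMatch] = []
    matched_gt: set[int] = set()
    tp = fp = 0
    for i in range(1, n_pred + 1):
        comp = pred_lab == i
        comp_size = int(comp.sum())
        overlaps = np.bincount(gt_lab[comp], minlength=n_gt + 1)
        overlaps[0] = 0
        best_j = int(np.argmax(overlaps)) if n_gt else 0
        inter = int(overlaps[best_j]) if best_j else 0
        pred_c = _centroid(pred_lab, i)
        if best_j == 0 or inter == 0:
            matches.append(
                ObjectMatch(i, None, 0.0, pred_c, None, None, matched=False)
            )
            fp += 1
            continue
        gt_size = int((gt_lab == best_j).sum())
        if params.overlap_mode == "pred":
            frac = inter / comp_size
        elif params.overlap_mode == "gt":
            frac = inter / gt_size
        elif params.overlap_mode == "min":
            frac = inter / min(comp_size, gt_size)
        else:  # iou
            frac = inter / (comp_size + gt_size - inter)
        gt_c = _centroid(gt_lab, best_j)
        d = float(np.hypot(pred_c[0] - gt_c[0], pred_c[1] - gt_c[1]))
        ok = frac >= params.overlap_threshold
        matches.append(ObjectMatch(i, best_j, float(frac), pred_c, gt_c, d, matched=ok))
        if ok:
            tp += 1
            matched_gt.add(best_j)
        else:
            fp += 1

    union = _area_union(attention_areas, predb.shape)
    fn = 0
    excluded_gt = 0
    for j in range(1, n_gt + 1):
        comp = gt_lab == j
        covered = int((comp & union).sum()) / int(comp.sum())
        if covered < 0.5:
            excluded_gt += 1
        elif j not in matched_gt:
            fn += 1

    if attention_areas is None:
        tn = int(not gtb.any() and not predb.any())
    else:
        tn = 0
        for a in attention_areas:
            x0, y0, x1, y1 = a.box
            if not gtb[y0:y1, x0:x1].any() and not predb[y0:y1, x0:x1].any():
                tn += 1

    return MatchResult(
        matches=matches, tp=tp, fp=fp, fn=fn, tn=tn, excluded_gt=excluded_gt
    )


def counting_metrics(
    tp: int, fp: int, fn: int, tn: int
) -> tuple[float | None, float | None]:
    """PD = TP/(TP+FN) and TNR = TN/(TN+FP); ``None`` when undefined."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    pd_ = tp / (tp + fn) if (tp + fn) > 0 else None
    tnr = tn / (tn + fp) if (tn + fp) > 0 else None
    return pd_, tnr


def shift_error(
    matches: Sequence[ObjectMatch],
) -> tuple[float | None, float | None]:
    """Mean and sd of centroid distances over matched pairs (>= threshold).

    The distance d(x_i, y_j) is the Euclidean distance between the centroid
    of a predicted object and the centroid of its maximum-intersection
    ground-truth partner; the mean over sufficiently overlapping pairs is
    the localization shift error.  ``(None, None)`` when nothing matched.
    """
    ds = [m.distance for m in matches if m.matched and m.distance is not None]
    if not ds:
        return None, None
    arr = np.asarray(ds, dtype=float)
    return float(arr.mean()), float(arr.std())


@dataclass
class MetricsReport:
    """Per-image, per-group and overall annotation-quality statistics.

    ``per_image`` holds one row per image (dice, jaccard, counts, pd, tnr,
    shift error); group rows average images within a group (a tree), and
    the overall row averages the group means, matching how multi-tree
    results are usually tabulated.  Pooled counts across all images give
    ``pooled_pd`` / ``pooled_tnr``, which are better behaved than averaging
    ratios over images with tiny denominators.
    """

    per_image: pd.DataFrame
    per_group: pd.DataFrame
    overall: dict
    pooled: dict
    config: dict = field(default_factory=dict)
    tn_definition: str = (
        "one TN per attention area containing neither ground-truth nor "
        "predicted pixels"
    )

    def to_json(self, path=None) -> str:
        per_group = self.per_group.copy()
        if per_group.columns.nlevels > 1:
            per_group.columns = ["_".join(c) for c in per_group.columns]
        payload = {
            "overall": self.overall,
            "pooled": self.pooled,
            "per_group": per_group.reset_index().to_dict(orient="records"),
            "per_image": self.per_image.reset_index().to_dict(orient="records"),
            "tn_definition": self.tn_definition,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        self.per_image.to_csv(path)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def evaluate_run(
    pred_masks: dict,
    gt_masks: dict,
    groups: dict | None = None,
    areas: dict | None = None,
    params: MatchParams | None = None,
    config: dict | None = None,
) -> MetricsReport:
    """Score a whole run: paired masks keyed by image id.

    ``groups`` maps image id to a group label (e.g. tree id); ``areas`` maps
    image id to that image's attention areas (``None`` entries mean whole
    frame).  Raises on ids present on one side only.
    """
    params = params or MatchParams()
    pred_ids, gt_ids = set(pred_masks), set(gt_masks)
    if pred_ids != gt_ids:
        missing = sorted(pred_ids ^ gt_ids)
        raise ValueError(f"unpaired mask ids: {missing}")

    rows = []
    for img_id in sorted(pred_masks):
        p, g = pred_masks[img_id], gt_masks[img_id]
        a = areas.get(img_id) if areas else None
        res = match_objects(p, g, attention_areas=a, params=params)
        pd_, tnr = counting_metrics(res.tp, res.fp, res.fn, res.tn)
        sh_mean, sh_sd = shift_error(res.matches)
        rows.append(
            {
                "image": img_id,
                "group": groups.get(img_id, img_id) if groups else img_id,
                "dice": dice(p, g),
                "jaccard": jaccard(p, g),
                "tp": res.tp,
                "fp": res.fp,
                "fn": res.fn,
                "tn": res.tn,
                "excluded_gt": res.excluded_gt,
                "pd": pd_,
                "tnr": tnr,
                "shift_error": sh_mean,
                "shift_error_sd": sh_sd,
            }
        )
    per_image = pd.DataFrame(rows).set_index("image")

    metric_cols = ["dice", "jaccard", "pd", "tnr", "shift_error"]
    per_group = per_image.groupby("group")[metric_cols].agg(["mean", "std"])

    group_means = per_image.groupby("group")[metric_cols].mean()
    overall = {}
    for c in metric_cols:
        vals = group_means[c].dropna()
        overall[f"{c}_mean"] = float(vals.mean()) if len(vals) else None
        overall[f"{c}_sd"] = float(vals.std(ddof=0)) if len(vals) else None

    tot = per_image[["tp", "fp", "fn", "tn", "excluded_gt"]].sum()
    pooled_pd, pooled_tnr = counting_metrics(
        int(tot.tp), int(tot.fp), int(tot.fn), int(tot.tn)
    )
    all_dist = per_image["shift_error"].dropna()
    pooled = {
        "tp": int(tot.tp),
        "fp": int(tot.fp),
        "fn": int(tot.fn),
        "tn": int(tot.tn),
        "excluded_gt": int(tot.excluded_gt),
        "pd": pooled_pd,
        "tnr": pooled_tnr,
        "shift_error_mean": float(all_dist.mean()) if len(all_dist) else None,
    }
    return MetricsReport(
        per_image=per_image,
        per_group=per_group,
        overall=overall,
        pooled=pooled,
        config=dict(config or {}) | {"match_params": asdict(params)},
    )
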