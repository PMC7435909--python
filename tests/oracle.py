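"""Naive brute-force reference implementations of the evaluation statistics.

Everything here is written directly from the metric definitions with plain
Python loops — per-pixel counting, BFS component labeling, centroid sums —
so it shares no code path with the package and can serve as an independent
check on small masks.
"""

from __future__ import annotations

import numpy as np


def pixel_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    """(|X|, |Y|, |X∩Y|, |X∪Y|) by explicit double loop."""
    nx = ny = ninter = nunion = 0
    h, w = x.shape
    for i in range(h):
        for j in range(w):
            a, b = bool(x[i, j]), bool(y[i, j])
            nx += a
            ny += b
            ninter += a and b
            nunion += a or b
    return nx, ny, ninter, nunion


def dice_naive(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny, inter, _ = pixel_counts(x, y)
    if nx + ny == 0:
        return 1.0
    return 2.0 * inter / (nx + ny)


def jaccard_naive(x: np.ndarray, y: np.ndarray) -> float:
    _, _, inter, union = pixel_counts(x, y)
    if union == 0:
        return 1.0
    return inter / union


def label_naive(mask: np.ndarray, connectivity: int = 8) -> list[set[tuple[int, int]]]:
    """Connected components as pixel sets, BFS, raster-scan discovery order."""
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps: list[set[tuple[int, int]]] = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j] or seen[i, j]:
                continue
            comp = set()
            queue = [(i, j)]
            seen[i, j] = True
            while queue:
                ci, cj = queue.pop()
                comp.add((ci, cj))
                for di, dj in nbrs:
                    ni, nj = ci + di, cj + dj
                    if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        queue.append((ni, nj))
            comps.append(comp)
    return comps


def centroid_naive(comp: set[tuple[int, int]]) -> tuple[float, float]:
    """(x, y) = (mean column, mean row) via integer sums."""
    sx = sum(j for _, j in comp)
    sy = sum(i for i, _ in comp)
    return (sx / len(comp), sy / len(comp))


def match_naive(
    pred: np.ndarray,
    gt: np.ndarray,
    threshold: float = 0.75,
    mode: str = "pred",
    connectivity: int = 8,
):
    """Full object-level scoring by enumeration over component pixel sets.

    The whole frame acts as the single attention area.  Returns a dict with
    counts, the sorted overlap fractions of unmatched predictions, and the
    sorted centroid distances of matched pairs.
    """
    pred_comps = label_naive(pred, connectivity)
    gt_comps = label_naive(gt, connectivity)

    tp = fp = 0
    matched_gt: set[int] = set()
    matched_distances: list[float] = []
    all_fracs: list[float] = []
    for pc in pred_comps:
        best_j, best_inter = None, 0
        for j, gc in enumerate(gt_comps):
            inter = len(pc & gc)
            if inter > best_inter:
                best_j, best_inter = j, inter
        if best_j is None:
            fp += 1
            all_fracs.append(0.0)
            continue
        gc = gt_comps[best_j]
        if mode == "pred":
            frac = best_inter / len(pc)
        elif mode == "gt":
            frac = best_inter / len(gc)
        elif mode == "min":
            frac = best_inter / min(len(pc), len(gc))
        else:
            frac = best_inter / len(pc | gc)
        all_fracs.append(frac)
        if frac >= threshold:
            tp += 1
            matched_gt.add(best_j)
            px, py = centroid_naive(pc)
            gx, gy = centroid_naive(gc)
            matched_distances.append(float(np.hypot(px - gx, py - gy)))
        else:
            fp += 1
    fn = sum(1 for j in range(len(gt_comps)) if j not in matched_gt)
    tn = int(len(gt_comps) == 0 and len(pred_comps) == 0)
    pd_ = tp / (tp + fn) if (tp + fn) > 0 else None
    tnr = tn / (tn + fp) if (tn + fp) > 0 else None
    return {
        "n_pred": len(pred_comps),
        "n_gt": len(gt_comps),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "pd": pd_,
        "tnr": tnr,
        "fracs": sorted(all_fracs),
        "distances": sorted(matched_distances),
        "pred_centroids": sorted(centroid_naive(c) for c in pred_comps),
        "gt_centroids": sorted(centroid_naive(c) for c in gt_comps),
    }


def random_blob_mask(rng: np.random.Generator, shape=(32, 32), density: float = 0.25) -> np.ndarray:
    """Random blobby binary mask: thresholded smoothed noise."""
    from scipy.ndimage import gaussian_filter

    noise = gaussian_filter(rng.standard_normal(shape), sigma=1.5)
    thr = np.quantile(noise, 1.0 - density)
    return noise > thr
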