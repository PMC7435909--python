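"""File I/O: PNG images and masks, JSON truth, YAML configs, overlays."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .segmentation import BinaryMask
from .synthetic import SceneTruth

__all__ = [
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
    "save_scene_truth",
    "overlay_mask",
    "load_config",
    "save_json",
]


def save_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_mask(mask, path) -> None:
    """Binary mask as 0/255 single-channel PNG."""
    raster = mask.raster if isinstance(mask, BinaryMask) else np.asarray(mask)
    save_image(raster.astype(np.uint8) * 255, path)


def load_mask(path) -> np.ndarray:
    """Any nonzero pixel counts as foreground."""
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 0


def save_scene_truth(scene: SceneTruth, out_dir) -> dict:
    """Write a scene as image.png, gt_mask.png and truth.json; return file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_image(scene.image, out / "image.png")
    save_mask(scene.gt_mask, out / "gt_mask.png")
    truth = {
        "apple_centroids": scene.apple_centroids,
        "apple_radii": scene.apple_radii,
        "fixation_truth": [
            {
                "centroid": ft.centroid,
                "duration_ms": ft.duration_ms,
                "apple_index": ft.apple_index,
            }
            for ft in scene.fixation_truth
        ],
        "seed": scene.spec.seed,
        "width": scene.spec.width,
        "height": scene.spec.height,
        "n_apples": scene.spec.n_apples,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return {
        "image": str(out / "image.png"),
        "gt_mask": str(out / "gt_mask.png"),
        "truth": str(out / "truth.json"),
    }


def overlay_mask(
    image: np.ndarray, mask, color=(255, 0, 255), alpha: float = 0.45
) -> np.ndarray:
    """Blend a mask over an RGB image and trace its boundary, for inspection."""
    from skimage.segmentation import find_boundaries

    raster = mask.raster if isinstance(mask, BinaryMask) else np.asarray(mask)
    out = np.asarray(image, dtype=float).copy()
    col = np.asarray(color, dtype=float)
    out[raster] = (1 - alpha) * out[raster] + alpha * col
    out[find_boundaries(raster, mode="outer")] = col
    return np.clip(out, 0, 255).astype(np.uint8)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
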