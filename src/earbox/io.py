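"""Raster and table I/O for the pipeline.

Label masks round-trip losslessly as 16-bit PNG or TIFF (one positive
integer per grain instance, background 0); ear masks as 8-bit PNG.  Traits
tables are CSV with a versioned schema header in the accompanying JSON
manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .synthetic import EarGroundTruth, EarImageSet

__all__ = [
    "read_label_mask", "write_label_mask", "read_ear_mask", "write_ear_mask",
    "read_traits", "write_traits", "write_ear_image_set", "read_ear_directory",
    "write_ground_truth", "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write an instance label mask as 16-bit PNG or TIFF (by extension)."""
    path = Path(path)
    arr = np.asarray(mask)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label masks must be integer rasters: {path.name}")
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise ValueError(f"labels must fit 16-bit unsigned range: {path.name}")
    arr16 = arr.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr16)
    else:
        Image.fromarray(arr16).save(path)


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read a label mask written by :func:`write_label_mask`.

    8-bit inputs are accepted but can encode at most 255 labels; floating
    point or multi-channel rasters are rejected as format errors.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.array(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"label mask must be single-channel: {path.name}")
    if np.issubdtype(arr.dtype, np.floating):
        if np.any(~np.isfinite(arr)):
            raise ValueError(f"label mask contains NaN/Inf: {path.name}")
        if np.any(arr != np.round(arr)):
            raise ValueError(f"label mask is not integer-valued: {path.name}")
        arr = arr.astype(np.int64)
    return arr.astype(np.uint16)


def write_ear_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary ear silhouette as 8-bit PNG (0 / 255)."""
    arr = (np.asarray(mask, dtype=bool) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def read_ear_mask(path: str | Path) -> np.ndarray:
    arr = np.array(Image.open(path).convert("L"))
    return arr > 127


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(Path(path), index=False, float_format="%.6g")


def read_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_ground_truth(truth: EarGroundTruth, ear_dir: str | Path) -> None:
    """Persist ground truth as JSON (scalars + profiles) and CSV (grains)."""
    ear_dir = Path(ear_dir)
    truth.grains.to_csv(ear_dir / "ground_truth_grains.csv", index=False)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "ear_length_cm": truth.ear_length,
        "vertical_extent_cm": truth.vertical_extent,
        "max_diameter_cm": truth.max_diameter,
        "n_cohorts": truth.n_cohorts,
        "grains_per_cohort": truth.grains_per_cohort,
        "total_set_grains": truth.total_set_grains,
        "set_per_zone": list(truth.set_per_zone),
        "fertile_length_cm": truth.fertile_length,
        "basal_aborted_length_cm": truth.basal_aborted_length,
        "apical_aborted_length_cm": truth.apical_aborted_length,
        "pixel_scale": truth.pixel_scale,
        "row_indices": truth.row_indices.tolist(),
        "diameter_profile_cm": truth.diameter_profile.tolist(),
        "gsr_profile": truth.gsr_profile.tolist(),
    }
    (ear_dir / "ground_truth.json").write_text(json.dumps(payload, indent=1))


def write_ear_image_set(images: EarImageSet, out_dir: str | Path,
                        write_pseudo: bool = True) -> Path:
    """Write one ear's views into ``out_dir/<ear_id>/`` and return the dir."""
    ear_dir = Path(out_dir) / images.ear_id
    ear_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "ear_id": images.ear_id,
        "pixel_scale": images.pixel_scale,
        "views": [],
    }
    for view in images.views:
        stem = f"view_{view.view_index:02d}"
        write_ear_mask(view.ear_mask, ear_dir / f"{stem}_earmask.png")
        write_label_mask(view.grain_labels, ear_dir / f"{stem}_grains.png")
        if write_pseudo and view.rgb is not None:
            Image.fromarray(view.rgb, mode="RGB").save(ear_dir / f"{stem}_rgb.png")
        if write_pseudo and view.ir is not None:
            Image.fromarray(view.ir, mode="L").save(ear_dir / f"{stem}_ir.png")
        meta["views"].append(
            {"view_index": view.view_index, "rotation_deg": view.rotation_deg}
        )
    (ear_dir / "meta.json").write_text(json.dumps(meta, indent=1))
    return ear_dir


def read_ear_directory(ear_dir: str | Path) -> tuple[str, float, list[dict]]:
    """Read one per-ear directory: (ear_id, pixel_scale, view records).

    Each view record carries ``ear_mask`` and ``grain_labels`` arrays plus
    the view index; all rasters of an ear must share dimensions.
    """
    ear_dir = Path(ear_dir)
    meta_path = ear_dir / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing meta.json in {ear_dir}")
    meta = json.loads(meta_path.read_text())
    views = []
    shape = None
    for rec in meta["views"]:
        stem = f"view_{rec['view_index']:02d}"
        mask_path = ear_dir / f"{stem}_earmask.png"
        labels_path = ear_dir / f"{stem}_grains.png"
        if not mask_path.exists() or not labels_path.exists():
            raise FileNotFoundError(f"missing view files for {stem} in {ear_dir}")
        ear_mask = read_ear_mask(mask_path)
        labels = read_label_mask(labels_path)
        if ear_mask.shape != labels.shape:
            raise ValueError(f"raster size mismatch in {ear_dir}/{stem}")
        if shape is None:
            shape = ear_mask.shape
        elif ear_mask.shape != shape:
            raise ValueError(f"raster sizes differ between views in {ear_dir}")
        views.append({"view_index": rec["view_index"], "ear_mask": ear_mask,
                      "grain_labels": labels})
    return meta["ear_id"], float(meta["pixel_scale"]), views
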