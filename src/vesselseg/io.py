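"""File formats: 8-bit PNG images, raw-index mask PNGs, float32 TIFF
probability stacks, JSON manifests/metric reports, CSV tables, and the
segmentation overlay renderer.

Masks are stored as single-channel 8-bit PNGs holding the raw class
index (sentinel 255); no palette is involved, so values survive a
write/read round trip bit-exactly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


# ---------------------------------------------------------------- images
def save_image(path, image):
    """Float [0,1] (or uint8) HxWx3 image -> 8-bit PNG/TIFF."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        image = (np.clip(image, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(Path(path), image)


def load_image(path):
    """8-bit image file -> float32 HxWx3 in [0,1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return (arr.astype(np.float32) / 255.0) if arr.dtype == np.uint8 else arr.astype(np.float32)


def save_mask(path, mask):
    mask = np.asarray(mask)
    if mask.dtype != np.uint8:
        raise ValueError("masks must be uint8 class indices")
    iio.imwrite(Path(path), mask)


def load_mask(path):
    mask = iio.imread(Path(path))
    if mask.ndim != 2:
        raise ValueError(f"mask file {path} is not single-channel")
    return mask.astype(np.uint8)


def save_probability_stack(path, probs):
    """HxWxC float probabilities -> float32 TIFF, one page per class."""
    probs = np.asarray(probs, dtype=np.float32)
    tifffile.imwrite(Path(path), probs.transpose(2, 0, 1))


def load_probability_stack(path):
    return tifffile.imread(Path(path)).transpose(1, 2, 0)


# ------------------------------------------------------------- manifests
def save_json(path, payload):
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_json(path):
    with open(path) as fh:
        return json.load(fh)


# ------------------------------------------------------------ patch sets
def write_patch_dataset(root, patches):
    """Benchmark patches -> images/, scribbles/, dense/ PNGs + manifest."""
    root = Path(root)
    for sub in ("images", "scribbles", "dense"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    ids = []
    for p in patches:
        save_image(root / "images" / f"{p.id}.png", p.image)
        save_mask(root / "scribbles" / f"{p.id}.png", p.scribble)
        if p.dense is not None:
            save_mask(root / "dense" / f"{p.id}.png", p.dense)
        ids.append(p.id)
    save_json(root / "manifest.json", {"ids": ids, "patch_px": patches[0].image.shape[0]})
    return ids


def read_patch_dataset(root):
    """Returns list of records with .image, .scribble, .dense (may be None), .id."""
    from .synthetic import BenchmarkPatch

    root = Path(root)
    manifest = load_json(root / "manifest.json")
    out = []
    for pid in manifest["ids"]:
        image = load_image(root / "images" / f"{pid}.png")
        scribble = load_mask(root / "scribbles" / f"{pid}.png")
        dense_path = root / "dense" / f"{pid}.png"
        dense = load_mask(dense_path) if dense_path.exists() else None
        out.append(BenchmarkPatch(image, scribble, dense, 0, 0, 0, pid=pid))
    return out


# ---------------------------------------------------------------- tables
def metrics_to_files(out_dir, metrics, roc=None, confusion=None, prefix="metrics"):
    """Write a metric report as nested JSON + flat CSV (+ ROC/confusion CSVs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = metrics.to_dict()
    if roc is not None:
        payload["auc"] = {str(c): roc.auc[c] for c in roc.auc}
        payload["auc_macro"] = roc.macro_auc
        payload["auc_excluded"] = list(roc.excluded)
    save_json(out_dir / f"{prefix}.json", payload)
    with open(out_dir / f"{prefix}.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "precision", "recall", "specificity", "dice"])
        for c, row in payload["per_class"].items():
            writer.writerow([c, row["precision"], row["recall"],
                             row["specificity"], row["dice"]])
        macro = payload["macro"]
        writer.writerow(["macro", macro["precision"], macro["recall"],
                         macro["specificity"], macro["dice"]])
    if roc is not None:
        for c in roc.fpr:
            with open(out_dir / f"roc_class{c}.csv", "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["fpr", "tpr"])
                writer.writerows(zip(roc.fpr[c], roc.tpr[c]))
    if confusion is not None:
        np.savetxt(out_dir / "confusion_matrix.csv",
                   np.asarray(confusion, dtype=int), fmt="%d", delimiter=",")


# --------------------------------------------------------------- overlay
def render_overlay(image, labels, scheme, alpha=0.5):
    """Alpha-blend class colors over an image; sentinel stays transparent."""
    image = np.asarray(image)
    labels = np.asarray(labels)
    if image.shape[:2] != labels.shape:
        raise ValueError("image and label map shapes differ")
    if image.dtype == np.uint8:
        base = image.astype(np.float64) / 255.0
    else:
        base = image.astype(np.float64)
    known = labels != scheme.sentinel
    bad = known & (labels >= len(scheme.names))
    if bad.any():
        raise ValueError(
            f"unknown class indices {sorted(set(labels[bad].tolist()))} in label map"
        )
    lut = np.zeros((256, 3))
    for i, color in enumerate(scheme.colors):
        lut[i] = np.asarray(color) / 255.0
    colored = lut[labels]
    out = base.copy()
    out[known] = (1.0 - alpha) * base[known] + alpha * colored[known]
    return (np.clip(out, 0, 1) * 255.0 + 0.5).astype(np.uint8)
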