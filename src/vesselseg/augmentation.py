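"""Randomized joint augmentation of image patches and scribble masks.

One parameter draw is applied identically (geometrically) to the image
and its mask: flip, rotation and anisotropic zoom are composed into a
single centered affine warp (bilinear for the image, nearest-neighbor
for the mask, mirror fill for exposed regions, output cropped to the
input geometry).  Photometric contrast/brightness changes touch the
image only.  Ranges follow the staining-variation regime of stained
sections: contrast +/-90%, brightness +/-30% of full scale, per-axis
zoom 50-200%, rotation +/-90 deg, optional horizontal/vertical flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, warp

FLIPS = ("none", "horizontal", "vertical")


@dataclass(frozen=True)
class AugmentationParams:
    contrast_range: tuple = (0.1, 1.9)
    brightness_range: tuple = (-0.3, 0.3)
    zoom_range: tuple = (0.5, 2.0)
    rotation_range: tuple = (-90.0, 90.0)
    flips: tuple = FLIPS
    augmentations_per_patch: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.augmentations_per_patch < 0:
            raise ValueError("augmentations_per_patch must be >= 0")


@dataclass(frozen=True)
class AugmentationDraw:
    """One concrete parameter draw; the identity draw leaves inputs unchanged."""

    contrast: float = 1.0
    brightness: float = 0.0
    zoom: tuple = (1.0, 1.0)
    rotation_deg: float = 0.0
    flip: str = "none"

    def is_geometric_identity(self):
        return (
            self.flip == "none"
            and self.rotation_deg == 0.0
            and tuple(self.zoom) == (1.0, 1.0)
        )


def draw_augmentation(params, rng):
    return AugmentationDraw(
        contrast=float(rng.uniform(*params.contrast_range)),
        brightness=float(rng.uniform(*params.brightness_range)),
        zoom=(
            float(rng.uniform(*params.zoom_range)),
            float(rng.uniform(*params.zoom_range)),
        ),
        rotation_deg=float(rng.uniform(*params.rotation_range)),
        flip=str(rng.choice(params.flips)),
    )


def _centered_affine(draw, shape):
    """Forward transform flip -> rotate -> zoom, all about the patch center."""
    h, w = shape[:2]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    center = AffineTransform(translation=(cx, cy))
    uncenter = AffineTransform(translation=(-cx, -cy))
    fx = -1.0 if draw.flip == "horizontal" else 1.0
    fy = -1.0 if draw.flip == "vertical" else 1.0
    flip = AffineTransform(np.diag([fx, fy, 1.0]))
    rot = AffineTransform(rotation=np.deg2rad(draw.rotation_deg))
    zoom = AffineTransform(scale=draw.zoom)
    return uncenter + flip + rot + zoom + center


def apply_draw(patch, mask, draw):
    """Apply one draw to an image/mask pair sharing geometry."""
    patch = np.asarray(patch)
    mask = np.asarray(mask)
    if patch.shape[:2] != mask.shape[:2]:
        raise ValueError(
            f"patch {patch.shape[:2]} and mask {mask.shape[:2]} geometry differ"
        )
    img = patch.astype(np.float64, copy=True)
    out_mask = mask
    if not draw.is_geometric_identity():
        tform = _centered_affine(draw, patch.shape)
        img = warp(img, tform.inverse, order=1, mode="reflect", preserve_range=True)
        out_mask = warp(
            mask.astype(np.float64),
            tform.inverse,
            order=0,
            mode="reflect",
            preserve_range=True,
        )
        out_mask = np.rint(out_mask).astype(mask.dtype)
    if draw.contrast != 1.0:
        m = img.mean()
        img = m + draw.contrast * (img - m)
    if draw.brightness != 0.0:
        img = img + draw.brightness
    img = np.clip(img, 0.0, 1.0)
    return img.astype(patch.dtype, copy=False), out_mask


def augment_pair(patch, mask, params, rng):
    """Draw one parameter set and apply it; returns (image, mask, draw)."""
    draw = draw_augmentation(params, rng)
    img, msk = apply_draw(patch, mask, draw)
    return img, msk, draw


@dataclass
class AugmentedPatch:
    image: np.ndarray
    mask: np.ndarray
    source_index: int
    draw: AugmentationDraw = field(default_factory=AugmentationDraw)


def expand_training_set(patches, params):
    """Emit ``augmentations_per_patch`` augmented copies per input patch.

    ``patches`` is a sequence of (image, mask) pairs.  The originals are
    not re-included, so 4500 inputs at the default 10 draws yield 45,000
    outputs.  Every output records its source index and parameter draw.
    """
    patches = list(patches)
    if not patches:
        raise ValueError("cannot expand an empty training set")
    if params.augmentations_per_patch < 1:
        raise ValueError("augmentations_per_patch must be >= 1 for expansion")
    rng = np.random.default_rng(params.seed)
    out = []
    for idx, (image, mask) in enumerate(patches):
        for _ in range(params.augmentations_per_patch):
            img, msk, draw = augment_pair(image, mask, params, rng)
            out.append(AugmentedPatch(img, msk, idx, draw))
    return out
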