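"""Cutting slides into fixed-size patches, stitching predictions back,
and the train/validation/test split.

Slides of arbitrary size are mirror-padded on the bottom/right edges to
the next multiple of the patch size and tiled row-major without overlap;
the grid manifest records everything needed to crop a stitched output
back to the original geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PATCH_PX = 128


def mirror_pad(image, bottom, right):
    """Symmetric (mirror) padding, robust to pads larger than the image."""
    image = np.asarray(image)
    h, w = image.shape[:2]

    def reflect(n, pad):
        idx = np.arange(n + pad) % max(2 * n, 1)
        return np.where(idx < n, idx, 2 * n - 1 - idx)

    return image[np.ix_(reflect(h, bottom), reflect(w, right))]


@dataclass(frozen=True)
class PatchGrid:
    """Tiling metadata: source size, patch size and per-patch rectangles."""

    height: int
    width: int
    patch_px: int = PATCH_PX
    padding: str = "mirror"

    @property
    def rows(self):
        return -(-self.height // self.patch_px)

    @property
    def cols(self):
        return -(-self.width // self.patch_px)

    @property
    def padded_shape(self):
        return self.rows * self.patch_px, self.cols * self.patch_px

    def rectangles(self):
        """(row, col, (y0, y1, x0, x1)) half-open rects on the padded canvas."""
        p = self.patch_px
        for r in range(self.rows):
            for c in range(self.cols):
                yield r, c, (r * p, (r + 1) * p, c * p, (c + 1) * p)

    def to_dict(self):
        return {
            "height": self.height,
            "width": self.width,
            "patch_px": self.patch_px,
            "padding": self.padding,
            "rows": self.rows,
            "cols": self.cols,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["height"], d["width"], d["patch_px"], d.get("padding", "mirror"))


def extract_patches(image, patch_px=PATCH_PX):
    """Tile an HxW(xC) image into non-overlapping patches.

    Returns (grid, patches) where patches is a row-major list and the
    image is mirror-padded bottom/right to a multiple of ``patch_px``.
    """
    if patch_px < 1:
        raise ValueError("patch_px must be >= 1")
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("image must be at least 1x1")
    grid = PatchGrid(h, w, patch_px)
    ph, pw = grid.padded_shape
    padded = mirror_pad(image, ph - h, pw - w)
    patches = [padded[y0:y1, x0:x1].copy() for _, _, (y0, y1, x0, x1) in grid.rectangles()]
    return grid, patches


def stitch(grid, patch_outputs):
    """Re-align per-patch outputs and crop back to the source size."""
    patch_outputs = list(patch_outputs)
    if len(patch_outputs) != grid.rows * grid.cols:
        raise ValueError(
            f"expected {grid.rows * grid.cols} patches, got {len(patch_outputs)}"
        )
    first = np.asarray(patch_outputs[0])
    p = grid.patch_px
    if first.shape[:2] != (p, p):
        raise ValueError(f"patch outputs must be {p}x{p}, got {first.shape[:2]}")
    ph, pw = grid.padded_shape
    canvas = np.zeros((ph, pw) + first.shape[2:], dtype=first.dtype)
    for (r, c, (y0, y1, x0, x1)), out in zip(grid.rectangles(), patch_outputs):
        out = np.asarray(out)
        if out.shape != first.shape:
            raise ValueError("inconsistent patch output shapes")
        canvas[y0:y1, x0:x1] = out
    return canvas[: grid.height, : grid.width]


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple
    val: tuple
    test: tuple
    fractions: tuple
    seed: int
    ids: tuple = field(default_factory=tuple, repr=False)


def split_dataset(ids, fractions=(0.6, 0.2, 0.2), seed=0):
    """Seeded shuffle, then contiguous train/val/test partition."""
    ids = list(ids)
    if not ids:
        raise ValueError("cannot split an empty id list")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(ids)
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in perm]
    n_train = round(n * fractions[0])
    n_val = round(n * (fractions[0] + fractions[1])) - n_train
    return DatasetSplit(
        train=tuple(shuffled[:n_train]),
        val=tuple(shuffled[n_train : n_train + n_val]),
        test=tuple(shuffled[n_train + n_val :]),
        fractions=tuple(fractions),
        seed=seed,
        ids=tuple(ids),
    )
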