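"""Parametric stained-slide scenes with dense six-class ground truth and
sparse scribble annotations.

The generator targets the *statistics* that matter for training and
evaluating the segmentation method — strong class imbalance (tissue and
background dominate), fine continuous vessel walls enclosing pale
heterogeneous lumina with residual-cell speckles, dark irregular
destroyed-tissue patches, compact debris, and global staining drift —
rather than visual fidelity to any particular immunohistochemical stain.

Classes: 0 background, 1 tissue, 2 destroyed tissue, 3 debris,
4 vessel wall, 5 vessel lumen; 255 marks unlabeled pixels in scribbles.

Scribbles follow the labeling rules used for sparse supervision:
walls are copied completely; each lumen gets an inner rim line plus
crossing lines that traverse any cell speckles; a tissue line marks the
outer side of each wall; tissue and background get long strokes, with a
background line along the tissue border.  Every scribbled pixel agrees
with the dense truth by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .patchwork import extract_patches

BACKGROUND, TISSUE, DESTROYED, DEBRIS, WALL, LUMEN = range(6)
SENTINEL = 255

_CLASS_COLORS = np.array(
    [
        [0.96, 0.95, 0.97],  # background: near-white glass
        [0.76, 0.60, 0.78],  # tissue: hematoxylin-like
        [0.38, 0.26, 0.33],  # destroyed: dark, heterogeneous
        [0.30, 0.32, 0.38],  # debris: compact gray-blue
        [0.33, 0.18, 0.45],  # wall: dark-stained ring
        [0.93, 0.88, 0.93],  # lumen: pale interior
    ]
)
_CLASS_NOISE = np.array([0.015, 0.05, 0.09, 0.04, 0.035, 0.02])
_SPECKLE_COLOR = np.array([0.55, 0.33, 0.42])


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parametric description of one vessel scene."""

    canvas_px: int = 256
    n_vessels: int = 3
    vessel_radius: tuple = (18.0, 40.0)  # outer radius range, px
    elongation: tuple = (1.0, 1.8)
    wall_thickness: tuple = (3.0, 6.0)  # px, >= 1 enforced
    speckle_density: float = 0.02  # lumen cell speckles per px^2
    tissue_margin: int = 16  # background rim width, px
    tissue_wobble: float = 0.12
    tissue_heterogeneity: float = 0.35
    n_destroyed: int = 2
    destroyed_radius: tuple = (10.0, 22.0)
    n_debris: int = 3
    debris_radius: tuple = (3.0, 7.0)
    drift_brightness: float = 0.10
    drift_contrast: float = 0.15
    noise: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.wall_thickness[0] < 1.0:
            raise ValueError("wall thickness must be >= 1 px")
        if self.canvas_px < 32:
            raise ValueError("canvas too small")


def _wobble_radius(theta, base, amount, rng):
    r = np.full_like(theta, 1.0)
    for k in range(2, 6):
        r += amount * rng.uniform(0.1, 0.5) / k * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return base * r


def _blob_mask(shape, cy, cx, radius, wobble, rng):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    rr = np.hypot(dy, dx)
    return rr <= _wobble_radius(theta, radius, wobble, rng)


def _place_vessel(dense, tissue_ok, spec, rng):
    """Rasterize one elliptical vessel (wall ring + lumen) inside tissue."""
    h = dense.shape[0]
    for _ in range(60):
        r = rng.uniform(*spec.vessel_radius)
        e = rng.uniform(*spec.elongation)
        t = max(1.0, rng.uniform(*spec.wall_thickness))
        phi = rng.uniform(0, np.pi)
        a, b = r * e, r / e
        reach = int(np.ceil(max(a, b))) + 2
        if 2 * reach >= h:
            continue  # vessel cannot fit this canvas at all
        cy = rng.uniform(reach, h - reach)
        cx = rng.uniform(reach, h - reach)
        yy, xx = np.mgrid[0:h, 0:h]
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2) * r  # elliptical px radius
        outer = rho < r
        if not outer.any():
            continue
        if not tissue_ok[outer].all():
            continue
        if np.isin(dense[outer], (WALL, LUMEN, DESTROYED, DEBRIS)).any():
            continue
        lumen = rho < r - t
        dense[outer] = WALL
        dense[lumen] = LUMEN
        return True
    return False


def generate_scene(spec, rng=None):
    """Render one scene; returns (RGB float image in [0,1], dense label map)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    h = spec.canvas_px
    dense = np.full((h, h), BACKGROUND, dtype=np.uint8)

    # tissue blob with a wobbly boundary, leaving a background rim
    base_r = h / 2.0 - spec.tissue_margin
    tissue = _blob_mask((h, h), h / 2.0, h / 2.0, base_r, spec.tissue_wobble, rng)
    dense[tissue] = TISSUE

    # destroyed-tissue patches inside tissue
    for _ in range(spec.n_destroyed):
        for _try in range(40):
            rad = rng.uniform(*spec.destroyed_radius)
            ys, xs = np.nonzero(tissue)
            i = rng.integers(len(ys))
            blob = _blob_mask((h, h), ys[i], xs[i], rad, 0.5, rng)
            blob &= dense == TISSUE
            if blob.any():
                dense[blob] = DESTROYED
                break

    # debris: small compact blobs anywhere off-vessel
    for _ in range(spec.n_debris):
        rad = rng.uniform(*spec.debris_radius)
        cy = rng.uniform(rad, h - rad)
        cx = rng.uniform(rad, h - rad)
        blob = _blob_mask((h, h), cy, cx, rad, 0.3, rng)
        blob &= np.isin(dense, (BACKGROUND, TISSUE))
        if blob.any():
            dense[blob] = DEBRIS

    # vessels last so their walls are never overwritten
    interior = ndi.binary_erosion(tissue, structure=disk(3))
    for _ in range(spec.n_vessels):
        if not _place_vessel(dense, interior, spec, rng):
            raise RuntimeError(
                "could not place a vessel inside the tissue; the spec's vessel "
                "radii do not fit the canvas"
            )

    # ---------------------------------------------------------------- render
    img = _CLASS_COLORS[dense] + rng.normal(
        0.0, 1.0, size=(h, h, 1)
    ) * _CLASS_NOISE[dense][..., None]
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=(h, h)), 4.0)
    img += (spec.tissue_heterogeneity * 0.3 * texture[..., None]) * (
        np.isin(dense, (TISSUE, DESTROYED))[..., None]
    )

    # residual blood cells inside lumina (rendered only; still lumen truth)
    lumen_px = np.argwhere(dense == LUMEN)
    n_speckles = int(spec.speckle_density * len(lumen_px))
    for i in rng.choice(len(lumen_px), size=n_speckles, replace=False) if n_speckles else []:
        cy, cx = lumen_px[i]
        rr, cc = draw_disk((cy, cx), rng.uniform(1.0, 2.2), shape=(h, h))
        keep = dense[rr, cc] == LUMEN
        img[rr[keep], cc[keep]] = _SPECKLE_COLOR + rng.normal(0, 0.03, 3)

    # global staining drift: linear brightness plane + contrast gradient
    yy, xx = np.mgrid[0:h, 0:h]
    direction = rng.uniform(0, 2 * np.pi)
    plane = (
        (xx - h / 2) * np.cos(direction) + (yy - h / 2) * np.sin(direction)
    ) / (h / 2)
    factor = 1.0 + spec.drift_contrast * plane[..., None]
    img = img.mean() + factor * (img - img.mean())
    img += spec.drift_brightness * plane[..., None]
    img += rng.normal(0.0, spec.noise, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32), dense


# --------------------------------------------------------------------------
# scribble sparsifier
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ScribblePolicy:
    stroke_width: int = 3
    lumen_rim_inset: int = 2
    lumen_cross_lines: int = 2
    wall_outer_rim: int = 2  # width of the tissue line outside each wall
    tissue_strokes: int = 3
    background_strokes: int = 2
    destroyed_strokes: int = 1
    debris_marks: int = 1
    seed: int = 0


def _stroke(canvas_shape, p0, p1, width):
    out = np.zeros(canvas_shape, dtype=bool)
    rr, cc = draw_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
    keep = (rr >= 0) & (rr < canvas_shape[0]) & (cc >= 0) & (cc < canvas_shape[1])
    out[rr[keep], cc[keep]] = True
    if width > 1:
        out = ndi.binary_dilation(out, structure=disk(width // 2))
    return out


def _long_strokes(region, n, width, rng, min_frac=0.35):
    """Long straight strokes clipped to ``region``."""
    out = np.zeros_like(region)
    ys, xs = np.nonzero(region)
    if len(ys) == 0 or n == 0:
        return out
    h = region.shape[0]
    for _ in range(n):
        for _try in range(20):
            i, j = rng.integers(len(ys), size=2)
            p0 = (ys[i], xs[i])
            p1 = (ys[j], xs[j])
            if np.hypot(p0[0] - p1[0], p0[1] - p1[1]) >= min_frac * h:
                break
        out |= _stroke(region.shape, p0, p1, width) & region
    return out


def _component_cross_lines(comp, n, width, rng):
    """Lines through the component centroid spanning its bounding box."""
    out = np.zeros_like(comp)
    ys, xs = np.nonzero(comp)
    cy, cx = ys.mean(), xs.mean()
    span = max(np.ptp(ys), np.ptp(xs)) + 2 * width + 4
    for _ in range(n):
        ang = rng.uniform(0, np.pi)
        dy, dx = np.sin(ang) * span, np.cos(ang) * span
        out |= _stroke(
            comp.shape, (cy - dy, cx - dx), (cy + dy, cx + dx), width
        ) & comp
    return out


def sparsify_labels(dense, policy, rng=None):
    """Reduce a dense label map to scribbles; everything else is sentinel.

    Consistency is exact by construction: every selected pixel set is
    intersected with its own class region before being written.
    """
    rng = np.random.default_rng(policy.seed) if rng is None else rng
    dense = np.asarray(dense)
    w = policy.stroke_width
    mask = np.full(dense.shape, SENTINEL, dtype=np.uint8)

    wall = dense == WALL
    lumen = dense == LUMEN
    tissue = dense == TISSUE
    background = dense == BACKGROUND

    # rule 1: walls are labeled completely
    mask[wall] = WALL

    # rules 2-3: lumen inner rim + crossing lines; tissue line outside wall
    lumen_cc = cc_label(lumen, connectivity=1)
    for comp_id in range(1, lumen_cc.max() + 1):
        comp = lumen_cc == comp_id
        rim = comp & ~ndi.binary_erosion(comp, structure=disk(policy.lumen_rim_inset))
        lines = _component_cross_lines(comp, policy.lumen_cross_lines, w, rng)
        mask[(rim | lines) & lumen] = LUMEN
    outer = ndi.binary_dilation(wall, structure=disk(policy.wall_outer_rim)) & tissue
    mask[outer] = TISSUE

    # rule 4: long tissue strokes
    mask[_long_strokes(tissue, policy.tissue_strokes, w, rng)] = TISSUE

    # rule 5: long background strokes + a line along the tissue border
    mask[_long_strokes(background, policy.background_strokes, w, rng)] = BACKGROUND
    border = ndi.binary_dilation(~background, structure=disk(2)) & background
    mask[border] = BACKGROUND

    # minority classes get modest marks so every class can be supervised
    for cls, n_lines in ((DESTROYED, policy.destroyed_strokes), (DEBRIS, policy.debris_marks)):
        region = dense == cls
        cc = cc_label(region, connectivity=1)
        for comp_id in range(1, cc.max() + 1):
            comp = cc == comp_id
            mask[_component_cross_lines(comp, n_lines, w, rng)] = cls
    return mask


# --------------------------------------------------------------------------
# benchmark assembly
# --------------------------------------------------------------------------
@dataclass
class BenchmarkPatch:
    image: np.ndarray  # 128x128x3 float32 in [0,1]
    scribble: np.ndarray  # 128x128 uint8, sentinel 255
    dense: np.ndarray  # 128x128 uint8 ground truth
    scene: int
    row: int
    col: int
    pid: str = ""

    @property
    def id(self):
        return self.pid or f"scene{self.scene:03d}_r{self.row}_c{self.col}"


@dataclass
class Benchmark:
    patches: list
    specs: list
    policy: ScribblePolicy
    seed: int

    def __len__(self):
        return len(self.patches)


def make_benchmark(n_scenes, spec=None, policy=None, seed=0, patch_px=128):
    """Generate scenes, sparsify, and cut everything into aligned patches.

    Dense truth is retained per patch, enabling the dense evaluation the
    original sparse-label study could not perform.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    spec = spec or SyntheticSceneSpec()
    policy = policy or ScribblePolicy()
    patches, specs = [], []
    for s in range(n_scenes):
        scene_spec = dataclasses.replace(spec, seed=(seed * 100003 + s) % (2 ** 31))
        rng = np.random.default_rng(scene_spec.seed)
        image, dense = generate_scene(scene_spec, rng)
        scribble = sparsify_labels(dense, policy, rng)
        grid, img_patches = extract_patches(image, patch_px)
        _, scr_patches = extract_patches(scribble, patch_px)
        _, den_patches = extract_patches(dense, patch_px)
        for (r, c, _), im, sc, de in zip(
            grid.rectangles(), img_patches, scr_patches, den_patches
        ):
            patches.append(BenchmarkPatch(im, sc, de, s, r, c))
        specs.append(scene_spec)
    return Benchmark(patches, specs, policy, seed)
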