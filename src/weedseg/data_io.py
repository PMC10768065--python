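"""Image/mask I/O, the colour-mask codec, preprocessing, augmentation and a
procedural synthetic crop/weed scene generator.

Masks use the three-colour palette common in crop/weed field datasets:
black = soil or paddy background (label 0), green = crop (label 1),
red = weed (label 2).

The synthetic generator emulates the structure of field imagery: a textured
soil (or paddy-water) background, a few large rosette-shaped crop plants and
many small, thin, scattered weeds, with optional crop/weed overlap and
optional blurred plant "reflections" on paddy water (which keep the
background label).  Rendered plant pixels and mask labels are aligned
exactly, and identical seeds reproduce identical scenes bit for bit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "PALETTE",
    "SceneSpec",
    "decode_color_mask",
    "encode_color_mask",
    "preprocess",
    "augment",
    "elastic_distort",
    "miscut_transform",
    "generate_synthetic_scene",
    "generate_synthetic_dataset",
    "compute_channel_stats",
    "write_dataset",
    "read_dataset",
]

#: label -> RGB colour of the mask palette
PALETTE = np.array([
    [0, 0, 0],       # 0: soil / paddy background (black)
    [0, 255, 0],     # 1: crop (green)
    [255, 0, 0],     # 2: weed (red)
], dtype=np.uint8)


# ---------------------------------------------------------------------------
# colour-mask codec
# ---------------------------------------------------------------------------

def decode_color_mask(rgb_mask: np.ndarray) -> np.ndarray:
    """RGB palette mask -> integer labels; off-palette pixels snap to the
    nearest palette colour in RGB distance."""
    rgb_mask = np.asarray(rgb_mask)
    if rgb_mask.ndim != 3 or rgb_mask.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 colour mask, got {rgb_mask.shape}")
    diff = rgb_mask[:, :, None, :].astype(np.int64) - PALETTE[None, None, :, :].astype(np.int64)
    dist = (diff * diff).sum(axis=3)
    return dist.argmin(axis=2).astype(np.int64)


def encode_color_mask(mask: np.ndarray) -> np.ndarray:
    """Integer labels -> RGB palette mask."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= len(PALETTE):
        raise ValueError(
            f"labels must lie in [0, {len(PALETTE)}), got [{mask.min()}, {mask.max()}]")
    return PALETTE[mask]


# ---------------------------------------------------------------------------
# preprocessing / augmentation
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray, mask: np.ndarray | None,
               size: tuple[int, int] = (256, 256),
               mean: np.ndarray | float = 0.5,
               std: np.ndarray | float = 0.5):
    """Resize and standardise an aligned image/mask pair.

    The image (H x W x 3, uint8 or float in [0, 1]) is resized bilinearly and
    standardised per channel to (3, size) float; the mask is resized with
    nearest-neighbour interpolation so labels are preserved exactly.  ``mean``
    and ``std`` default to 0.5 when dataset statistics are not supplied.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got {image.shape}")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != image.shape[:2]:
            raise ValueError(
                f"image {image.shape[:2]} and mask {mask.shape} are misaligned")
    if image.dtype == np.uint8:
        image = image.astype(np.float64) / 255.0
    resized = _sk_resize(image, size, order=1, mode="reflect",
                         anti_aliasing=False, preserve_range=True)
    mean = np.broadcast_to(np.asarray(mean, dtype=np.float64), (3,))
    std = np.broadcast_to(np.asarray(std, dtype=np.float64), (3,))
    standardized = (resized - mean) / std
    chw = np.ascontiguousarray(standardized.transpose(2, 0, 1))
    if mask is None:
        return chw, None
    h, w = mask.shape
    th, tw = size
    rows = np.clip((np.arange(th) + 0.5) * h / th, 0, h - 1).astype(int)
    cols = np.clip((np.arange(tw) + 0.5) * w / tw, 0, w - 1).astype(int)
    return chw, mask[np.ix_(rows, cols)]


def augment(image: np.ndarray, mask: np.ndarray, seed: int,
            blur_prob: float = 0.5, blur_sigma: tuple[float, float] = (0.1, 2.0)):
    """Random flips (applied jointly to image and mask) plus random Gaussian
    blur applied to the image only.  Deterministic under ``seed``."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape} are misaligned")
    rng = np.random.default_rng(seed)
    if rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]       # horizontal flip
    if rng.random() < 0.5:
        image, mask = image[::-1, :], mask[::-1, :]       # vertical flip
    if rng.random() < blur_prob:
        sigma = rng.uniform(*blur_sigma)
        image = ndimage.gaussian_filter(image, sigma=(sigma, sigma, 0))
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def elastic_distort(image: np.ndarray, mask: np.ndarray, seed: int,
                    alpha: float = 20.0, sigma: float = 5.0):
    """Optional elastic distortion (offline dataset expansion; not part of the
    default augmentation path).  Geometric, so applied jointly; the mask is
    warped with nearest-neighbour sampling."""
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = [np.clip(yy + dy, 0, h - 1), np.clip(xx + dx, 0, w - 1)]
    warped = np.stack([
        ndimage.map_coordinates(image[:, :, c], coords, order=1, mode="reflect")
        for c in range(3)], axis=2)
    warped_mask = mask[tuple(np.round(c).astype(int) for c in coords)]
    return warped, warped_mask


def miscut_transform(image: np.ndarray, mask: np.ndarray, seed: int,
                     max_shear: float = 0.2):
    """Optional shear ("miscut") transform for offline dataset expansion."""
    rng = np.random.default_rng(seed)
    shear = rng.uniform(-max_shear, max_shear)
    h, w = mask.shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    src_x = np.clip(xx + shear * (yy - h / 2), 0, w - 1)
    coords = [yy.astype(float), src_x]
    warped = np.stack([
        ndimage.map_coordinates(image[:, :, c], coords, order=1, mode="reflect")
        for c in range(3)], axis=2)
    warped_mask = mask[yy, np.round(src_x).astype(int)]
    return warped, warped_mask


# ---------------------------------------------------------------------------
# synthetic scene generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the procedural crop/weed scene generator.

    Crops are few and large (rosettes); weeds are many, small and thin —
    ``weed_radius_range`` must stay strictly below ``crop_radius_range``.
    ``overlap_prob`` is the chance a weed is allowed to grow over a crop.
    """

    size: tuple[int, int] = (256, 256)
    n_crops: int = 3
    n_weeds: int = 12
    crop_radius_range: tuple[float, float] = (24.0, 40.0)
    weed_radius_range: tuple[float, float] = (4.0, 10.0)
    overlap_prob: float = 0.3
    background: str = "soil"
    reflection: bool = False
    noise_level: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if self.background not in ("soil", "paddy"):
            raise ValueError(f"background must be 'soil' or 'paddy', got {self.background!r}")
        if self.weed_radius_range[1] >= self.crop_radius_range[0]:
            raise ValueError("weed radii must be strictly smaller than crop radii")
        if not 0.0 <= self.overlap_prob <= 1.0:
            raise ValueError("overlap_prob must lie in [0, 1]")
        if self.n_crops < 0 or self.n_weeds < 0:
            raise ValueError("object counts must be non-negative")

    def scaled_to(self, size: tuple[int, int]) -> "SceneSpec":
        """Rescale object radii proportionally to a new canvas size."""
        factor = min(size) / min(self.size)
        return replace(
            self, size=size,
            crop_radius_range=tuple(r * factor for r in self.crop_radius_range),
            weed_radius_range=tuple(max(1.5, r * factor) for r in self.weed_radius_range),
        )

    @classmethod
    def for_size(cls, size: tuple[int, int], **overrides) -> "SceneSpec":
        """Default spec with object radii scaled to ``size``, then overridden."""
        return replace(cls().scaled_to(size), **overrides)


def _textured_background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    lowfreq = ndimage.gaussian_filter(rng.normal(size=(h, w)), min(h, w) / 16)
    lowfreq /= max(np.abs(lowfreq).max(), 1e-9)
    grain = 0.5 * rng.normal(size=(h, w))
    if spec.background == "soil":
        base = np.array([0.42, 0.30, 0.20])         # brown earth
        tone = 1.0 + 0.25 * lowfreq + 0.10 * grain
        img = base[None, None, :] * tone[:, :, None]
    else:
        base = np.array([0.25, 0.38, 0.36])         # green-blue paddy water
        streaks = ndimage.gaussian_filter(rng.normal(size=(h, w)), (1, min(h, w) / 8))
        streaks /= max(np.abs(streaks).max(), 1e-9)
        tone = 1.0 + 0.2 * lowfreq + 0.15 * streaks + 0.05 * grain
        img = base[None, None, :] * tone[:, :, None]
    return np.clip(img, 0.0, 1.0)


def _rosette_mask(h: int, w: int, cy: float, cx: float, radius: float,
                  lobes: int, phase: float) -> np.ndarray:
    """Boolean footprint of a lobed rosette (crop plant)."""
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = radius * (0.45 + 0.55 * np.abs(np.cos(lobes * (theta - phase) / 2.0)))
    return dist <= boundary


def _weed_mask(h: int, w: int, cy: float, cx: float, radius: float,
               rng: np.random.Generator) -> np.ndarray:
    """Boolean footprint of a thin, straggly weed: a few narrow strokes."""
    canvas = np.zeros((h, w), dtype=bool)
    n_strokes = int(rng.integers(2, 5))
    for _ in range(n_strokes):
        angle = rng.uniform(0, 2 * np.pi)
        curve = rng.uniform(-0.3, 0.3)
        n_steps = max(int(radius * 2), 3)
        for t in np.linspace(0, 1, n_steps):
            a = angle + curve * t * np.pi
            py = cy + t * radius * np.sin(a)
            px = cx + t * radius * np.cos(a)
            iy, ix = int(round(py)), int(round(px))
            if 0 <= iy < h and 0 <= ix < w:
                canvas[iy, ix] = True
                if t > 0.3 and iy + 1 < h:   # slight thickening away from root
                    canvas[iy + 1, ix] = True
    return canvas


def _place_centers(rng: np.random.Generator, n: int, h: int, w: int,
                   radii: np.ndarray, min_gap: float, max_tries: int = 2000):
    """Rejection-sample object centres so footprints keep ``min_gap`` apart."""
    centers: list[tuple[float, float]] = []
    for i in range(n):
        r = radii[i]
        if 2 * r + 2 >= min(h, w):
            raise ValueError(
                f"object of radius {r:.1f} cannot fit the {h}x{w} canvas")
        for attempt in range(max_tries):
            cy = rng.uniform(r, h - 1 - r)
            cx = rng.uniform(r, w - 1 - r)
            ok = all(np.hypot(cy - py, cx - px) >= r + pr + min_gap
                     for (py, px), pr in zip(centers, radii[:len(centers)]))
            if ok:
                centers.append((cy, cx))
                break
        else:
            raise ValueError(
                f"could not place {n} objects of radius ~{r:.1f} on a {h}x{w} canvas")
    return centers


def generate_synthetic_scene(spec: SceneSpec):
    """Render one aligned (image, mask) pair according to ``spec``.

    Returns ``image`` (H x W x 3 float64 in [0, 1]) and ``mask`` (H x W
    int64 labels in {0, 1, 2}).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    image = _textured_background(spec, rng)
    mask = np.zeros((h, w), dtype=np.int64)

    crop_radii = rng.uniform(*spec.crop_radius_range, size=spec.n_crops)
    crop_centers = _place_centers(rng, spec.n_crops, h, w, crop_radii, min_gap=3.0)
    crop_pixels = np.zeros((h, w), dtype=bool)
    for (cy, cx), radius in zip(crop_centers, crop_radii):
        lobes = int(rng.integers(5, 9))
        phase = rng.uniform(0, 2 * np.pi)
        foot = _rosette_mask(h, w, cy, cx, radius, lobes, phase)
        crop_pixels |= foot
        shade = rng.uniform(0.85, 1.1)
        yy, xx = np.nonzero(foot)
        radial = np.hypot(yy - cy, xx - cx) / max(radius, 1e-9)
        green = np.stack([
            0.13 * shade * (1 - 0.3 * radial),
            0.55 * shade * (1 - 0.35 * radial),
            0.12 * shade * np.ones_like(radial),
        ], axis=1)
        image[yy, xx] = np.clip(green, 0, 1)
        mask[yy, xx] = 1

    if spec.background == "paddy" and spec.reflection:
        # blurred plant reflections on the water; background label is kept
        refl = np.zeros((h, w))
        for (cy, cx), radius in zip(crop_centers, crop_radii):
            ry = min(h - 1, int(cy + 2.2 * radius))
            foot = _rosette_mask(h, w, ry, cx, 0.8 * radius, 6, 0.0)
            refl[foot] += 1.0
        refl = ndimage.gaussian_filter(refl, 3.0)
        image[:, :, 1] = np.clip(image[:, :, 1] + 0.12 * refl, 0, 1)

    # weeds: small and dispersed; drawn after crops so overlapping weeds win
    keepout = ndimage.binary_dilation(crop_pixels, iterations=2)
    for _ in range(spec.n_weeds):
        radius = rng.uniform(*spec.weed_radius_range)
        allow_overlap = rng.random() < spec.overlap_prob
        for attempt in range(200):
            cy = rng.uniform(radius, h - 1 - radius)
            cx = rng.uniform(radius, w - 1 - radius)
            foot = _weed_mask(h, w, cy, cx, radius, rng)
            if not foot.any():
                continue
            if allow_overlap or not (foot & keepout).any():
                break
        else:
            continue  # crowded canvas: skip this weed rather than fail
        yy, xx = np.nonzero(foot)
        shade = rng.uniform(0.8, 1.2)
        image[yy, xx] = np.clip(
            np.stack([0.20 * shade * np.ones_like(yy, dtype=float),
                      0.48 * shade * np.ones_like(yy, dtype=float),
                      0.10 * shade * np.ones_like(yy, dtype=float)], axis=1), 0, 1)
        mask[yy, xx] = 2

    if spec.noise_level > 0:
        image = image + rng.normal(0.0, spec.noise_level, image.shape)
    return np.clip(image, 0.0, 1.0), mask


def generate_synthetic_dataset(spec: SceneSpec, n_train: int, n_val: int,
                               n_test: int, seed: int = 0,
                               augment_per_scene: int = 0):
    """Three disjoint lists of (image, mask) pairs.

    Each split draws scene seeds from its own child of ``seed``'s seed
    sequence, so splits never share a scene; augmentation (when requested)
    is applied within each split only, after splitting.
    """
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split sizes must be non-negative")
    children = np.random.SeedSequence(seed).spawn(3)
    splits = []
    for n, child in zip((n_train, n_val, n_test), children):
        scene_seeds = child.generate_state(max(n, 1), dtype=np.uint32)[:n]
        pairs = []
        for s in scene_seeds:
            img, msk = generate_synthetic_scene(replace(spec, seed=int(s)))
            pairs.append((img, msk))
            for k in range(augment_per_scene):
                pairs.append(augment(img, msk, seed=int(s) + 1 + k))
        splits.append(pairs)
    return tuple(splits)


def compute_channel_stats(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and standard deviation over an image list."""
    pixels = np.concatenate([np.asarray(img).reshape(-1, 3) for img, _ in pairs])
    return pixels.mean(axis=0), pixels.std(axis=0)


# ---------------------------------------------------------------------------
# dataset directory layout: images/ + masks/ with matching stems
# ---------------------------------------------------------------------------

def write_dataset(root: str, pairs, prefix: str = "scene") -> None:
    img_dir = os.path.join(root, "images")
    mask_dir = os.path.join(root, "masks")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(mask_dir, exist_ok=True)
    for i, (image, mask) in enumerate(pairs):
        stem = f"{prefix}_{i:04d}"
        arr = np.asarray(image)
        if arr.dtype != np.uint8:
            arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(os.path.join(img_dir, stem + ".png"))
        Image.fromarray(encode_color_mask(mask)).save(
            os.path.join(mask_dir, stem + ".png"))


def read_dataset(root: str):
    """Load aligned (image, mask) pairs from an images/ + masks/ layout."""
    img_dir = os.path.join(root, "images")
    mask_dir = os.path.join(root, "masks")
    if not os.path.isdir(img_dir) or not os.path.isdir(mask_dir):
        raise FileNotFoundError(f"{root} needs images/ and masks/ subdirectories")
    pairs = []
    for fname in sorted(os.listdir(img_dir)):
        stem, ext = os.path.splitext(fname)
        if ext.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        mask_path = os.path.join(mask_dir, stem + ".png")
        if not os.path.exists(mask_path):
            raise FileNotFoundError(f"no mask for image {fname}")
        image = np.asarray(Image.open(os.path.join(img_dir, fname)).convert("RGB"))
        mask = decode_color_mask(np.asarray(Image.open(mask_path).convert("RGB")))
        pairs.append((image.astype(np.float64) / 255.0, mask))
    return pairs
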