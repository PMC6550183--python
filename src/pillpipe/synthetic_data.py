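"""Procedural pill-scene generation for segmentation and classification.

The generator emulates the two image styles of pill-recognition datasets:

* *reference* images — a single pill photographed on a uniform gray
  background (RGB about (117, 117, 117)), from which cut-out sprites are
  keyed;
* *consumer* images — one to five pills composited onto textured
  backgrounds (paper, noise, stripes, wood-like gradients) with random
  rotation, scaling to a 20-50 px footprint, and a 0-20 px drop shadow.

Every composite carries exact per-instance masks, tight bounding boxes and
NDC labels, so it doubles as segmentation ground truth.  All randomness flows
through seeded :class:`numpy.random.Generator` streams; a scene is
reproducible from ``(dataset_seed, scene_index)``.

Coordinates are 0-based row-major; boxes are half-open ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from scipy import ndimage
from skimage.transform import AffineTransform, ProjectiveTransform, warp

from .errors import InvalidArgument, NoPillFound, PlacementFailed

REFERENCE_BG = (117, 117, 117)

SHAPE_ASPECT = {"ROUND": 1.0, "OVAL": 0.62, "CAPSULE": 0.45}

COLOR_TABLE = {
    "WHITE": (235, 233, 228), "YELLOW": (228, 200, 60), "RED": (190, 45, 45),
    "ORANGE": (230, 140, 40), "PINK": (235, 160, 180), "BLUE": (60, 95, 190),
    "GREEN": (70, 160, 90), "BROWN": (130, 85, 50), "PURPLE": (130, 70, 160),
    "GRAY": (150, 150, 150),
}


def _nearest_color_tag(rgb) -> str:
    arr = np.asarray(rgb, dtype=float)
    best = min(COLOR_TABLE, key=lambda k: np.sum((np.asarray(COLOR_TABLE[k]) - arr) ** 2))
    return best


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Half-open tight bounding box (r0, c0, r1, c1) of a boolean mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise InvalidArgument("mask has no foreground pixel")
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


# ------------------------------------------------------------------ types --

@dataclass
class PillSprite:
    """A tight-cropped pill cut-out with a binary alpha mask."""
    image: np.ndarray          # (H, W, 3) uint8
    alpha: np.ndarray          # (H, W) bool
    ndc: str
    color_tag: str
    shape_tag: str

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.uint8)
        self.alpha = np.asarray(self.alpha, dtype=bool)
        if self.image.shape[:2] != self.alpha.shape:
            raise InvalidArgument("sprite image and alpha dimensions differ")
        if not self.alpha.any():
            raise InvalidArgument("sprite alpha has no foreground pixel")
        r0, c0, r1, c1 = tight_bbox(self.alpha)
        if (r0, c0) != (0, 0) or (r1, c1) != self.alpha.shape:
            raise InvalidArgument("sprite must be tight-cropped to its alpha")


@dataclass
class SceneParams:
    """Sampling ranges for consumer-style scene composition."""
    n_pills_range: tuple[int, int] = (1, 5)
    rotation_range_deg: tuple[float, float] = (0.0, 360.0)
    pill_size_px_range: tuple[int, int] = (20, 50)
    shadow_offset_px_range: tuple[int, int] = (0, 20)
    canvas: tuple[int, int] = (480, 640)
    max_place_retries: int = 30

    def __post_init__(self):
        for name in ("n_pills_range", "rotation_range_deg",
                     "pill_size_px_range", "shadow_offset_px_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise InvalidArgument(f"{name} is empty: {lo}..{hi}")
        if self.pill_size_px_range[0] <= 0:
            raise InvalidArgument("pill size range must be positive")

    def scaled_down(self, canvas=(96, 128)) -> "SceneParams":
        """Proportionally shrunk variant for small-resolution experiments."""
        f = canvas[0] / self.canvas[0]
        size = (max(6, round(self.pill_size_px_range[0] * f * 2)),
                max(8, round(self.pill_size_px_range[1] * f * 2)))
        shadow = (round(self.shadow_offset_px_range[0] * f),
                  max(1, round(self.shadow_offset_px_range[1] * f)))
        return replace(self, canvas=canvas, pill_size_px_range=size,
                       shadow_offset_px_range=shadow,
                       n_pills_range=(1, min(3, self.n_pills_range[1])))


@dataclass
class CompositeScene:
    image: np.ndarray                     # (H, W, 3) uint8
    instance_masks: list[np.ndarray]      # list of (H, W) bool
    union_mask: np.ndarray                # (H, W) bool
    boxes: list[tuple[int, int, int, int]]
    labels: list[str]

    def validate(self):
        assert np.array_equal(self.union_mask,
                              np.logical_or.reduce([np.zeros_like(self.union_mask)]
                                                   + self.instance_masks))
        assert len(self.instance_masks) == len(self.boxes) == len(self.labels)
        for m, b in zip(self.instance_masks, self.boxes):
            assert tight_bbox(m) == tuple(b)
        return self


@dataclass
class AugmentConfig:
    """Photometric + geometric augmentation ranges.

    The default configuration is the identity: every range is degenerate and
    every application probability is zero, which must reproduce the input
    bit-exactly.
    """
    brightness_delta_range: tuple[float, float] = (0.0, 0.0)
    contrast_factor_range: tuple[float, float] = (1.0, 1.0)
    gaussian_blur_sigma_range: tuple[float, float] = (0.0, 0.0)
    rotation_deg_range: tuple[float, float] = (0.0, 0.0)
    scale_range: tuple[float, float] = (1.0, 1.0)
    shear_deg_range: tuple[float, float] = (0.0, 0.0)
    translate_px_range: tuple[float, float] = (0.0, 0.0)
    perspective_jitter_px: float = 0.0
    p_brightness: float = 0.0
    p_contrast: float = 0.0
    p_blur: float = 0.0
    p_affine: float = 0.0
    p_perspective: float = 0.0

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls()

    @classmethod
    def default_training(cls) -> "AugmentConfig":
        return cls(brightness_delta_range=(-30.0, 30.0),
                   contrast_factor_range=(0.7, 1.3),
                   gaussian_blur_sigma_range=(0.0, 1.5),
                   rotation_deg_range=(-15.0, 15.0),
                   scale_range=(0.9, 1.1),
                   shear_deg_range=(-5.0, 5.0),
                   translate_px_range=(-10.0, 10.0),
                   perspective_jitter_px=8.0,
                   p_brightness=0.5, p_contrast=0.5, p_blur=0.3,
                   p_affine=0.5, p_perspective=0.3)


# ---------------------------------------------------------------- sprites --

_SUPER = 4


def make_pill_sprite(shape_tag: str, color, size_px: int, imprint_text: str = "",
                     seed: int = 0) -> PillSprite:
    """Draw an anti-aliased synthetic pill sprite.

    ``color`` is either a tag from :data:`COLOR_TABLE` or an RGB triple.  The
    tight alpha bounding box has max dimension exactly ``size_px``.  The
    raster is deterministic per ``seed`` (seed drives shading/noise detail).
    """
    if shape_tag not in SHAPE_ASPECT:
        raise InvalidArgument(f"unknown shape_tag {shape_tag!r}")
    if size_px < 8:
        raise InvalidArgument("size_px must be >= 8")
    if isinstance(color, str):
        tag = color.upper()
        if tag not in COLOR_TABLE:
            raise InvalidArgument(f"unknown color tag {color!r}")
        rgb = COLOR_TABLE[tag]
    else:
        rgb = tuple(int(c) for c in color)
        tag = _nearest_color_tag(rgb)
    rng = np.random.default_rng(seed)

    w = size_px
    h = max(8, round(size_px * SHAPE_ASPECT[shape_tag]))
    sw, sh = w * _SUPER, h * _SUPER
    shape_img = Image.new("L", (sw, sh), 0)
    d = ImageDraw.Draw(shape_img)
    if shape_tag == "ROUND" or shape_tag == "OVAL":
        d.ellipse([0, 0, sw - 1, sh - 1], fill=255)
    else:  # CAPSULE: stadium = rounded rectangle, radius = half height
        d.rounded_rectangle([0, 0, sw - 1, sh - 1], radius=sh // 2, fill=255)

    base = np.asarray(rgb, dtype=float)
    jitter = rng.normal(0, 6, size=3)
    body = np.clip(base + jitter, 0, 255)

    # simple top-left highlight shading for a convex look
    yy, xx = np.mgrid[0:sh, 0:sw]
    gx = (xx / max(sw - 1, 1)) - 0.35
    gy = (yy / max(sh - 1, 1)) - 0.35
    shade = 1.0 - 0.25 * np.sqrt(gx ** 2 + gy ** 2)
    img = body[None, None, :] * shade[:, :, None]
    noise = rng.normal(0, 3.0, size=(sh, sw, 1))
    img = np.clip(img + noise, 0, 255).astype(np.uint8)
    pil_img = Image.fromarray(img)

    if imprint_text:
        dark = tuple(int(v * 0.55) for v in body)
        dimg = ImageDraw.Draw(pil_img)
        font = ImageFont.load_default()
        tw, th = dimg.textbbox((0, 0), imprint_text, font=font)[2:]
        # draw at supersampled scale so the imprint survives downsampling
        txt = Image.new("L", (max(tw, 1), max(th, 1)), 0)
        ImageDraw.Draw(txt).text((0, 0), imprint_text, fill=255, font=font)
        scale = max(1, int(0.5 * sh / max(th, 1)))
        txt = txt.resize((txt.width * scale, txt.height * scale), Image.NEAREST)
        ox = (sw - txt.width) // 2
        oy = (sh - txt.height) // 2
        stamp = Image.new("RGB", txt.size, dark)
        pil_img.paste(stamp, (ox, oy), txt)

    pil_img = pil_img.resize((w, h), Image.BOX)
    coverage = shape_img.resize((w, h), Image.BOX)
    alpha = np.asarray(coverage) >= 128
    image = np.asarray(pil_img, dtype=np.uint8)

    r0, c0, r1, c1 = tight_bbox(alpha)
    alpha = alpha[r0:r1, c0:c1]
    image = image[r0:r1, c0:c1]
    if max(alpha.shape) != size_px:  # guard: anti-aliased edge shaved a pixel
        img_p = Image.fromarray(image)
        a_p = Image.fromarray(alpha.astype(np.uint8) * 255)
        f = size_px / max(alpha.shape)
        new = (max(1, round(alpha.shape[1] * f)), max(1, round(alpha.shape[0] * f)))
        if np.argmax(alpha.shape) == 0:
            new = (new[0], size_px)
        else:
            new = (size_px, new[1])
        image = np.asarray(img_p.resize(new, Image.BILINEAR))
        alpha = np.asarray(a_p.resize(new, Image.NEAREST)) >= 128
    return PillSprite(image=image, alpha=alpha, ndc=f"synthetic-{shape_tag.lower()}-{seed}",
                      color_tag=tag, shape_tag=shape_tag)


def extract_reference_cutout(reference_image: np.ndarray,
                             bg_color=REFERENCE_BG, tol: int = 1,
                             ndc: str = "", color_tag: str = "",
                             shape_tag: str = "") -> PillSprite:
    """Key the pill out of a uniform-gray reference image.

    A pixel is background when *every* channel lies within ``tol`` of the
    corresponding ``bg_color`` channel (per-channel tolerance).  The pill is
    the largest 8-connected foreground component, returned tight-cropped.
    """
    img = np.asarray(reference_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidArgument("reference image must be H x W x 3")
    diff = np.abs(img.astype(int) - np.asarray(bg_color, dtype=int))
    fg = (diff > tol).any(axis=2)
    if not fg.any():
        raise NoPillFound("no non-background pixel in reference image")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = labels == (1 + int(np.argmax(sizes)))
    r0, c0, r1, c1 = tight_bbox(keep)
    alpha = keep[r0:r1, c0:c1]
    crop = img[r0:r1, c0:c1].astype(np.uint8)
    if not color_tag:
        mean_rgb = crop[alpha].mean(axis=0)
        color_tag = _nearest_color_tag(mean_rgb)
    if not shape_tag:
        shape_tag = "ROUND"
    return PillSprite(image=crop, alpha=alpha, ndc=ndc or "unknown",
                      color_tag=color_tag, shape_tag=shape_tag)


# ------------------------------------------------------------ backgrounds --

BACKGROUND_KINDS = ("flat", "noise", "stripes", "wood", "paper")


def make_background(kind: str, shape=(480, 640), rng=None) -> np.ndarray:
    """Procedural background texture (office-ish surfaces), uint8 HxWx3."""
    rng = rng or np.random.default_rng(0)
    h, w = shape
    if kind == "flat":
        base = rng.integers(40, 216, size=3)
        img = np.tile(base, (h, w, 1)).astype(float)
    elif kind == "noise":
        base = rng.integers(60, 196, size=3).astype(float)
        img = base + rng.normal(0, 18, size=(h, w, 3))
    elif kind == "stripes":
        base = rng.integers(60, 180, size=3).astype(float)
        period = int(rng.integers(8, 40))
        amp = float(rng.integers(10, 50))
        phase = np.arange(w) * (2 * np.pi / period)
        stripe = amp * np.sin(phase)[None, :, None]
        img = np.tile(base, (h, w, 1)) + stripe
    elif kind == "wood":
        base = np.array([150, 105, 60], dtype=float) + rng.normal(0, 12, 3)
        yy = np.arange(h)[:, None] / h
        rings = 18 * np.sin(yy * rng.uniform(20, 60) + rng.uniform(0, 6))
        img = np.tile(base, (h, w, 1)) + rings[:, :, None]
        img += rng.normal(0, 4, size=(h, w, 3))
    elif kind == "paper":
        base = rng.integers(200, 246)
        img = np.full((h, w, 3), float(base)) + rng.normal(0, 5, size=(h, w, 3))
    else:
        raise InvalidArgument(f"unknown background kind {kind!r}")
    return np.clip(img, 0, 255).astype(np.uint8)


def _fit_background(background: np.ndarray, canvas: tuple[int, int]) -> np.ndarray:
    h, w = canvas
    bg = np.asarray(background, dtype=np.uint8)
    if bg.shape[0] < h or bg.shape[1] < w:
        reps = (-(-h // bg.shape[0]), -(-w // bg.shape[1]), 1)
        bg = np.tile(bg, reps)
    return bg[:h, :w].copy()


# ----------------------------------------------------------- composition --

def _rotate_sprite(sprite: PillSprite, angle_deg: float):
    if angle_deg % 360.0 == 0.0:
        return sprite.image.copy(), sprite.alpha.copy()
    rgba = np.dstack([sprite.image, sprite.alpha.astype(np.uint8) * 255])
    rot = Image.fromarray(rgba, "RGBA").rotate(angle_deg, expand=True,
                                               resample=Image.BILINEAR)
    arr = np.asarray(rot)
    alpha = arr[:, :, 3] >= 128
    return arr[:, :, :3].copy(), alpha


def _scale_to(image: np.ndarray, alpha: np.ndarray, target_max: int):
    r0, c0, r1, c1 = tight_bbox(alpha)
    image, alpha = image[r0:r1, c0:c1], alpha[r0:r1, c0:c1]
    h, w = alpha.shape
    f = target_max / max(h, w)
    if h >= w:
        new = (max(1, round(w * f)), target_max)
    else:
        new = (target_max, max(1, round(h * f)))
    img = np.asarray(Image.fromarray(image).resize(new, Image.BILINEAR))
    a = np.asarray(Image.fromarray(alpha.astype(np.uint8) * 255)
                   .resize(new, Image.NEAREST)) >= 128
    r0, c0, r1, c1 = tight_bbox(a)
    return img[r0:r1, c0:c1], a[r0:r1, c0:c1]


def _uniform(rng, lo, hi):
    return lo if hi == lo else rng.uniform(lo, hi)


def compose_scene(sprites_pool: list[PillSprite], background: np.ndarray,
                  params: SceneParams = None, rng=None) -> CompositeScene:
    """Composite 1-5 pills (per ``params``) onto a background with shadows.

    Per pill: rotation uniform in ``rotation_range_deg``, scale such that the
    alpha bounding box's max dimension is uniform in ``pill_size_px_range``,
    and a drop shadow offset uniform in ``shadow_offset_px_range`` in a random
    direction, rendered as a Gaussian-blurred darkening of the background
    beneath the pill.  Placements rejecting instance-mask overlap are retried
    up to ``params.max_place_retries`` times before :class:`PlacementFailed`.
    """
    if not sprites_pool:
        raise InvalidArgument("sprites_pool is empty")
    params = params or SceneParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    H, W = params.canvas
    canvas = _fit_background(background, (H, W)).astype(float)

    n_lo, n_hi = params.n_pills_range
    n = int(rng.integers(n_lo, n_hi + 1))
    occupied = np.zeros((H, W), dtype=bool)
    instance_masks, boxes, labels = [], [], []

    for _ in range(n):
        sprite = sprites_pool[int(rng.integers(len(sprites_pool)))]
        angle = float(_uniform(rng, *params.rotation_range_deg))
        s_lo, s_hi = params.pill_size_px_range
        size = int(rng.integers(s_lo, s_hi + 1))
        off_lo, off_hi = params.shadow_offset_px_range
        offset = int(rng.integers(off_lo, off_hi + 1))
        direction = float(rng.uniform(0.0, 360.0))

        img, alpha = _rotate_sprite(sprite, angle)
        img, alpha = _scale_to(img, alpha, size)
        h, w = alpha.shape
        if h > H or w > W:
            raise PlacementFailed("pill larger than canvas")

        placed = False
        for _attempt in range(params.max_place_retries):
            r0 = int(rng.integers(0, H - h + 1))
            c0 = int(rng.integers(0, W - w + 1))
            if not (occupied[r0:r0 + h, c0:c0 + w] & alpha).any():
                placed = True
                break
        if not placed:
            raise PlacementFailed(
                f"could not place pill after {params.max_place_retries} retries")

        inst = np.zeros((H, W), dtype=bool)
        inst[r0:r0 + h, c0:c0 + w] = alpha

        if offset > 0:
            theta = np.deg2rad(direction)
            dr = int(round(offset * np.sin(theta)))
            dc = int(round(offset * np.cos(theta)))
            shadow = np.zeros((H, W), dtype=float)
            sr0, sc0 = r0 + dr, c0 + dc
            rr0, rr1 = max(sr0, 0), min(sr0 + h, H)
            cc0, cc1 = max(sc0, 0), min(sc0 + w, W)
            if rr0 < rr1 and cc0 < cc1:
                shadow[rr0:rr1, cc0:cc1] = alpha[rr0 - sr0:rr1 - sr0,
                                                 cc0 - sc0:cc1 - sc0]
            sigma = max(offset / 3.0, 1.0)
            shadow = ndimage.gaussian_filter(shadow, sigma)
            canvas *= (1.0 - 0.5 * shadow)[:, :, None]

        region = canvas[r0:r0 + h, c0:c0 + w]
        region[alpha] = img[alpha]
        occupied |= inst
        instance_masks.append(inst)
        boxes.append(tight_bbox(inst))
        labels.append(sprite.ndc)

    union = np.logical_or.reduce([np.zeros((H, W), dtype=bool)] + instance_masks)
    return CompositeScene(image=np.clip(canvas, 0, 255).astype(np.uint8),
                          instance_masks=instance_masks, union_mask=union,
                          boxes=boxes, labels=labels)


# ----------------------------------------------------------- augmentation --

def augment_pair(image: np.ndarray, mask: np.ndarray,
                 config: AugmentConfig = None, rng=None):
    """Apply photometric transforms to the image and geometric ones to both.

    The mask is warped with the same geometric transform and re-binarized at
    0.5.  A fully degenerate config returns the inputs bit-identically.
    """
    config = config or AugmentConfig.identity()
    rng = rng if rng is not None else np.random.default_rng(0)
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise InvalidArgument("image and mask spatial sizes differ")
    img = image.astype(float)
    msk = mask.astype(bool)
    changed_photo = False
    c = config

    if c.p_brightness > 0 and rng.random() < c.p_brightness:
        delta = _uniform(rng, *c.brightness_delta_range)
        if delta != 0.0:
            img = img + delta
            changed_photo = True
    if c.p_contrast > 0 and rng.random() < c.p_contrast:
        f = _uniform(rng, *c.contrast_factor_range)
        if f != 1.0:
            img = (img - 127.5) * f + 127.5
            changed_photo = True
    if c.p_blur > 0 and rng.random() < c.p_blur:
        sigma = _uniform(rng, *c.gaussian_blur_sigma_range)
        if sigma > 0:
            img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0)[:img.ndim])
            changed_photo = True

    tform = None
    if c.p_affine > 0 and rng.random() < c.p_affine:
        rot = np.deg2rad(_uniform(rng, *c.rotation_deg_range))
        scale = _uniform(rng, *c.scale_range)
        shear = np.deg2rad(_uniform(rng, *c.shear_deg_range))
        tr, tc = (_uniform(rng, *c.translate_px_range),
                  _uniform(rng, *c.translate_px_range))
        if (rot, scale, shear, tr, tc) != (0.0, 1.0, 0.0, 0.0, 0.0):
            h, w = msk.shape[:2]
            center = np.array([w / 2.0, h / 2.0])
            shift = AffineTransform(translation=-center)
            core = AffineTransform(rotation=rot, scale=scale, shear=shear)
            back = AffineTransform(translation=center + np.array([tc, tr]))
            tform = shift + core + back
    if c.p_perspective > 0 and rng.random() < c.p_perspective:
        j = c.perspective_jitter_px
        if j > 0:
            h, w = msk.shape[:2]
            src = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
            dst = src + rng.uniform(-j, j, size=(4, 2))
            p = ProjectiveTransform()
            p.estimate(src, dst)
            tform = p if tform is None else tform + p

    if tform is not None:
        img = warp(img, tform.inverse, order=1, mode="edge", preserve_range=True)
        msk = warp(msk.astype(float), tform.inverse, order=1, mode="constant",
                   cval=0.0, preserve_range=True) > 0.5
    elif not changed_photo:
        return image.copy(), mask.copy()

    out_img = np.clip(img, 0, 255).astype(image.dtype)
    out_mask = msk if mask.dtype == bool else msk.astype(mask.dtype) * (
        255 if mask.dtype == np.uint8 and mask.max() > 1 else 1)
    return out_img, out_mask


# ---------------------------------------------------------------- dataset --

_CATALOG_SPECS = [
    ("ROUND", "WHITE", "L5"), ("ROUND", "YELLOW", "A2"), ("ROUND", "PINK", ""),
    ("OVAL", "BLUE", "M10"), ("OVAL", "ORANGE", ""), ("OVAL", "WHITE", "ZC"),
    ("CAPSULE", "RED", "T7"), ("CAPSULE", "GREEN", ""), ("CAPSULE", "PURPLE", "RX1"),
    ("ROUND", "BROWN", "88"), ("OVAL", "GREEN", "E4"), ("CAPSULE", "BLUE", ""),
    ("ROUND", "GRAY", "P"), ("OVAL", "PINK", "V2"), ("CAPSULE", "YELLOW", "Q9"),
    ("ROUND", "RED", ""), ("OVAL", "PURPLE", "DX"), ("CAPSULE", "WHITE", "10"),
    ("ROUND", "BLUE", "B1"), ("OVAL", "BROWN", ""),
]


def make_default_catalog(n: int = 20, base_size: int = 96, seed: int = 0
                         ) -> list[PillSprite]:
    """Deterministic catalog of synthetic pill sprites with NDC-style codes."""
    sprites = []
    for i in range(n):
        shape, color, imprint = _CATALOG_SPECS[i % len(_CATALOG_SPECS)]
        s = make_pill_sprite(shape, color, base_size, imprint, seed=seed * 1000 + i)
        s.ndc = f"{10000 + i:05d}-{100 + i:03d}"
        sprites.append(s)
    return sprites


def generate_dataset(n_images: int, scene_config: SceneParams, out_dir: str,
                     seed: int = 0, sprites_pool=None, backgrounds=None) -> dict:
    """Write ``n_images`` PNG image/mask pairs plus a JSON manifest.

    Masks are single-channel PNGs with values {0, 255} (union of instances).
    The manifest is byte-reproducible for a given seed (no timestamps).
    """
    if n_images < 0:
        raise InvalidArgument("n_images must be >= 0")
    os.makedirs(out_dir, exist_ok=True)
    scene_config = scene_config or SceneParams()
    sprites_pool = sprites_pool or make_default_catalog(seed=seed % 1000)
    entries = []
    for i in range(n_images):
        rng = np.random.default_rng([seed % (2 ** 31), i])
        for attempt in range(10):
            try:
                if backgrounds is not None:
                    bg = backgrounds[int(rng.integers(len(backgrounds)))]
                else:
                    kind = BACKGROUND_KINDS[int(rng.integers(len(BACKGROUND_KINDS)))]
                    bg = make_background(kind, scene_config.canvas, rng)
                scene = compose_scene(sprites_pool, bg, scene_config, rng)
                break
            except PlacementFailed:
                if attempt == 9:
                    raise
        img_name = f"img_{i:05d}.png"
        mask_name = f"mask_{i:05d}.png"
        Image.fromarray(scene.image).save(os.path.join(out_dir, img_name))
        Image.fromarray(scene.union_mask.astype(np.uint8) * 255).save(
            os.path.join(out_dir, mask_name))
        entries.append({"image": img_name, "mask": mask_name,
                        "boxes": [list(b) for b in scene.boxes],
                        "labels": scene.labels})
    manifest = {"version": 1, "seed": seed,
                "canvas": list(scene_config.canvas), "entries": entries}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_manifest_arrays(out_dir: str):
    """Load images and union masks referenced by a dataset manifest."""
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    images, masks = [], []
    for e in manifest["entries"]:
        images.append(np.asarray(Image.open(os.path.join(out_dir, e["image"]))))
        masks.append(np.asarray(Image.open(os.path.join(out_dir, e["mask"]))) >= 128)
    return np.stack(images) if images else np.empty((0,)), \
        np.stack(masks) if masks else np.empty((0,)), manifest


# ------------------------------------------------- classification fixture --

def generate_classification_set(n_classes: int = 10, per_class: int = 100,
                                seed: int = 0, crop_size: int = 224,
                                consumer_fraction: float = 0.75,
                                augment: bool = True) -> dict:
    """Synthetic NDC-labelled crop set for classifier experiments.

    Emulates the dataset's two sources: consumer-style crops (textured
    background, random pose/lighting) and reference-style crops (uniform gray
    backdrop).  Returns crops standardized exactly as the pipeline would feed
    a classifier, plus per-class color/shape attributes for grouped-confusion
    analyses.  ``augment=False`` skips the photometric jitter on consumer
    crops (clean renders, e.g. for overfit sanity checks).
    """
    from .standardize import crop_pad_resize

    rng = np.random.default_rng(seed)
    classes = []
    for k in range(n_classes):
        shape, color, imprint = _CATALOG_SPECS[k % len(_CATALOG_SPECS)]
        classes.append({"ndc": f"{20000 + k:05d}-{200 + k:03d}",
                        "shape": shape, "color": color, "imprint": imprint})
    crops, labels, is_consumer = [], [], []
    aug = AugmentConfig(brightness_delta_range=(-25, 25),
                        contrast_factor_range=(0.8, 1.2),
                        gaussian_blur_sigma_range=(0.0, 1.0),
                        p_brightness=0.7, p_contrast=0.7, p_blur=0.3)
    for k, cls in enumerate(classes):
        for j in range(per_class):
            item_rng = np.random.default_rng([seed % (2 ** 31), k, j])
            consumer = item_rng.random() < consumer_fraction
            sprite = make_pill_sprite(cls["shape"], cls["color"],
                                      96, cls["imprint"],
                                      seed=seed * 997 + k)
            if consumer:
                kind = BACKGROUND_KINDS[int(item_rng.integers(len(BACKGROUND_KINDS)))]
                bg = make_background(kind, (192, 192), item_rng)
            else:
                bg = np.full((192, 192, 3), REFERENCE_BG, dtype=np.uint8)
            params = SceneParams(n_pills_range=(1, 1),
                                 pill_size_px_range=(70, 130),
                                 shadow_offset_px_range=(0, 10) if consumer else (0, 0),
                                 canvas=(192, 192))
            scene = compose_scene([sprite], bg, params, item_rng)
            image = scene.image
            if consumer and augment:
                image, _ = augment_pair(image, scene.union_mask, aug, item_rng)
            crop = crop_pad_resize(image, scene.boxes[0], out_size=crop_size)
            crops.append(crop.image)
            labels.append(k)
            is_consumer.append(consumer)
    order = rng.permutation(len(crops))
    return {
        "crops": np.stack(crops)[order],
        "labels": np.asarray(labels)[order],
        "is_consumer": np.asarray(is_consumer)[order],
        "class_ndcs": [c["ndc"] for c in classes],
        "class_colors": [c["color"] for c in classes],
        "class_shapes": [c["shape"] for c in classes],
    }
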