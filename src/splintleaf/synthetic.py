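"""Seeded synthetic leaf imagery with exact ground truth.

Emulates the imaging conditions of a single-leaf acquisition rig: one
rapeseed-like leaf on a light background, a 5 mm x 5 mm calibration square
of a reserved color in a corner of the frame, day/night illumination, the
visual symptoms of macronutrient deficiency, and the artifacts specific to
each area-measurement method:

* ``splint``     — leaf clamped flat between transparent plates: the imaged
                   silhouette equals the true outline (no artifact);
* ``stretching`` — five margin clips occlude tissue, so the observed
                   silhouette under-counts the leaf (negative area bias);
* ``manual``     — a hand-held, slightly tilted photograph: a mild
                   projective warp inflates the silhouette and low-frequency
                   fold shading modulates brightness (positive area bias).

Leaf outlines are Fourier-perturbed ellipses, so every sample carries an
exact analytic polygon area alongside its rasterized mask, and masks are
rasterized with a pixel-center-in-polygon rule (0-based indices, origin at
the top-left corner).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import ndimage
from skimage.transform import ProjectiveTransform, warp

TREATMENTS = ("CK", "N_def", "P_def", "K_def", "Mg_def")
METHODS = ("splint", "stretching", "manual")
ILLUMINATIONS = ("day", "night")

#: Reserved calibration-marker color, absent from leaf and background palettes.
CALIBRATION_COLOR = (255, 0, 255)

_LEAF_GREEN = np.array([62.0, 138.0, 70.0])
_YELLOW = np.array([205.0, 190.0, 60.0])
_BACKGROUND = np.array([231.0, 229.0, 224.0])
_CLIP_COLOR = np.array([70.0, 70.0, 75.0])


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for one synthetic leaf sample.

    Defaults place a 20 px calibration square (5 mm at 0.25 mm/px) in the
    top-left corner of a 128 x 128 frame and draw leaves of 150-450 mm^2
    (2,400-7,200 px), large enough that rasterization error is negligible
    yet small enough never to reach the calibration corner.
    """

    image_height: int = 128
    image_width: int = 128
    mm_per_pixel: float = 0.25
    calibration_side_mm: float = 5.0
    leaf_area_range_mm2: tuple[float, float] = (150.0, 450.0)
    treatment: str = "CK"
    method: str = "splint"
    illumination: str = "day"
    noise_sd: float = 4.0
    clip_size_px: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dims must be >= 64")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be > 0")
        lo, hi = self.leaf_area_range_mm2
        if not lo < hi:
            raise ValueError("leaf_area_range_mm2 must satisfy min < max")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}; "
                             f"choose from {TREATMENTS}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; "
                             f"choose from {METHODS}")
        if self.illumination not in ILLUMINATIONS:
            raise ValueError(f"unknown illumination {self.illumination!r}")
        side_px = self.calibration_side_mm / self.mm_per_pixel
        if side_px + 2 * _CAL_MARGIN > min(self.image_height, self.image_width):
            raise ValueError("calibration square does not fit in frame")

    @property
    def calibration_area_mm2(self) -> float:
        return self.calibration_side_mm ** 2


_CAL_MARGIN = 4  # px between frame edge and calibration square


@dataclass
class LeafSample:
    """One synthetic acquisition with exact ground truth.

    ``mask`` is the *observed* silhouette (what a perfect segmenter would
    recover from ``image``); ``unoccluded_mask`` is the silhouette before
    method artifacts, and ``true_area_mm2`` is its pixel count scaled to
    mm^2 — the stand-in for the destructive scanner standard.
    """

    image: np.ndarray            # H x W x 3 uint8
    mask: np.ndarray             # H x W uint8 {0, 1}, observed
    unoccluded_mask: np.ndarray  # H x W uint8 {0, 1}, before artifacts
    true_area_mm2: float
    calibration_pixel_count: int
    calibration_area_mm2: float
    calibration_region: tuple[int, int, int, int]   # (r0, c0, r1, c1) half-open
    outline_xy: np.ndarray       # analytic outline polygon, (n, 2) (x, y)
    metadata: GeneratorParams


def shoelace_area(vertices_xy: np.ndarray) -> float:
    """Polygon area (shoelace formula) of an (n, 2) vertex array."""
    v = np.asarray(vertices_xy, dtype=np.float64)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _leaf_outline(rng: np.random.Generator, curl: bool) -> np.ndarray:
    """Unit-scale Fourier-perturbed ellipse, (n, 2), centered at origin."""
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    r = np.ones_like(theta)
    n_harm = int(rng.integers(3, 9))
    for k in range(2, 2 + n_harm):
        amp = rng.uniform(0.02, 0.10) / np.sqrt(k)
        r += amp * np.cos(k * theta + rng.uniform(0.0, 2.0 * np.pi))
    if curl:
        # phosphorus-deficiency curl: extra high-frequency margin distortion
        for k in (9, 11, 13):
            r += 0.05 * np.cos(k * theta + rng.uniform(0.0, 2.0 * np.pi))
    r = np.clip(r, 0.35, None)
    aspect = rng.uniform(0.65, 0.95)
    tilt = rng.uniform(0.0, np.pi)
    x = r * np.cos(theta)
    y = r * np.sin(theta) * aspect
    rot = np.array([[np.cos(tilt), -np.sin(tilt)], [np.sin(tilt), np.cos(tilt)]])
    return np.column_stack([x, y]) @ rot.T


def rasterize_polygon(vertices_xy: np.ndarray, height: int, width: int) -> np.ndarray:
    """Binary mask via pixel-center-in-polygon (center of pixel (r, c) is
    the point (c, r))."""
    path = MplPath(vertices_xy)
    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    inside = path.contains_points(pts)
    return inside.reshape(height, width).astype(np.uint8)


def _calibration_region(params: GeneratorParams) -> tuple[int, int, int, int]:
    side = int(round(params.calibration_side_mm / params.mm_per_pixel))
    return (_CAL_MARGIN, _CAL_MARGIN, _CAL_MARGIN + side, _CAL_MARGIN + side)


def generate_leaf(params: GeneratorParams) -> LeafSample:
    """Render one seeded leaf sample (before method artifacts are applied
    the returned ``mask`` equals ``unoccluded_mask``; call
    :func:`apply_method_artifacts` for the method-specific observation).

    Deterministic for a fixed seed.  Raises ``GenerationError`` if the leaf
    cannot be placed clear of the calibration square.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    r0, c0, r1, c1 = _calibration_region(params)

    target_mm2 = rng.uniform(*params.leaf_area_range_mm2)
    target_px = target_mm2 / params.mm_per_pixel ** 2

    # draw outlines until one fits the frame (an especially elongated draw
    # can exceed it); then place it clear of the calibration corner
    for _ in range(10):
        outline = _leaf_outline(rng, curl=(params.treatment == "P_def"))
        outline = outline * np.sqrt(target_px / shoelace_area(outline))
        dx0, dx1 = outline[:, 0].min(), outline[:, 0].max()
        dy0, dy1 = outline[:, 1].min(), outline[:, 1].max()
        xlo, xhi = 1.5 - dx0, (w - 2.5) - dx1
        ylo, yhi = 1.5 - dy0, (h - 2.5) - dy1
        if xhi >= xlo and yhi >= ylo:
            break
    else:
        raise GenerationError(
            "leaf outline larger than the frame; reduce leaf_area_range_mm2 "
            "or enlarge the frame")
    for _ in range(40):
        cx = rng.uniform(0.5 * (xlo + xhi), xhi)
        cy = rng.uniform(0.5 * (ylo + yhi), yhi)
        verts = outline + np.array([cx, cy])
        mask = rasterize_polygon(verts, h, w)
        if mask[max(0, r0 - 2):r1 + 2, max(0, c0 - 2):c1 + 2].any():
            continue
        break
    else:
        raise GenerationError(
            "could not place leaf without overlapping the calibration region; "
            "reduce leaf_area_range_mm2 or enlarge the frame")

    image = _render_colors(rng, params, mask)
    image = _stamp_calibration(image, (r0, c0, r1, c1))

    return LeafSample(
        image=image,
        mask=mask.copy(),
        unoccluded_mask=mask,
        true_area_mm2=float(mask.sum()) * params.mm_per_pixel ** 2,
        calibration_pixel_count=(r1 - r0) * (c1 - c0),
        calibration_area_mm2=params.calibration_area_mm2,
        calibration_region=(r0, c0, r1, c1),
        outline_xy=verts,
        metadata=params,
    )


def _render_colors(rng: np.random.Generator, params: GeneratorParams,
                   mask: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = _BACKGROUND
    # gentle diagonal background gradient
    gy, gx = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w),
                         indexing="ij")
    img += ((gy + gx) * 6.0)[..., None]

    leaf = np.tile(_LEAF_GREEN, (h, w, 1))
    # vein-like low-frequency texture
    tex = np.sin(gy * rng.uniform(6, 10) + rng.uniform(0, 6)) \
        * np.sin(gx * rng.uniform(6, 10) + rng.uniform(0, 6))
    leaf += (tex * 10.0)[..., None]

    t = params.treatment
    if t == "N_def":
        leaf = 0.5 * leaf + 0.5 * _YELLOW        # global yellowing
    elif t == "K_def":
        dist = ndimage.distance_transform_edt(mask)
        wgt = np.exp(-dist / 5.0)[..., None]     # marginal yellowing
        leaf = (1 - wgt) * leaf + wgt * _YELLOW
    elif t == "Mg_def":
        blobs = ndimage.gaussian_filter(rng.standard_normal((h, w)), 6.0)
        wgt = (1.0 / (1.0 + np.exp(-blobs * 8.0)))[..., None]  # patchy
        leaf = (1 - wgt) * leaf + wgt * _YELLOW

    m3 = mask.astype(bool)[..., None]
    img = np.where(m3, leaf, img)

    if params.illumination == "night":
        img *= 0.55
        ry = (np.arange(h) - h / 2.0) / h
        rx = (np.arange(w) - w / 2.0) / w
        lamp = 1.25 * np.exp(-(ry[:, None] ** 2 + rx[None, :] ** 2) / 0.35)
        img *= lamp[..., None]

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _stamp_calibration(image: np.ndarray,
                       region: tuple[int, int, int, int]) -> np.ndarray:
    r0, c0, r1, c1 = region
    image[r0:r1, c0:c1] = CALIBRATION_COLOR
    return image


class GenerationError(RuntimeError):
    """Raised when a sample cannot be generated under the given parameters."""


def apply_method_artifacts(sample: LeafSample, method: str | None = None) -> LeafSample:
    """Return a new sample with the observation artifacts of ``method``
    (default: the method recorded in the sample's parameters).

    ``true_area_mm2`` is never modified — artifacts bias only the
    *observed* image and mask, which is precisely how the measurement
    methods differ in practice.
    """
    if method is None:
        method = sample.metadata.method
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    params = dataclasses.replace(sample.metadata, method=method)
    out = dataclasses.replace(
        sample, image=sample.image.copy(), mask=sample.unoccluded_mask.copy(),
        metadata=params)
    if method == "splint":
        return out
    if method == "stretching":
        return _apply_clips(out)
    return _apply_manual(out)


def _apply_clips(sample: LeafSample) -> LeafSample:
    """Five margin clips at roughly equispaced outline points; clipped
    pixels leave the observed mask (the tissue is hidden, not gone)."""
    params = sample.metadata
    radius = float(params.clip_size_px)
    if radius <= 0:
        return sample
    rng = np.random.default_rng(params.seed + 1)
    h, w = sample.mask.shape
    verts = sample.outline_xy
    n = len(verts)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for k in range(5):
        idx = int((k / 5.0 + rng.uniform(-0.04, 0.04)) % 1.0 * n)
        cx, cy = verts[idx]
        clip = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        sample.image[clip] = _CLIP_COLOR
        sample.mask[clip] = 0
    return sample


def _apply_manual(sample: LeafSample) -> LeafSample:
    """Mild projective tilt (inflating the silhouette) plus low-frequency
    fold shading, emulating a hand-held frontal photograph."""
    params = sample.metadata
    rng = np.random.default_rng(params.seed + 2)
    h, w = sample.mask.shape
    # expand the top edge more than the bottom: camera tilted toward the leaf
    top, bottom = rng.uniform(0.045, 0.075), rng.uniform(0.01, 0.03)
    src = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=np.float64)
    dst = np.array([[-w * top, -h * top], [w * (1 + top), -h * top],
                    [w * (1 + bottom), h * (1 + bottom)],
                    [-w * bottom, h * (1 + bottom)]])
    # the board is fixed to the camera frame: blank the marker before the
    # leaf-plane warp, re-stamp it afterwards
    r0, c0, r1, c1 = sample.calibration_region
    sample.image[r0:r1, c0:c1] = _BACKGROUND.astype(np.uint8)
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(src, dst)
        if not tf:
            raise GenerationError("projective estimate failed")
    else:  # older scikit-image
        tf = ProjectiveTransform()
        if not tf.estimate(src, dst):
            raise GenerationError("projective estimate failed")
    inv = tf.inverse
    img = warp(sample.image.astype(np.float64), inv, order=1,
               mode="edge", preserve_range=True)
    msk = warp(sample.mask.astype(np.float64), inv, order=0,
               mode="constant", cval=0.0, preserve_range=True)
    fold = 1.0 + 0.12 * np.sin(
        np.linspace(0, rng.uniform(2.0, 4.0) * np.pi, w))[None, :, None] \
        * np.ones((h, 1, 1))
    img = np.clip(img * fold, 0, 255)
    sample.image = img.astype(np.uint8)
    sample.mask = (msk > 0.5).astype(np.uint8)
    # re-stamp the calibration marker: the board moves with the camera frame
    _stamp_calibration(sample.image, sample.calibration_region)
    return sample


def split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment of ``n`` samples to three splits."""
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    raw = [n * f for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    rem = n - sum(base)
    order = np.argsort([-(x - b) for x, b in zip(raw, base)], kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return tuple(base)


def generate_dataset(n: int, params_template: GeneratorParams, out_dir,
                     split: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0,
                     treatments: tuple[str, ...] | None = TREATMENTS) -> pd.DataFrame:
    """Write ``n`` samples (images, observed masks) and a manifest CSV.

    Samples cycle round-robin through ``treatments`` (pass ``None`` to pin
    every sample to the template's treatment), mirroring a balanced
    multi-treatment acquisition design.  Split assignment is a seeded
    permutation into train/val/test with largest-remainder sizes.
    """
    from . import io as sio

    if n < 5:
        raise GenerationError("n must be >= 5 to populate all three splits")
    sizes = split_sizes(n, split)
    if min(s for s, f in zip(sizes, split) if f > 0) == 0:
        raise GenerationError(f"n={n} too small to populate all splits {split}")

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[perm[:sizes[0]]] = "train"
    labels[perm[sizes[0]:sizes[0] + sizes[1]]] = "val"
    labels[perm[sizes[0] + sizes[1]:]] = "test"

    rows = []
    for i in range(n):
        p = dataclasses.replace(
            params_template,
            treatment=(treatments[i % len(treatments)] if treatments
                       else params_template.treatment),
            seed=int((seed * 1_000_003 + i) % 2_147_483_647),
        )
        sample = apply_method_artifacts(generate_leaf(p))
        img_rel = f"images/sample_{i:05d}.png"
        msk_rel = f"masks/sample_{i:05d}.png"
        sio.write_image(out_dir / img_rel, sample.image)
        sio.write_mask(out_dir / msk_rel, sample.mask)
        rows.append({
            "sample_id": i,
            "image": img_rel,
            "mask": msk_rel,
            "split": labels[i],
            "method": p.method,
            "treatment": p.treatment,
            "illumination": p.illumination,
            "true_area_mm2": sample.true_area_mm2,
            "calibration_pixel_count": sample.calibration_pixel_count,
            "calibration_area_mm2": sample.calibration_area_mm2,
            "seed": p.seed,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
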