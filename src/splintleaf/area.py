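"""From probability map to physical leaf area.

The measurement chain is: binarize the network's leaf-probability map,
fill interior holes (specular highlights, vein misclassifications), keep
the largest connected component (one leaf per frame), count its pixels
(PNL), count the calibration-square pixels (PNC), and convert with

    LA = PNL x S_c / PNC        [mm^2]

where S_c is the known physical area of the calibration square (default
25 mm^2 for a 5 mm x 5 mm marker).  Measurement accuracy against a
standard area S is the relative error |S - S_t| / S x 100%; the signed
variant keeps the sign of (S_t - S), negative meaning under-measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as _cc_label

from .synthetic import CALIBRATION_COLOR


@dataclass(frozen=True)
class AreaMeasurement:
    leaf_pixel_count: int
    calibration_pixel_count: int
    calibration_area_mm2: float
    leaf_area_mm2: float
    method: str = "splint"
    day_index: int | None = None
    empty_mask: bool = False


@dataclass(frozen=True)
class AccuracyRecord:
    standard_area_mm2: float
    measured_area_mm2: float
    signed_error_pct: float
    abs_error_pct: float


class CalibrationError(RuntimeError):
    """Raised when the calibration marker cannot be resolved."""


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Foreground where probability >= threshold (ties go to foreground)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return (np.asarray(prob) >= threshold).astype(np.uint8)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set background regions not 4-connected to the border to foreground."""
    m = np.asarray(mask) != 0
    return ndimage.binary_fill_holes(m).astype(np.uint8)


def largest_component(mask: np.ndarray) -> tuple[np.ndarray, bool]:
    """Keep only the largest 8-connected foreground component.

    Returns ``(mask, empty_flag)``; an empty mask passes through with the
    flag set.  Size ties are broken by the component whose first pixel in
    raster (row, col) order comes first.
    """
    m = np.asarray(mask) != 0
    if not m.any():
        return m.astype(np.uint8), True
    labels = _cc_label(m, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(np.argmax(sizes))   # argmax takes the lowest label on ties,
    # and skimage assigns labels in raster order of first occurrence
    return (labels == best).astype(np.uint8), False


def calibration_pixels(image: np.ndarray,
                       marker_color: tuple[int, int, int] = CALIBRATION_COLOR,
                       tolerance: int = 10,
                       region: tuple[int, int, int, int] | None = None) -> int:
    """Count calibration pixels by reserved-color match, or from an
    explicit half-open rectangle ``(r0, c0, r1, c1)`` when given.

    Real-world images should supply ``region``: the marker's appearance in
    the field is not standardized, and guessing would silently corrupt
    every downstream area.  Zero matching pixels raises
    :class:`CalibrationError` rather than returning a bogus scale.
    """
    if region is not None:
        r0, c0, r1, c1 = region
        if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
            raise CalibrationError(f"region {region} outside image bounds")
        return (r1 - r0) * (c1 - c0)
    diff = np.abs(image.astype(np.int32) - np.asarray(marker_color, dtype=np.int32))
    match = (diff <= tolerance).all(axis=-1)
    n = int(match.sum())
    if n == 0:
        raise CalibrationError(
            "no pixels match the calibration marker color; supply an explicit "
            "region=(r0, c0, r1, c1) for this image")
    return n


def compute_area(leaf_pixels: int, calib_pixels: int,
                 calib_area_mm2: float = 25.0) -> float:
    """LA = PNL x S_c / PNC, the pixel-count-to-area conversion."""
    if leaf_pixels <= 0 or calib_pixels <= 0 or calib_area_mm2 <= 0:
        raise ValueError(
            f"all inputs must be positive, got leaf={leaf_pixels}, "
            f"calib={calib_pixels}, area={calib_area_mm2}")
    return leaf_pixels * calib_area_mm2 / calib_pixels


def measurement_error(standard_mm2: float, measured_mm2: float) -> AccuracyRecord:
    """Relative measurement error (absolute and signed percentages)."""
    if standard_mm2 <= 0:
        raise ValueError(f"standard area must be positive, got {standard_mm2}")
    signed = (measured_mm2 - standard_mm2) / standard_mm2 * 100.0
    return AccuracyRecord(
        standard_area_mm2=float(standard_mm2),
        measured_area_mm2=float(measured_mm2),
        signed_error_pct=float(signed),
        abs_error_pct=float(abs(signed)),
    )


class OracleModel:
    """Model stub that returns a stored reference mask as its probability
    map — the upper bound of the pipeline given perfect segmentation."""

    def __init__(self, mask: np.ndarray):
        self.mask = np.asarray(mask)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        return self.mask.astype(np.float32)


def measure(image: np.ndarray, model, calibration=None, threshold: float = 0.5,
            calib_area_mm2: float = 25.0, method: str = "splint",
            day_index: int | None = None, log=None) -> AreaMeasurement:
    """Full pipeline: predict, binarize, fill holes, keep the largest
    component, count pixels, convert to mm^2.

    ``model`` is anything with ``predict_proba(image) -> H x W`` leaf
    probabilities; ``calibration`` is either an explicit region tuple or
    None for reserved-color detection.  Every intermediate pixel count is
    passed to ``log`` (a callable) when given.
    """
    prob = model.predict_proba(image)
    raw = binarize(prob, threshold)
    filled = fill_holes(raw)
    leaf, empty = largest_component(filled)
    calib = calibration_pixels(image, region=calibration)
    n_leaf = int(leaf.sum())
    if log is not None:
        log({"binarized_px": int(raw.sum()), "filled_px": int(filled.sum()),
             "leaf_px": n_leaf, "calibration_px": calib})
    if empty or n_leaf == 0:
        return AreaMeasurement(0, calib, calib_area_mm2, 0.0, method=method,
                               day_index=day_index, empty_mask=True)
    la = compute_area(n_leaf, calib, calib_area_mm2)
    return AreaMeasurement(n_leaf, calib, calib_area_mm2, la, method=method,
                           day_index=day_index)
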