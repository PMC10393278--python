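"""Labelme-dialect polygon annotations: parsing and rasterization.

A labelme JSON file carries a top-level ``shapes`` list, each shape with a
``label`` and a ``points`` list of [x, y] pixel coordinates.  Masks are
rasterized with the same pixel-center-in-polygon rule used everywhere in
this package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthetic import rasterize_polygon

LEAF_LABELS = {"leaf"}


class AnnotationFormatError(ValueError):
    pass


@dataclass(frozen=True)
class PolygonAnnotation:
    image_path: str
    polygons: tuple[np.ndarray, ...]   # each (n, 2) float array of (x, y)
    labels: tuple[str, ...]


def read_annotation(path) -> PolygonAnnotation:
    """Parse a labelme-style JSON annotation file."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise AnnotationFormatError(f"{path}: malformed JSON ({e})") from e
    if "shapes" not in doc:
        raise AnnotationFormatError(f"{path}: missing required 'shapes' key")
    shapes = doc["shapes"]
    if not isinstance(shapes, list):
        raise AnnotationFormatError(f"{path}: 'shapes' must be a list")
    if not shapes:
        warnings.warn(f"{path}: empty shapes list — annotation has no polygons")
    polys, labels = [], []
    for i, shape in enumerate(shapes):
        pts = shape.get("points")
        if pts is None:
            raise AnnotationFormatError(f"{path}: shape {i} missing 'points'")
        arr = np.asarray(pts, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
            raise AnnotationFormatError(
                f"{path}: shape {i} needs >= 3 [x, y] vertices, got {pts!r}")
        polys.append(arr)
        labels.append(str(shape.get("label", "")))
    return PolygonAnnotation(
        image_path=str(doc.get("imagePath", "")),
        polygons=tuple(polys),
        labels=tuple(labels),
    )


def annotation_to_mask(ann: PolygonAnnotation, height: int, width: int,
                       leaf_labels=LEAF_LABELS) -> np.ndarray:
    """Union of the leaf-labeled polygons as a binary mask."""
    mask = np.zeros((height, width), dtype=np.uint8)
    n_leaf = 0
    for poly, label in zip(ann.polygons, ann.labels):
        if label in leaf_labels:
            mask |= rasterize_polygon(poly, height, width)
            n_leaf += 1
    if n_leaf == 0:
        warnings.warn("no leaf-labeled polygons; mask is empty")
    return mask
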