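"""Vegetation-index pixel labeling: rapeseed leaf / weed / bare soil.

Training patches for the leaf classifier come from a three-class label
raster built in two steps, mirroring the annotation-then-index workflow of
field studies: pixels inside a hand-annotated (here: generated) leaf outline
are LEAF regardless of color — a shadowed leaf pixel stays a leaf; remaining
green pixels (excess-green minus excess-red index positive) are WEED; and
everything else is SOIL, which coincides with the normalized green–red
difference index (NGRDI) being non-positive for non-vegetation.

Index closed forms, on chromatic coordinates r+g+b=1:

    ExG = 2g - r - b        (excess green, Woebbecke)
    ExR = 1.4r - g          (excess red, Meyer)
    ExG - ExR = 3g - 2.4r - b
    NGRDI = (G - R) / (G + R)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon

__all__ = [
    "SOIL",
    "WEED",
    "LEAF",
    "CLASS_NAMES",
    "PixelClassMap",
    "exg_exr",
    "ngrdi",
    "label_pixels",
    "polygons_mask",
]

SOIL, WEED, LEAF = 0, 1, 2
CLASS_NAMES = {SOIL: "soil", WEED: "weed", LEAF: "leaf"}


@dataclass
class PixelClassMap:
    """Per-pixel class raster; values in {SOIL, WEED, LEAF}."""

    labels: np.ndarray  # H x W uint8
    provenance: dict = field(default_factory=dict)

    def class_fraction(self, cls: int) -> float:
        return float(np.mean(self.labels == cls))


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    return image.astype(np.float64)


def exg_exr(image: np.ndarray) -> np.ndarray:
    """Excess-green minus excess-red index on chromatic coordinates.

    Positive values indicate green vegetation. Black pixels (R+G+B = 0)
    map to 0.
    """
    img = _check_rgb(image)
    total = img.sum(axis=2)
    safe = np.where(total > 0, total, 1.0)
    r = img[:, :, 0] / safe
    g = img[:, :, 1] / safe
    b = img[:, :, 2] / safe
    exg = 2.0 * g - r - b
    exr = 1.4 * r - g
    out = exg - exr
    out[total == 0] = 0.0
    return out


def ngrdi(image: np.ndarray) -> np.ndarray:
    """Normalized green–red difference index (G−R)/(G+R); 0 where G+R = 0."""
    img = _check_rgb(image)
    gr = img[:, :, 1] + img[:, :, 0]
    safe = np.where(gr > 0, gr, 1.0)
    out = (img[:, :, 1] - img[:, :, 0]) / safe
    out[gr == 0] = 0.0
    return out


def polygons_mask(polygons, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of all pixels covered by any of the given polygons.

    Accepts LeafAnnotation objects or bare (n, 2) vertex arrays in
    (row, col) order.
    """
    mask = np.zeros(shape, dtype=bool)
    for poly in polygons:
        verts = getattr(poly, "vertices", poly)
        verts = np.asarray(verts, dtype=float)
        rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
        mask[rr, cc] = True
    return mask


def label_pixels(scene) -> PixelClassMap:
    """Three-class labeling of a plot scene.

    Leaf outlines take precedence; remaining pixels are WEED where
    ExG−ExR > 0 and SOIL otherwise (the tie at index 0 goes to soil — a
    gray pixel is not vegetation).
    """
    labels = np.full(scene.image.shape[:2], SOIL, dtype=np.uint8)
    green = exg_exr(scene.image) > 0.0
    labels[green] = WEED
    leaf = polygons_mask(scene.leaf_polygons, labels.shape)
    labels[leaf] = LEAF
    return PixelClassMap(
        labels=labels,
        provenance={
            "leaf": "ground-truth leaf outlines",
            "weed": "ExG-ExR > 0 outside leaf outlines",
            "soil": "remainder (NGRDI <= 0 for non-vegetation)",
        },
    )
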