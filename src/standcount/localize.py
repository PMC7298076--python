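"""Leaf localization: dilation-based local maxima of the heat map.

A grayscale dilation with a square structuring element (5x5 by default,
matching the convolution kernel) replaces each heat-map pixel by the
maximum of its neighborhood; pixels that keep their own value under
dilation — and lie at or above the detection threshold — are local maxima,
each taken to mark one detected leaf. Flat plateaus of equal-valued maxima
are merged into a single point at the (rounded) plateau centroid, since a
plateau is one leaf candidate, not several. Dilation uses reflected
padding so maxima at the image border remain detectable.

No distance-based merging of nearby points is applied beyond the dilation
neighborhood: leaf boundaries are too indistinct and leaf sizes too varied
for a fixed merge tolerance to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cnn import HeatMap

__all__ = ["DetectionSet", "local_maxima", "threshold_sweep", "default_threshold_grid"]


@dataclass
class DetectionSet:
    """Detected leaf points for one heat map at one threshold.

    ``points`` is an (n, 3) float array of (row, col, peak_value) in plot
    pixel coordinates (the heat-map offset has been applied).
    """

    points: np.ndarray
    threshold: float
    dilation_size: int = 5

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def count(self) -> int:
        return self.points.shape[0]


def local_maxima(
    heat: HeatMap | np.ndarray, threshold: float, filter_size: int = 5
) -> DetectionSet:
    """Locate leaf-candidate points in a heat map.

    A pixel is retained iff its value equals the grayscale dilation of the
    heat map at that location (it is the maximum of its ``filter_size``
    square neighborhood) and is >= ``threshold``. 8-connected plateaus of
    retained pixels are merged to their rounded centroid.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if filter_size < 1 or filter_size % 2 == 0:
        raise ValueError("filter_size must be a positive odd integer")

    if isinstance(heat, HeatMap):
        values = heat.values
        offset = heat.offset
    else:
        values = np.asarray(heat)
        offset = (0, 0)

    dilated = ndimage.grey_dilation(values, size=filter_size, mode="reflect")
    retained = (values >= threshold) & (values == dilated)
    labels, n = ndimage.label(retained, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        pts = np.empty((0, 3))
    else:
        centroids = ndimage.center_of_mass(retained, labels, np.arange(1, n + 1))
        peak = ndimage.maximum(values, labels, np.arange(1, n + 1))
        pts = np.array(
            [
                [round(r) + offset[0], round(c) + offset[1], v]
                for (r, c), v in zip(centroids, np.atleast_1d(peak))
            ],
            dtype=float,
        )
    return DetectionSet(points=pts, threshold=threshold, dilation_size=filter_size)


def default_threshold_grid() -> np.ndarray:
    """The standard detection-threshold grid: 0.50 to 1.00, step 0.01."""
    return np.round(0.5 + 0.01 * np.arange(51), 2)


def threshold_sweep(
    heat: HeatMap | np.ndarray,
    thresholds: np.ndarray | None = None,
    filter_size: int = 5,
) -> list[tuple[float, DetectionSet]]:
    """Run :func:`local_maxima` over a threshold grid.

    The retained-pixel mask depends only on the dilation, so detection
    counts are non-increasing in the threshold.
    """
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    return [
        (float(t), local_maxima(heat, float(t), filter_size)) for t in thresholds
    ]
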