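"""Fluorescent spot detection.

Objects appear as resolution-limited, low-contrast blurry spots.  The
detection recipe: subtract the most common intensity value (modal
background), band-pass with a difference-of-Gaussians (DoG) filter,
threshold the response, and drop connected components smaller than a
minimum area (3 px for fixed cells, 8 px for noisier live cells).
Centroids of the surviving components form the point set handed to the
matcher.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import PointSet

__all__ = [
    "DetectionParams",
    "DetectionResult",
    "subtract_background_mode",
    "dog_filter",
    "detect_spots",
]

# 8-connectivity: the 3/8-px size filters are defined on 8-connected components.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class DetectionParams:
    """Spot-detection parameters.

    dog_sigma_small, dog_sigma_large : float
        DoG band-pass sigmas in pixels; must satisfy small < large.
        Defaults 1.0 / 2.0 px suit diffraction-limited spots.
    threshold : float or "otsu"
        Threshold on the DoG response; ``"otsu"`` (default) picks it
        automatically, a number overrides manually.
    min_size : int
        Minimum component area in pixels (3 fixed-cell mode, 8 live mode).
    """

    dog_sigma_small: float = 1.0
    dog_sigma_large: float = 2.0
    threshold: Union[float, str] = "otsu"
    min_size: int = 3

    def __post_init__(self) -> None:
        if self.dog_sigma_small >= self.dog_sigma_large:
            raise ValueError("dog_sigma_small must be < dog_sigma_large")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass
class DetectionResult:
    mask: np.ndarray  # binary image
    labels: np.ndarray  # labeled-component image (0 = background)
    centroids: PointSet
    object_areas: List[int] = field(default_factory=list)

    @property
    def n_objects(self) -> int:
        return len(self.centroids)


def subtract_background_mode(image: np.ndarray) -> np.ndarray:
    """Subtract the most common intensity value, clipping at zero.

    The mode is taken over the integer intensity histogram (non-integer
    images are rounded for the histogram only), which is the right
    estimator for the flat camera background that dominates pixel counts.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    vals, counts = np.unique(np.round(img).astype(np.int64), return_counts=True)
    mode = vals[np.argmax(counts)]
    return np.clip(img - mode, 0.0, None)


def dog_filter(
    image: np.ndarray, dog_sigma_small: float, dog_sigma_large: float
) -> np.ndarray:
    """Difference-of-Gaussians band-pass response."""
    if dog_sigma_small >= dog_sigma_large:
        raise ValueError("dog_sigma_small must be < dog_sigma_large")
    img = np.asarray(image, dtype=float)
    return ndimage.gaussian_filter(img, dog_sigma_small) - ndimage.gaussian_filter(
        img, dog_sigma_large
    )


def detect_spots(
    image: np.ndarray,
    params: Optional[DetectionParams] = None,
    channel_id: int = 0,
    frame_index: Optional[int] = None,
) -> DetectionResult:
    """Detect spots in a single-channel image.

    Pipeline: modal background subtraction → DoG → threshold → 8-connected
    components → size filter → unweighted area centroids, ordered by label.
    An image with nothing above threshold yields an empty result, not an
    error.
    """
    params = params or DetectionParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a 2D grayscale image")

    bg_sub = subtract_background_mode(img)
    response = dog_filter(bg_sub, params.dog_sigma_small, params.dog_sigma_large)

    if params.threshold == "otsu":
        if np.ptp(response) == 0:  # flat response: nothing to detect
            thr = np.inf
        else:
            thr = threshold_otsu(response)
    else:
        thr = float(params.threshold)

    mask = response > thr
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)

    if n == 0:
        return DetectionResult(
            mask=mask,
            labels=labels,
            centroids=PointSet(np.empty((0, 2)), channel_id, frame_index),
            object_areas=[],
        )

    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1)).astype(int)
    keep = areas >= params.min_size
    # relabel so labels are consecutive over surviving components
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1:][keep] = np.arange(1, keep.sum() + 1)
    labels = remap[labels]
    mask = labels > 0

    if keep.sum() == 0:
        centroids = np.empty((0, 2))
    else:
        # center_of_mass returns (row, col); convert to (x=col, y=row)
        com = ndimage.center_of_mass(mask, labels, index=np.arange(1, keep.sum() + 1))
        com = np.atleast_2d(np.asarray(com, dtype=float))
        centroids = com[:, ::-1]

    return DetectionResult(
        mask=mask,
        labels=labels,
        centroids=PointSet(centroids, channel_id, frame_index),
        object_areas=[int(a) for a in areas[keep]],
    )
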