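"""Pixelwise colocalization baselines.

The traditional estimators the object-based association measure is
compared against: Pearson correlation of channel intensities, the Manders
coefficient (fraction of one channel's intensity lying over above-
threshold pixels of the other), direct mask-overlap fractions, and an
objectwise overlap count.  All support an analysis mask to exclude
background, mirroring typical workflows where a DoG-derived mask selects
the signal region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "ColocResult",
    "pearson",
    "manders",
    "overlap_fraction",
    "object_overlap",
    "coloc_summary",
]


@dataclass
class ColocResult:
    pearson_r: float
    manders_m1: float
    manders_m2: float
    overlap_frac_ch1: float
    overlap_frac_ch2: float
    n_mask_pixels: int


def _masked(arr: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if mask is None:
        return arr.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError("mask shape must match image shape")
    return arr[mask]


def pearson(
    ch1: np.ndarray, ch2: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Sample Pearson correlation of the two channels' intensities.

    Positive values indicate matching intensity patterns (evidence of
    colocalization); values near zero give no evidence; negative values an
    inverse relation.  Raises if either channel is constant over the
    analysis region, where the correlation is undefined.
    """
    a = _masked(ch1, mask)
    b = _masked(np.asarray(ch2), mask)
    if a.shape != b.shape:
        raise ValueError("channel shapes must match")
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined for a constant channel")
    return float(np.corrcoef(a, b)[0, 1])


def manders(
    ch_i: np.ndarray,
    ch_ref: np.ndarray,
    threshold: Union[float, str] = "otsu",
    mask: Optional[np.ndarray] = None,
) -> float:
    """Manders coefficient M_i: the colocalized proportion of channel i.

    M_i = Σ ch_i over pixels where ch_ref > T, divided by Σ ch_i, with all
    sums restricted to the analysis mask.  ``threshold="otsu"`` picks T
    automatically on the reference channel (threshold selection is not
    trivial and often needs manual adjustment, hence the override).
    """
    ci = np.asarray(ch_i, dtype=float)
    cr = np.asarray(ch_ref, dtype=float)
    if ci.shape != cr.shape:
        raise ValueError("channel shapes must match")
    if threshold == "otsu":
        ref_vals = _masked(cr, mask)
        if np.ptp(ref_vals) == 0:
            raise ValueError("cannot auto-threshold a constant reference channel")
        t = float(threshold_otsu(ref_vals))
    else:
        t = float(threshold)
        if t < 0:
            raise ValueError("threshold must be >= 0")
    ci_m = _masked(ci, mask)
    cr_m = _masked(cr, mask)
    total = ci_m.sum()
    if total <= 0:
        raise ValueError("Manders coefficient undefined: channel has zero total signal")
    return float(ci_m[cr_m > t].sum() / total)


def overlap_fraction(
    mask1: np.ndarray, mask2: np.ndarray
) -> Tuple[float, float]:
    """Direct pixel-overlap percentage of two binary masks.

    Returns (|m1∧m2|/|m1|, |m1∧m2|/|m2|); an empty mask yields 0.
    """
    m1 = np.asarray(mask1, dtype=bool)
    m2 = np.asarray(mask2, dtype=bool)
    if m1.shape != m2.shape:
        raise ValueError("mask shapes must match")
    inter = int(np.logical_and(m1, m2).sum())
    n1, n2 = int(m1.sum()), int(m2.sum())
    return (inter / n1 if n1 else 0.0, inter / n2 if n2 else 0.0)


def object_overlap(labels1: np.ndarray, labels2: np.ndarray) -> Tuple[float, float]:
    """Objectwise overlap: fraction of each channel's objects touching
    (≥ 1 shared pixel with) any object of the other channel."""
    l1 = np.asarray(labels1)
    l2 = np.asarray(labels2)
    if l1.shape != l2.shape:
        raise ValueError("label image shapes must match")

    def frac(a: np.ndarray, other_mask: np.ndarray) -> float:
        ids = np.unique(a)
        ids = ids[ids > 0]
        if ids.size == 0:
            return 0.0
        touching = np.unique(a[other_mask & (a > 0)])
        return float(len(touching) / len(ids))

    return frac(l1, l2 > 0), frac(l2, l1 > 0)


def coloc_summary(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask1: Optional[np.ndarray] = None,
    mask2: Optional[np.ndarray] = None,
    manders_threshold: Union[float, str] = "otsu",
) -> ColocResult:
    """All pixelwise estimates in one pass.

    Pearson and Manders use the union of the two object masks as the
    analysis region when masks are given (masked statistics are the
    default workflow); overlap fractions use the masks directly.
    """
    if mask1 is not None and mask2 is not None:
        analysis = np.asarray(mask1, dtype=bool) | np.asarray(mask2, dtype=bool)
        ov1, ov2 = overlap_fraction(mask1, mask2)
        n_mask = int(analysis.sum())
    else:
        analysis = None
        ov1 = ov2 = float("nan")
        n_mask = int(np.asarray(ch1).size)
    return ColocResult(
        pearson_r=pearson(ch1, ch2, analysis),
        manders_m1=manders(ch1, ch2, manders_threshold, analysis),
        manders_m2=manders(ch2, ch1, manders_threshold, analysis),
        overlap_frac_ch1=ov1,
        overlap_frac_ch2=ov2,
        n_mask_pixels=n_mask,
    )
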