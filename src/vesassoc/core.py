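"""Shared domain types and coordinate conventions.

Coordinate convention used throughout the package: a point is ``(x, y)``
with ``x`` = column and ``y`` = row, 0-based, referring to pixel centers.
Sub-pixel (continuous) centroids are allowed everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PointSet",
    "Translation",
    "PPMParams",
    "Matching",
    "AssociationResult",
    "distance",
    "validate_matching",
    "read_points_csv",
    "write_points_csv",
]

#: Recognized point-distance norms.  All experiments here use Euclidean
#: distance (search areas are circular), but the norm is selectable.
NORMS = ("euclidean", "manhattan", "chebyshev")


def distance(a: Sequence[float], b: Sequence[float], norm: str = "euclidean") -> float:
    """Distance between two 2D points under the configured norm (pixels).

    Parameters
    ----------
    a, b : sequence of float
        ``(x, y)`` coordinates.
    norm : str
        One of ``"euclidean"`` (default), ``"manhattan"``, ``"chebyshev"``.

    Raises
    ------
    ValueError
        If the norm tag is unknown or a coordinate is non-finite.
    """
    dx = float(a[0]) - float(b[0])
    dy = float(a[1]) - float(b[1])
    if not (math.isfinite(dx) and math.isfinite(dy)):
        raise ValueError("point coordinates must be finite")
    if norm == "euclidean":
        return math.hypot(dx, dy)
    if norm == "manhattan":
        return abs(dx) + abs(dy)
    if norm == "chebyshev":
        return max(abs(dx), abs(dy))
    raise ValueError(f"unknown norm {norm!r}; expected one of {NORMS}")


def _vector_norm(v: np.ndarray, norm: str = "euclidean") -> float:
    if norm == "euclidean":
        return float(np.linalg.norm(v))
    if norm == "manhattan":
        return float(np.abs(v).sum())
    if norm == "chebyshev":
        return float(np.abs(v).max()) if v.size else 0.0
    raise ValueError(f"unknown norm {norm!r}; expected one of {NORMS}")


@dataclass(frozen=True)
class Translation:
    """A 2D translation ``(dx, dy)`` in pixels — the transformation class
    searched by the matcher (rotations/scalings are out of scope: the two
    channels image the same field of view, so only moderate shifts occur)."""

    dx: float = 0.0
    dy: float = 0.0

    @property
    def magnitude(self) -> float:
        return math.hypot(self.dx, self.dy)

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy], dtype=float)

    def __neg__(self) -> "Translation":
        return Translation(-self.dx, -self.dy)


@dataclass
class PointSet:
    """Ordered collection of 2D object centroids for one channel.

    Index ``i`` always refers to the same object within one analysis run;
    the matcher reports correspondences as index pairs into two PointSets.
    """

    points: np.ndarray  # (n, 2) float array of (x, y)
    channel_id: int = 0
    frame_index: Optional[int] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.points[i]

    def translate(self, t: Translation) -> "PointSet":
        return PointSet(self.points + t.as_array(), self.channel_id, self.frame_index)

    @property
    def centroid(self) -> np.ndarray:
        if len(self) == 0:
            raise ValueError("centroid of an empty point set is undefined")
        return self.points.mean(axis=0)


@dataclass
class PPMParams:
    """Tuning parameters of the point-pattern matcher.

    matching_distance : float
        δ, pixels — maximum distance between a translated model point and
        its matched scene point.  Default 4 px.
    matching_ratio : float
        α in [0, 1] — minimum matched fraction of the smaller point set for
        a matching to count as found.
    max_bias : float
        β_max ≥ 0 — maximum allowed bias (normalized mean-residual
        magnitude); rejects matchings whose errors all point one way.
    max_neighbors : int
        k ≥ 1 — nearest neighbors considered per translated point.
    max_translation : float
        Largest translation magnitude accepted as a genuine alignment; a
        drastic shift indicates a correspondence found by chance.
    norm : str
        Point-distance norm tag (default Euclidean).
    """

    matching_distance: float = 4.0
    matching_ratio: float = 0.1
    max_bias: float = 0.2
    max_neighbors: int = 10
    max_translation: float = 3.0
    norm: str = "euclidean"

    def __post_init__(self) -> None:
        if self.matching_distance <= 0:
            raise ValueError("matching_distance must be > 0")
        if not 0.0 <= self.matching_ratio <= 1.0:
            raise ValueError("matching_ratio must be in [0, 1]")
        if self.max_bias < 0:
            raise ValueError("max_bias must be >= 0")
        if self.max_neighbors < 1:
            raise ValueError("max_neighbors must be >= 1")
        if self.max_translation < 0:
            raise ValueError("max_translation must be >= 0")
        if self.norm not in NORMS:
            raise ValueError(f"unknown norm {self.norm!r}; expected one of {NORMS}")


@dataclass
class Matching:
    """A one-to-one correspondence between two point sets.

    ``pairs`` holds ``(index_in_P, index_in_Q)`` tuples; ``translation``
    is the shift that produced it, ``bias`` its normalized mean residual,
    and ``accepted`` records whether the ratio, bias and translation
    constraints were all satisfied.
    """

    pairs: Tuple[Tuple[int, int], ...] = ()
    translation: Translation = field(default_factory=Translation)
    bias: float = float("nan")
    accepted: bool = False

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AssociationResult:
    """Per-channel association estimate: the matched fraction of each
    channel's objects (0 when no acceptable matching exists)."""

    assoc_ch1: float
    assoc_ch2: float
    matching: Matching
    n_objects_ch1: int
    n_objects_ch2: int


def validate_matching(
    m: Matching, p: PointSet, q: PointSet, delta: float, norm: str = "euclidean"
) -> None:
    """Check the structural invariants of a matching; raise on violation.

    A valid matching is one-to-one and every pair satisfies the matching
    distance constraint under the matching's translation.
    """
    left = [i for i, _ in m.pairs]
    right = [j for _, j in m.pairs]
    if len(set(left)) != len(left) or len(set(right)) != len(right):
        raise ValueError("matching is not one-to-one")
    t = m.translation.as_array()
    for i, j in m.pairs:
        d = distance(p.points[i] + t, q.points[j], norm)
        if d > delta + 1e-9:
            raise ValueError(
                f"pair ({i}, {j}) violates the matching distance: {d:.4f} > {delta}"
            )


# --- CSV interchange -------------------------------------------------------
# One row per object, header `x,y` with optional `frame,channel` columns.


def read_points_csv(
    path, channel: Optional[int] = None, frame: Optional[int] = None
) -> PointSet:
    """Read a point set from CSV (columns ``x,y``; optional ``frame,channel``)."""
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'x' and 'y'")
    if channel is not None and "channel" in df.columns:
        df = df[df["channel"] == channel]
    if frame is not None and "frame" in df.columns:
        df = df[df["frame"] == frame]
    return PointSet(
        df[["x", "y"]].to_numpy(dtype=float),
        channel_id=0 if channel is None else channel,
        frame_index=frame,
    )


def write_points_csv(path, ps: PointSet, extra: Optional[dict] = None) -> None:
    """Write a point set as CSV; ``extra`` adds constant-valued columns."""
    df = pd.DataFrame(ps.points, columns=["x", "y"])
    if ps.frame_index is not None:
        df["frame"] = ps.frame_index
    df["channel"] = ps.channel_id
    for k, v in (extra or {}).items():
        df[k] = v
    df.to_csv(path, index=False)
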