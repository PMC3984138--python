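"""Biunique iterated-closest-points (ICP) registration baseline.

Translation-only ICP initialized so the point-set centroids coincide,
with one-to-one correspondences enforced by mutual-nearest-neighbor
filtering.  This is the registration-style comparison point for the PPM
matcher: it refines an initial guess and therefore fails when extraneous
objects drag the centroid initialization far from the true shift — the
failure mode that motivates the global PPM search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import Matching, PointSet, Translation
from .matching import bias as matching_bias

__all__ = ["ICPParams", "icp_register"]


@dataclass
class ICPParams:
    """max_iterations / convergence_tol control the iteration; match_radius
    (δ, pixels) gates which converged pairs count as final matches;
    biunique enforces one-to-one correspondences via mutual nearest
    neighbors."""

    max_iterations: int = 50
    convergence_tol: float = 1e-3
    match_radius: float = 4.0
    biunique: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


def _pair_points(
    p_shifted: np.ndarray, q: np.ndarray, biunique: bool
) -> List[Tuple[int, int]]:
    """Nearest-neighbor correspondences, optionally mutual-nearest only."""
    tree_q = cKDTree(q)
    _, nn_q = tree_q.query(p_shifted)  # for each p: nearest q
    if not biunique:
        return [(i, int(j)) for i, j in enumerate(nn_q)]
    tree_p = cKDTree(p_shifted)
    _, nn_p = tree_p.query(q)  # for each q: nearest p
    return [(i, int(j)) for i, j in enumerate(nn_q) if nn_p[j] == i]


def icp_register(p: PointSet, q: PointSet, params: ICPParams | None = None) -> Matching:
    """Register P onto Q by translation-only biunique ICP.

    Starts from t₀ = centroid(Q) − centroid(P); each iteration pairs every
    translated P-point with its nearest Q-point, keeps mutually-nearest
    pairs when biunique, and moves t by the mean residual.  Stops when the
    translation update is below convergence_tol or max_iterations is
    reached.  The final matching keeps only pairs within match_radius.
    """
    params = params or ICPParams()
    if len(p) == 0 or len(q) == 0:
        raise ValueError("icp_register requires non-empty point sets")

    t = q.centroid - p.centroid
    pairs: List[Tuple[int, int]] = []
    for _ in range(params.max_iterations):
        p_shifted = p.points + t
        pairs = _pair_points(p_shifted, q.points, params.biunique)
        if not pairs:
            break
        residuals = np.array([q.points[j] - p_shifted[i] for i, j in pairs])
        update = residuals.mean(axis=0)
        t = t + update
        if float(np.linalg.norm(update)) < params.convergence_tol:
            break

    translation = Translation(float(t[0]), float(t[1]))
    p_shifted = p.points + t
    final = tuple(
        sorted(
            (i, j)
            for i, j in pairs
            if float(np.linalg.norm(q.points[j] - p_shifted[i])) <= params.match_radius
        )
    )
    if final:
        b = matching_bias(final, p, q, translation, params.match_radius)
    else:
        b = float("nan")
    return Matching(pairs=final, translation=translation, bias=b, accepted=bool(final))
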