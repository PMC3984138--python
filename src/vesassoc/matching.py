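"""Point-pattern matching (PPM) under translations — the association
estimator at the heart of this package.

Given two point sets P (model) and Q (scene) detected from the two
fluorescence channels, the matcher searches the set of translations for one
that puts subsets of P and Q into one-to-one correspondence, where a
translated model point may pair with any scene point within the matching
distance δ.  Unlike registration (e.g. ICP), nothing is assumed about the
initial alignment: every difference vector Q[j] − P[i] with magnitude below
the translation limit is tried as a candidate shift.  A candidate's
matching is the maximum bipartite matching of the "within δ among the k
nearest" graph, and is accepted only if

* it pairs at least an α-fraction of the smaller set (matching ratio),
* its bias — the normalized magnitude of the mean residual vector — stays
  below β_max (residuals that all point one way indicate that a shifted
  copy of the pattern was matched off-by-one), and
* the translation magnitude stays moderate (a drastic shift indicates a
  correspondence found by chance, not association).

The association estimate is then simply the matched fraction of each
channel's objects, directly comparable to object-overlap percentages but
robust to channel misalignment and object movement between acquisitions.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core import (
    AssociationResult,
    Matching,
    PointSet,
    PPMParams,
    Translation,
    _vector_norm,
)

__all__ = [
    "NeighborIndex",
    "build_neighbor_index",
    "bias",
    "max_bipartite_matching",
    "try_translation",
    "ppm_match",
    "association",
]


class NeighborIndex:
    """k-nearest-neighbor index over a point set.

    Backed by a kd-tree with the sliding-midpoint splitting rule
    (``scipy.spatial.cKDTree``).  Queries return neighbors sorted by
    distance; exact ties are broken by point label (index) order so results
    are deterministic.  For non-Euclidean norms the tree queries with the
    matching Minkowski p.
    """

    _P_FOR_NORM = {"euclidean": 2.0, "manhattan": 1.0, "chebyshev": np.inf}

    def __init__(self, q: PointSet, norm: str = "euclidean"):
        self.q = q
        self.norm = norm
        self._p = self._P_FOR_NORM[norm]
        self._tree = cKDTree(q.points) if len(q) else None

    def query(self, x: Sequence[float], k: int) -> Tuple[np.ndarray, np.ndarray]:
        """Return (distances, indices) of up to k nearest points to x."""
        if self._tree is None:
            return np.empty(0), np.empty(0, dtype=int)
        k_eff = min(k, len(self.q))
        d, idx = self._tree.query(np.asarray(x, dtype=float), k=k_eff, p=self._p)
        d = np.atleast_1d(d)
        idx = np.atleast_1d(idx)
        # stable secondary order for equidistant points: label order
        order = np.lexsort((idx, np.round(d, 12)))
        return d[order], idx[order]

    def query_ball(self, x: Sequence[float], r: float) -> List[int]:
        if self._tree is None:
            return []
        return sorted(self._tree.query_ball_point(np.asarray(x, dtype=float), r, p=self._p))


def build_neighbor_index(q: PointSet, norm: str = "euclidean") -> NeighborIndex:
    """Build a spatial index over Q for k-nearest-neighbor queries."""
    return NeighborIndex(q, norm)


def bias(
    pairs: Iterable[Tuple[int, int]],
    p: PointSet,
    q: PointSet,
    t: Translation,
    delta: float,
    norm: str = "euclidean",
) -> float:
    """Bias of a matching: ‖mean residual vector‖ / δ.

    The residual of pair (i, j) is Q[j] − (P[i] + t).  Residuals spread
    uniformly in all directions average near zero (bias ≈ 0); residuals
    that all point one way — the signature of matching a shifted copy to
    the wrong neighbors — average near δ (bias ≈ 1).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("bias of an empty matching is undefined")
    tv = t.as_array()
    residuals = np.array([q.points[j] - (p.points[i] + tv) for i, j in pairs])
    return _vector_norm(residuals.mean(axis=0), norm) / delta


def max_bipartite_matching(
    edges: Iterable[Tuple[int, int]],
    n_left: Optional[int] = None,
) -> List[Tuple[int, int]]:
    """Maximum-cardinality matching of a bipartite graph via Hopcroft-Karp.

    ``edges`` are (left, right) index pairs.  Returns the matched pairs
    sorted by left index; an empty edge set yields an empty matching.
    """
    edges = list(edges)
    if not edges:
        return []
    g = nx.Graph()
    left_nodes = sorted({i for i, _ in edges})
    g.add_nodes_from((("L", i) for i in left_nodes), bipartite=0)
    g.add_nodes_from((("R", j) for _, j in edges), bipartite=1)
    g.add_edges_from((("L", i), ("R", j)) for i, j in edges)
    top = [("L", i) for i in left_nodes]
    mate = nx.bipartite.hopcroft_karp_matching(g, top_nodes=top)
    out = [(i, mate[("L", i)][1]) for i in left_nodes if ("L", i) in mate]
    return sorted(out)


def _candidate_edges(
    p_translated: np.ndarray, index: NeighborIndex, params: PPMParams
) -> List[Tuple[int, int]]:
    """Edges (i, j): Q[j] within δ of translated P[i], among its k nearest."""
    edges: List[Tuple[int, int]] = []
    for i, x in enumerate(p_translated):
        d, idx = index.query(x, params.max_neighbors)
        for dist_ij, j in zip(d, idx):
            if dist_ij <= params.matching_distance:
                edges.append((i, int(j)))
    return edges


def try_translation(
    p: PointSet,
    q: PointSet,
    t: Translation,
    params: PPMParams,
    index: Optional[NeighborIndex] = None,
) -> Matching:
    """Evaluate a single candidate translation.

    Translates P by t, builds the bipartite "within δ among k nearest"
    graph against Q, takes its maximum matching, and applies the three
    acceptance checks (ratio, bias, translation magnitude).
    """
    if len(p) == 0 or len(q) == 0:
        return Matching(pairs=(), translation=t, bias=float("nan"), accepted=False)
    if index is None:
        index = build_neighbor_index(q, params.norm)

    p_translated = p.points + t.as_array()
    edges = _candidate_edges(p_translated, index, params)
    pairs = tuple(max_bipartite_matching(edges))

    if not pairs:
        return Matching(pairs=(), translation=t, bias=float("nan"), accepted=False)

    b = bias(pairs, p, q, t, params.matching_distance, params.norm)
    required = params.matching_ratio * min(len(p), len(q))
    accepted = (
        len(pairs) >= required
        and b <= params.max_bias
        and t.magnitude <= params.max_translation
    )
    return Matching(pairs=pairs, translation=t, bias=b, accepted=accepted)


def _candidate_translations(
    p: PointSet, q: PointSet, max_translation: float, norm: str
) -> List[Tuple[int, int, Translation]]:
    """Candidate shifts t = Q[j] − P[i] with ‖t‖ ≤ max_translation.

    Only pairs already close to each other can generate an acceptable
    translation, so the enumeration is pruned with a radius query; the
    result is ordered by (i, j) for deterministic tie-breaking.
    """
    if len(p) == 0 or len(q) == 0:
        return []
    index = NeighborIndex(q, norm)
    out: List[Tuple[int, int, Translation]] = []
    for i, x in enumerate(p.points):
        for j in index.query_ball(x, max_translation):
            diff = q.points[j] - x
            out.append((i, j, Translation(float(diff[0]), float(diff[1]))))
    return out


def ppm_match(p: PointSet, q: PointSet, params: Optional[PPMParams] = None) -> Matching:
    """Run the full PPM search and return the best accepted matching.

    Every pairwise difference vector within the translation limit is tried
    as a candidate shift; among accepted candidates the winner has the
    largest matching, then the smallest bias, then the smallest shift
    magnitude, then the lexicographically smallest generating pair.  If no
    candidate is accepted the result is an empty, non-accepted matching
    ("no match at the required ratio").
    """
    params = params or PPMParams()
    empty = Matching(pairs=(), translation=Translation(), bias=float("nan"), accepted=False)
    if len(p) == 0 or len(q) == 0:
        return empty

    index = build_neighbor_index(q, params.norm)
    best: Optional[Matching] = None
    best_key: Optional[tuple] = None
    for i, j, t in _candidate_translations(p, q, params.max_translation, params.norm):
        m = try_translation(p, q, t, params, index=index)
        if not m.accepted:
            continue
        key = (-len(m.pairs), m.bias, t.magnitude, i, j)
        if best_key is None or key < best_key:
            best, best_key = m, key
    return best if best is not None else empty


def association(
    p: PointSet, q: PointSet, params: Optional[PPMParams] = None
) -> AssociationResult:
    """Estimate per-channel association as the matched object fraction.

    If an acceptable matching exists, assoc_chX = |M| / n_objects_chX for
    each channel; otherwise both associations are 0.  Values near 1 mean
    nearly every object has a counterpart within δ after compensating a
    moderate shift; values near 0 mean little association.
    """
    m = ppm_match(p, q, params)
    n1, n2 = len(p), len(q)
    if m.accepted and n1 > 0 and n2 > 0:
        a1 = len(m.pairs) / n1
        a2 = len(m.pairs) / n2
    else:
        a1 = a2 = 0.0
    return AssociationResult(
        assoc_ch1=a1, assoc_ch2=a2, matching=m, n_objects_ch1=n1, n_objects_ch2=n2
    )
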