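"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: maximum
matchings are found by exhaustive recursion, nearest neighbors by a full
distance scan, and the translation search by enumerating every candidate
shift — so they can certify the kd-tree / Hopcroft-Karp / PPM pipeline on
small instances.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pytest

from vesassoc import PointSet


@pytest.fixture
def rng():
    return np.random.default_rng(20140411)


def brute_force_knn(
    points: np.ndarray, query: np.ndarray, k: int
) -> List[int]:
    """k nearest by full scan; ties broken by index order."""
    d = np.linalg.norm(points - query, axis=1)
    order = sorted(range(len(points)), key=lambda i: (round(float(d[i]), 12), i))
    return order[:k]


def brute_force_max_matching(edges: Iterable[Tuple[int, int]]) -> int:
    """Maximum bipartite matching cardinality by exhaustive recursion."""
    edges = list(edges)
    adj: Dict[int, List[int]] = {}
    for i, j in edges:
        adj.setdefault(i, []).append(j)
    lefts = sorted(adj)

    def rec(pos: int, used: frozenset) -> int:
        if pos == len(lefts):
            return 0
        best = rec(pos + 1, used)  # leave this left vertex unmatched
        for j in adj[lefts[pos]]:
            if j not in used:
                best = max(best, 1 + rec(pos + 1, used | {j}))
        return best

    return rec(0, frozenset())


def brute_force_ppm_cardinality(
    p: np.ndarray, q: np.ndarray, delta: float, max_translation: float = np.inf
) -> int:
    """Best matching size over every candidate translation Q[j] − P[i]."""
    best = 0
    for i in range(len(p)):
        for j in range(len(q)):
            t = q[j] - p[i]
            if np.linalg.norm(t) > max_translation:
                continue
            shifted = p + t
            edges = [
                (a, b)
                for a in range(len(p))
                for b in range(len(q))
                if np.linalg.norm(shifted[a] - q[b]) <= delta
            ]
            best = max(best, brute_force_max_matching(edges))
    return best


def planted_sets(
    rng: np.random.Generator,
    n_shared: int,
    n_unique1: int = 0,
    n_unique2: int = 0,
    shift: Sequence[float] = (0.0, 0.0),
    jitter: float = 0.0,
    extent: float = 100.0,
    min_sep: float = 5.0,
) -> Tuple[PointSet, PointSet]:
    """Two point sets with a planted correspondence on the first n_shared
    indices of each; all base locations respect a minimum separation."""
    pts: List[np.ndarray] = []
    while len(pts) < n_shared + n_unique1 + n_unique2:
        c = rng.uniform(10, extent, size=2)
        if pts and np.min(np.linalg.norm(np.asarray(pts) - c, axis=1)) < min_sep:
            continue
        pts.append(c)
    pts = np.asarray(pts)
    shared, u1, u2 = (
        pts[:n_shared],
        pts[n_shared : n_shared + n_unique1],
        pts[n_shared + n_unique1 :],
    )
    ch2_shared = shared + np.asarray(shift, dtype=float)
    if jitter > 0:
        ch2_shared = ch2_shared + rng.normal(0, jitter, size=ch2_shared.shape)
    p = PointSet(np.vstack([shared, u1]), channel_id=1)
    q = PointSet(np.vstack([ch2_shared, u2]), channel_id=2)
    return p, q
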