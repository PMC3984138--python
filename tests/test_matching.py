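"""The PPM matcher: neighbor index, bias, Hopcroft-Karp, translation
search, association — each certified against a brute-force oracle."""

import numpy as np
import pytest

from conftest import (
    brute_force_knn,
    brute_force_max_matching,
    brute_force_ppm_cardinality,
    planted_sets,
)
from vesassoc import (
    PointSet,
    PPMParams,
    Translation,
    association,
    bias,
    build_neighbor_index,
    max_bipartite_matching,
    ppm_match,
    try_translation,
    validate_matching,
)
from vesassoc.matching import try_translation as _try


# --- nearest neighbor index ------------------------------------------------

def test_knn_returns_nearer_point():
    idx = build_neighbor_index(PointSet(np.array([[0.0, 0.0], [10.0, 0.0]])))
    _, nn = idx.query([1.0, 0.0], k=1)
    assert list(nn) == [0]


def test_knn_tie_broken_by_label_order():
    # query equidistant to both points: lower index wins, deterministically
    idx = build_neighbor_index(PointSet(np.array([[2.0, 0.0], [-2.0, 0.0]])))
    _, nn = idx.query([0.0, 0.0], k=2)
    assert list(nn) == [0, 1]


def test_knn_matches_brute_force_scan(rng):
    pts = rng.uniform(0, 50, size=(200, 2))
    idx = build_neighbor_index(PointSet(pts))
    for _ in range(50):
        query = rng.uniform(0, 50, size=2)
        _, nn = idx.query(query, k=5)
        assert list(nn) == brute_force_knn(pts, query, 5)


def test_knn_empty_set():
    idx = build_neighbor_index(PointSet(np.empty((0, 2))))
    d, nn = idx.query([0.0, 0.0], k=3)
    assert len(d) == 0 and len(nn) == 0


# --- bias ------------------------------------------------------------------

def test_bias_zero_for_perfect_alignment():
    p = PointSet(np.array([[0.0, 0.0], [5.0, 5.0]]))
    q = PointSet(p.points.copy())
    assert bias([(0, 0), (1, 1)], p, q, Translation(), delta=2.0) == 0.0


def test_bias_zero_for_symmetric_residuals():
    # residuals (+d, 0) and (-d, 0) cancel: error distributed uniformly
    d = 2.0
    p = PointSet(np.array([[0.0, 0.0], [10.0, 0.0]]))
    q = PointSet(np.array([[d, 0.0], [10.0 - d, 0.0]]))
    assert bias([(0, 0), (1, 1)], p, q, Translation(), delta=d) == pytest.approx(0.0)


def test_bias_one_for_uniformly_directed_residuals():
    d = 2.0
    p = PointSet(np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]))
    q = PointSet(p.points + [d, 0.0])
    pairs = [(i, i) for i in range(3)]
    assert bias(pairs, p, q, Translation(), delta=d) == pytest.approx(1.0)


def test_bias_empty_matching_is_undefined():
    p = PointSet(np.array([[0.0, 0.0]]))
    with pytest.raises(ValueError, match="undefined"):
        bias([], p, p, Translation(), delta=1.0)


# --- maximum bipartite matching -------------------------------------------

def test_single_edge_matching():
    assert max_bipartite_matching([(1, 7)]) == [(1, 7)]


def test_complete_3x3_has_perfect_matching():
    edges = [(i, j) for i in range(3) for j in range(3)]
    m = max_bipartite_matching(edges)
    assert len(m) == 3
    assert len({i for i, _ in m}) == 3 and len({j for _, j in m}) == 3


def test_empty_graph_empty_matching():
    assert max_bipartite_matching([]) == []


def test_hopcroft_karp_matches_exhaustive_enumeration(rng):
    for _ in range(60):
        n_l, n_r = rng.integers(1, 9, size=2)
        density = rng.uniform(0.1, 0.7)
        edges = [
            (int(i), int(j))
            for i in range(n_l)
            for j in range(n_r)
            if rng.random() < density
        ]
        got = max_bipartite_matching(edges)
        # result is a valid matching of maximum cardinality
        assert len({i for i, _ in got}) == len(got)
        assert len({j for _, j in got}) == len(got)
        assert set(got) <= set(edges)
        assert len(got) == brute_force_max_matching(edges)


# --- try_translation -------------------------------------------------------

def test_exact_copy_matches_perfectly_under_generating_shift(rng):
    p, q = planted_sets(rng, n_shared=8, shift=(2.0, 1.0))
    params = PPMParams(matching_distance=0.5)
    m = try_translation(p, q, Translation(2.0, 1.0), params)
    assert len(m.pairs) == 8
    assert m.bias == pytest.approx(0.0, abs=1e-9)
    assert m.accepted
    assert set(m.pairs) == {(i, i) for i in range(8)}


def test_zero_translation_beyond_delta_matches_nothing(rng):
    p, q = planted_sets(rng, n_shared=8, shift=(2.0, 1.0))  # |shift| > delta
    m = try_translation(p, q, Translation(), PPMParams(matching_distance=0.5))
    assert len(m.pairs) == 0 and not m.accepted


def test_try_translation_equals_brute_force_assignment(rng):
    for _ in range(20):
        p, q = planted_sets(rng, n_shared=6, n_unique2=1, jitter=0.5)
        params = PPMParams(matching_distance=2.0, max_neighbors=10)
        m = try_translation(p, q, Translation(), params)
        edges = [
            (a, b)
            for a in range(len(p))
            for b in range(len(q))
            if np.linalg.norm(p.points[a] - q.points[b]) <= 2.0
        ]
        assert len(m.pairs) == brute_force_max_matching(edges)


def test_empty_inputs_give_non_accepted_matching():
    empty = PointSet(np.empty((0, 2)))
    some = PointSet(np.array([[1.0, 1.0]]))
    for a, b in ((empty, some), (some, empty)):
        m = try_translation(a, b, Translation(), PPMParams())
        assert len(m.pairs) == 0 and not m.accepted


# --- ppm_match -------------------------------------------------------------

def test_planted_correspondence_recovered_with_distractors(rng):
    shift = (1.5, -2.0)
    p, q = planted_sets(rng, n_shared=20, n_unique1=5, n_unique2=5,
                        shift=shift, jitter=0.1)
    params = PPMParams(matching_distance=1.0, max_translation=3.0)
    m = ppm_match(p, q, params)
    assert m.accepted
    recovered = np.array([m.translation.dx, m.translation.dy])
    assert np.linalg.norm(recovered - shift) <= params.matching_distance
    true = {(i, i) for i in range(20)}
    assert true <= set(m.pairs) or len(true & set(m.pairs)) >= 19


def test_no_match_reported_for_incompatible_clouds(rng):
    p = PointSet(rng.uniform(0, 20, size=(10, 2)))
    q = PointSet(rng.uniform(500, 520, size=(10, 2)))
    m = ppm_match(p, q, PPMParams(matching_distance=1.0, max_translation=3.0,
                                  matching_ratio=0.5))
    assert not m.accepted and len(m.pairs) == 0


def test_normal_cloud_with_missing_points_matches_at_expected_fraction(rng):
    """300 normally distributed points, 20% dropped from the second set,
    small jitter: the matched fraction of the smaller set is ~0.8 of the
    model set and every matched pair is a true correspondence."""
    base = rng.normal(0, 40, size=(300, 2))
    keep = rng.random(300) > 0.2
    jitter = rng.normal(0, 0.05, size=(keep.sum(), 2))
    shift = np.array([1.0, -0.5])
    p = PointSet(base)
    q = PointSet(base[keep] + shift + jitter)
    params = PPMParams(matching_distance=0.5, max_translation=3.0, max_neighbors=10)
    m = ppm_match(p, q, params)
    assert m.accepted
    true_pairs = {(i, rank) for rank, i in enumerate(np.flatnonzero(keep))}
    correct = len(set(m.pairs) & true_pairs)
    assert correct / 300 == pytest.approx(keep.mean(), abs=0.03)
    assert correct / len(m.pairs) >= 0.98


def test_ppm_cardinality_equals_exhaustive_search(rng):
    """Small-instance oracle equivalence over random configurations."""
    params = PPMParams(matching_distance=1.5, matching_ratio=0.0,
                       max_bias=np.inf, max_neighbors=10, max_translation=1e9)
    for _ in range(40):
        n, m_ = rng.integers(2, 9, size=2)
        p = rng.uniform(0, 10, size=(n, 2))
        q = rng.uniform(0, 10, size=(m_, 2))
        got = ppm_match(PointSet(p), PointSet(q), params)
        want = brute_force_ppm_cardinality(p, q, delta=1.5)
        assert len(got.pairs) == want


def test_translation_invariance_of_association(rng):
    p, q = planted_sets(rng, n_shared=15, n_unique1=3, n_unique2=4, jitter=0.1)
    params = PPMParams(matching_distance=1.0)
    base = association(p, q, params)
    v = np.array([30.0, -12.5])
    moved = association(
        PointSet(p.points + v), PointSet(q.points + v), params
    )
    assert moved.assoc_ch1 == pytest.approx(base.assoc_ch1)
    assert moved.assoc_ch2 == pytest.approx(base.assoc_ch2)
    # shifting only Q within the translation budget changes nothing (zero jitter)
    p0, q0 = planted_sets(rng, n_shared=15, n_unique1=3, n_unique2=4)
    a0 = association(p0, q0, params)
    a_shift = association(p0, PointSet(q0.points + [2.0, 1.0]), params)
    assert a_shift.assoc_ch1 == pytest.approx(a0.assoc_ch1)


def test_matching_cardinality_symmetric_between_channels(rng):
    p, q = planted_sets(rng, n_shared=12, n_unique1=4, n_unique2=6,
                        shift=(1.0, 1.0))
    params = PPMParams(matching_distance=1.0)
    assert len(ppm_match(p, q, params).pairs) == len(ppm_match(q, p, params).pairs)


def test_accepted_matching_satisfies_all_constraints(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        p, q = planted_sets(r, n_shared=15, n_unique1=5, n_unique2=5,
                            shift=(2.0, 0.5), jitter=0.3)
        params = PPMParams(matching_distance=1.5)
        m = ppm_match(p, q, params)
        if not m.accepted:
            continue
        validate_matching(m, p, q, params.matching_distance)
        assert len(m.pairs) >= params.matching_ratio * min(len(p), len(q))
        assert m.bias <= params.max_bias
        assert m.translation.magnitude <= params.max_translation


# --- association -----------------------------------------------------------

def test_identical_sets_fully_associated(rng):
    pts = rng.uniform(0, 50, size=(20, 2))
    res = association(PointSet(pts), PointSet(pts.copy()),
                      PPMParams(matching_distance=1.0))
    assert res.assoc_ch1 == res.assoc_ch2 == 1.0


def test_planted_high_scenario_counts_give_preset_fractions(rng):
    """83 shared of 111 and 97 objects, zero jitter: the matched fractions
    are exactly 83/111 and 83/97."""
    p, q = planted_sets(rng, n_shared=83, n_unique1=28, n_unique2=14,
                        shift=(1.0, 0.5), extent=400.0)
    res = association(p, q, PPMParams(matching_distance=1.5))
    assert res.n_objects_ch1 == 111 and res.n_objects_ch2 == 97
    assert res.assoc_ch1 == pytest.approx(83 / 111)
    assert res.assoc_ch2 == pytest.approx(83 / 97)
    assert round(res.assoc_ch1, 4) == 0.7477
    assert round(res.assoc_ch2, 4) == 0.8557


def test_empty_channel_gives_zero_association(rng):
    p = PointSet(rng.uniform(0, 10, size=(5, 2)))
    res = association(p, PointSet(np.empty((0, 2))), PPMParams())
    assert res.assoc_ch1 == 0.0 and res.assoc_ch2 == 0.0
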