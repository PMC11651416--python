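"""Box-overlap measures and point-to-trajectory distance geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pointline.geometry import (
    Box,
    Detection,
    SegmentCase,
    diou,
    iou,
    line_distance,
    match_detections,
    mean_line_distance,
    point_polyline_distance,
    point_segment_distance,
)

from conftest import random_box


def dense_segment_distance(p, a, b, n=100_000):
    """Brute-force oracle: min distance over n evenly spaced points on [a, b]."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = np.asarray(a, float) + t * (np.asarray(b, float) - np.asarray(a, float))
    return float(np.min(np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1])))


class TestIoU:
    def test_identical_boxes(self):
        b = Box(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(Box(0, 0, 1, 1), Box(5, 5, 6, 6)) == 0.0

    def test_partial_overlap_exact(self):
        # unit overlap, union 7
        assert iou(Box(0, 0, 2, 2), Box(1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_matches_shapely_on_random_boxes(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import box as sbox

        for _ in range(300):
            a, b = random_box(rng), random_box(rng)
            sa = sbox(a.x1, a.y1, a.x2, a.y2)
            sb = sbox(b.x1, b.y1, b.x2, b.y2)
            expected = sa.intersection(sb).area / sa.union(sb).area
            assert iou(a, b) == pytest.approx(expected, abs=1e-9)

    def test_zero_area_union_is_zero(self):
        z = Box(1, 1, 1, 1)
        assert iou(z, z) == 0.0


class TestDIoU:
    def test_identical_boxes(self):
        b = Box(0, 0, 4, 4)
        assert diou(b, b) == 1.0

    def test_concentric_equals_iou(self):
        a, b = Box(0, 0, 8, 8), Box(2, 2, 6, 6)
        assert diou(a, b) == pytest.approx(iou(a, b))

    def test_offset_boxes_exact(self):
        # IoU 1/7, center distance^2 = 2, enclosing diagonal^2 = 18
        assert diou(Box(0, 0, 2, 2), Box(1, 1, 3, 3)) == pytest.approx(1 / 7 - 1 / 9)

    def test_never_exceeds_iou_and_symmetric(self, rng):
        for _ in range(500):
            a, b = random_box(rng), random_box(rng)
            assert diou(a, b) <= iou(a, b) + 1e-12
            assert diou(a, b) == pytest.approx(diou(b, a))

    def test_translation_invariance(self, rng):
        for _ in range(100):
            a, b = random_box(rng), random_box(rng)
            dx, dy = rng.uniform(-50, 50, size=2)
            a2 = Box(a.x1 + dx, a.y1 + dy, a.x2 + dx, a.y2 + dy)
            b2 = Box(b.x1 + dx, b.y1 + dy, b.x2 + dx, b.y2 + dy)
            assert diou(a2, b2) == pytest.approx(diou(a, b), abs=1e-9)
            assert iou(a2, b2) == pytest.approx(iou(a, b), abs=1e-9)

    def test_coincident_degenerate_points_rejected(self):
        z = Box(1, 1, 1, 1)
        with pytest.raises(ValueError):
            diou(z, z)


class TestPointSegmentDistance:
    def test_foot_before_a_boundary(self):
        r = point_segment_distance((0, 0), (0, 1), (1, 1))
        assert r.case is SegmentCase.FOOT_BEFORE_A
        assert r.distance == pytest.approx(1.0)
        assert r.foot is None

    def test_interior_foot(self):
        r = point_segment_distance((0.5, 0), (0, 1), (1, 1))
        assert r.case is SegmentCase.FOOT_INTERIOR
        assert r.distance == pytest.approx(1.0)
        assert r.foot == pytest.approx((0.5, 1.0))

    def test_foot_after_b(self):
        r = point_segment_distance((3, 1), (0, 1), (1, 1))
        assert r.case is SegmentCase.FOOT_AFTER_B
        assert r.distance == pytest.approx(2.0)

    def test_degenerate_segment(self):
        r = point_segment_distance((3, 4), (0, 0), (0, 0))
        assert r.case is SegmentCase.FOOT_BEFORE_A
        assert r.distance == pytest.approx(5.0)

    def test_against_dense_sampling_oracle(self, rng):
        for _ in range(1000):
            p, a, b = rng.uniform(-10, 10, size=(3, 2))
            got = point_segment_distance(p, a, b).distance
            assert got == pytest.approx(dense_segment_distance(p, a, b, 20_000), abs=1e-4)

    def test_never_exceeds_endpoint_distances(self, rng):
        for _ in range(500):
            p, a, b = rng.uniform(-10, 10, size=(3, 2))
            d = point_segment_distance(p, a, b).distance
            assert d <= math.dist(p, a) + 1e-12
            assert d <= math.dist(p, b) + 1e-12

    def test_continuity_in_p(self, rng):
        # small moves of p change the distance by at most the move length
        for _ in range(200):
            p, a, b = rng.uniform(-5, 5, size=(3, 2))
            eps = rng.normal(0, 1e-4, size=2)
            d0 = point_segment_distance(p, a, b).distance
            d1 = point_segment_distance(p + eps, a, b).distance
            assert abs(d1 - d0) <= float(np.hypot(*eps)) + 1e-12


class TestPointPolylineDistance:
    def test_on_vertex_is_zero(self):
        poly = [(0, 0), (5, 1), (9, -2)]
        assert point_polyline_distance((5, 1), poly) == 0.0

    def test_vertical_drop(self):
        assert point_polyline_distance((5, 3), [(0, 0), (10, 0)]) == pytest.approx(3.0)

    def test_single_point_polyline(self):
        assert point_polyline_distance((3, 4), [(0, 0)]) == pytest.approx(5.0)

    def test_empty_polyline_rejected(self):
        with pytest.raises(ValueError):
            point_polyline_distance((0, 0), np.empty((0, 2)))

    def test_against_shapely_oracle(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import LineString, Point

        for _ in range(300):
            p = rng.uniform(-20, 20, size=2)
            poly = rng.uniform(-20, 20, size=(10, 2))
            expected = LineString(poly).distance(Point(p))
            assert point_polyline_distance(p, poly) == pytest.approx(expected, abs=1e-9)

    def test_zero_length_segments_ignored(self):
        poly = [(0, 0), (0, 0), (10, 0)]
        assert point_polyline_distance((5, 2), poly) == pytest.approx(2.0)


class TestLineDistance:
    def test_three_point_example(self):
        preds = [(1, 1), (5, -1), (9, 0)]
        assert line_distance(preds, [(0, 0), (10, 0)]) == pytest.approx(2 / 3)

    def test_points_on_trajectory_give_zero(self, rng):
        poly = rng.uniform(0, 50, size=(6, 2))
        t = rng.uniform(0, 1, size=8)
        seg = rng.integers(0, 5, size=8)
        preds = poly[seg] + t[:, None] * (poly[seg + 1] - poly[seg])
        assert line_distance(preds, poly) == pytest.approx(0.0, abs=1e-9)

    def test_single_point_degenerate(self):
        assert line_distance([(2, 2)], [(2, 2)]) == 0.0

    def test_no_predictions_rejected(self):
        with pytest.raises(ValueError):
            line_distance(np.empty((0, 2)), [(0, 0), (1, 1)])


class _GT:
    def __init__(self, category, points):
        self.category = category
        self.points = np.asarray(points, float)


def _det(box, category="leaf", score=0.9, kps=()):
    return Detection(box, category, score, np.asarray(kps, float).reshape(-1, 2))


class TestMatching:
    def test_exact_overlap_matches(self):
        gt = (Box(0, 0, 10, 10), _GT("leaf", [(0, 0), (10, 10)]))
        table = match_detections([_det(Box(0, 0, 10, 10))], [gt], 0.5)
        assert table.pairs == [(0, 0)]
        assert not table.unmatched_detections
        assert not table.unmatched_ground_truths

    def test_class_gate(self):
        gt = (Box(0, 0, 10, 10), _GT("stalk", [(0, 0), (10, 10)]))
        table = match_detections([_det(Box(0, 0, 10, 10), "leaf")], [gt], 0.5)
        assert table.pairs == []
        assert table.unmatched_detections == [0]
        assert table.unmatched_ground_truths == [0]

    def test_higher_score_wins_double_detection(self):
        gt = (Box(0, 0, 10, 10), _GT("leaf", [(0, 0), (10, 10)]))
        dets = [_det(Box(0, 0, 10, 10), score=0.7), _det(Box(0, 0, 10, 10), score=0.9)]
        table = match_detections(dets, [gt], 0.5)
        assert table.pairs == [(1, 0)]
        assert table.unmatched_detections == [0]
        # reversed score order flips the winner
        dets2 = [_det(Box(0, 0, 10, 10), score=0.9), _det(Box(0, 0, 10, 10), score=0.7)]
        assert match_detections(dets2, [gt], 0.5).pairs == [(0, 0)]

    def test_empty_inputs(self):
        table = match_detections([], [], 0.5)
        assert table.pairs == [] and table.unmatched_detections == []


class TestMeanLineDistance:
    def test_single_pair(self):
        gt = (Box(0, 0, 10, 10), _GT("leaf", [(0, 0), (10, 0)]))
        det = _det(Box(0, 0, 10, 10), kps=[(5, 5)])
        table = match_detections([det], [gt], 0.5)
        rep = mean_line_distance(table, [det], [gt])
        assert rep.mld == pytest.approx(5.0)
        assert rep.n_matched == 1

    def test_mean_of_two_pairs(self):
        gts = [
            (Box(0, 0, 10, 10), _GT("leaf", [(0, 0), (10, 0)])),
            (Box(20, 0, 30, 10), _GT("leaf", [(20, 0), (30, 0)])),
        ]
        dets = [
            _det(Box(0, 0, 10, 10), kps=[(5, 1)]),
            _det(Box(20, 0, 30, 10), kps=[(25, 3)]),
        ]
        rep = mean_line_distance(match_detections(dets, gts, 0.5), dets, gts)
        assert rep.mld == pytest.approx(2.0)
        assert rep.per_target_ld == pytest.approx([1.0, 3.0])

    def test_perfect_predictions_give_zero(self):
        gt = (Box(0, 0, 10, 10), _GT("leaf", [(0, 0), (10, 10)]))
        det = _det(Box(0, 0, 10, 10), kps=[(2, 2), (7, 7)])
        rep = mean_line_distance(match_detections([det], [gt], 0.5), [det], [gt])
        assert rep.mld == 0.0

    def test_no_matches_reports_absent(self):
        rep = mean_line_distance(match_detections([], [], 0.5), [], [])
        assert rep.mld is None and rep.n_matched == 0

    def test_scales_linearly_with_coordinates(self, rng):
        gts, dets = [], []
        for i in range(4):
            off = 40.0 * i
            poly = rng.uniform(0, 30, size=(5, 2)) + off
            kps = rng.uniform(0, 30, size=(6, 2)) + off
            lo, hi = poly.min(0) - 5, poly.max(0) + 5
            gts.append((Box(lo[0], lo[1], hi[0], hi[1]), _GT("leaf", poly)))
            dets.append(_det(Box(lo[0], lo[1], hi[0], hi[1]), kps=kps))
        base = mean_line_distance(match_detections(dets, gts, 0.5), dets, gts).mld
        s = 3.7
        gts_s = [
            (Box(b.x1 * s, b.y1 * s, b.x2 * s, b.y2 * s), _GT("leaf", g.points * s))
            for b, g in gts
        ]
        dets_s = [
            _det(Box(d.box.x1 * s, d.box.y1 * s, d.box.x2 * s, d.box.y2 * s),
                 kps=d.keypoints * s)
            for d in dets
        ]
        scaled = mean_line_distance(match_detections(dets_s, gts_s, 0.5), dets_s, gts_s).mld
        assert scaled == pytest.approx(s * base, rel=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.tuples(
        st.floats(-50, 50), st.floats(-50, 50),
        st.floats(0.1, 40), st.floats(0.1, 40),
    ),
    st.tuples(
        st.floats(-50, 50), st.floats(-50, 50),
        st.floats(0.1, 40), st.floats(0.1, 40),
    ),
)
def test_diou_le_iou_property(a, b):
    """D-IoU never exceeds IoU; they agree exactly when centers coincide."""
    box_a = Box(a[0], a[1], a[0] + a[2], a[1] + a[3])
    box_b = Box(b[0], b[1], b[0] + b[2], b[1] + b[3])
    assert diou(box_a, box_b) <= iou(box_a, box_b) + 1e-12
    centered = Box(
        box_a.center[0] - box_b.width / 2,
        box_a.center[1] - box_b.height / 2,
        box_a.center[0] + box_b.width / 2,
        box_a.center[1] + box_b.height / 2,
    )
    assert diou(box_a, centered) == pytest.approx(iou(box_a, centered), abs=1e-12)
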