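import math

import numpy as np
import pytest

from conftest import flood_fill_count
from micronuclei.clsa import MicronucleusCall
from micronuclei.io_images import DetectionBox
from micronuclei.regions import (
    CountsReport,
    boundary_regions,
    count_report,
    label_components,
    rasterize_boxes,
    ratio_split,
    region_algebra,
)


def brute_force_algebra(n, c_mask, y_mask, min_frac=0.0):
    """Independent oracle: literal per-component set operations."""
    h, w = n.shape
    out = {}
    for cid in range(1, n.component_count + 1):
        pix = set(zip(*np.nonzero(n.labels == cid)))
        on_border = any(y in (0, h - 1) or x in (0, w - 1) for y, x in pix)
        c_pix = set(zip(*np.nonzero(c_mask)))
        y_pix = set(zip(*np.nonzero(y_mask)))
        if on_border:
            out[cid] = "B"
        elif (len(pix & c_pix) == 0 if min_frac <= 0 else len(pix & c_pix) < min_frac * len(pix)):
            out[cid] = "D"
        elif pix & (y_pix & c_pix):
            out[cid] = "A"
        else:
            out[cid] = "M"
    return out


class TestLabeling:
    def test_empty_mask(self):
        assert label_components(np.zeros((8, 8), bool)).component_count == 0

    def test_two_disjoint_squares(self):
        m = np.zeros((10, 10), bool)
        m[1:4, 1:4] = True
        m[6:9, 6:9] = True
        assert label_components(m).component_count == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(5):
            m = rng.random((64, 64)) < 0.35
            rm = label_components(m, connectivity=connectivity)
            assert rm.component_count == flood_fill_count(m, connectivity)
            assert ((rm.labels > 0) == m).all()

    def test_diagonal_touch_connectivity(self):
        m = np.zeros((4, 4), bool)
        m[0, 0] = m[1, 1] = True
        assert label_components(m, connectivity=8).component_count == 1
        assert label_components(m, connectivity=4).component_count == 2


class TestRasterize:
    def test_no_boxes(self):
        assert rasterize_boxes([], (20, 20)).mask.sum() == 0

    def test_single_box_area(self):
        y = rasterize_boxes([DetectionBox(10, 10, 10, 10)], (20, 20))
        assert y.mask.sum() == 100

    def test_overlapping_boxes_inclusion_exclusion(self):
        boxes = [DetectionBox(10, 10, 10, 10), DetectionBox(14, 14, 10, 10)]
        y = rasterize_boxes(boxes, (30, 30))
        # brute-force pixel count
        a = np.zeros((30, 30), bool)
        for b in boxes:
            x0, x1, y0, y1 = b.pixel_bounds(30, 30)
            a[y0:y1, x0:x1] = True
        assert y.mask.sum() == a.sum()
        assert y.component_count == 1  # merged into one component


class TestBoundary:
    def test_interior_components_excluded(self):
        m = np.zeros((12, 12), bool)
        m[4:7, 4:7] = True
        assert boundary_regions(label_components(m)).mask.sum() == 0

    def test_corner_component_included_entirely(self):
        m = np.zeros((12, 12), bool)
        m[0:4, 0:4] = True
        m[6:9, 6:9] = True
        b = boundary_regions(label_components(m))
        assert b.mask.sum() == 16  # the whole corner square, nothing else


class TestAlgebra:
    def test_saturation(self):
        n = np.zeros((16, 16), bool)
        n[3:6, 3:6] = True
        n[9:13, 9:13] = True
        full = np.ones((16, 16), bool)
        res = region_algebra(
            label_components(n), label_components(full, tag="C"),
            label_components(full, tag="Y"),
        )
        assert res.d.component_count == 0
        assert res.m.component_count == 0
        assert (res.a.mask == n).all()

    def test_empty_cytoskeleton_invalidates_everything(self):
        n = np.zeros((16, 16), bool)
        n[3:6, 3:6] = True
        empty = np.zeros((16, 16), bool)
        full = np.ones((16, 16), bool)
        res = region_algebra(
            label_components(n), label_components(empty, tag="C"),
            label_components(full, tag="Y"),
        )
        assert res.p.component_count == 0
        assert (res.d.mask == n).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            region_algebra(
                label_components(np.zeros((4, 4), bool)),
                label_components(np.zeros((5, 5), bool), tag="C"),
                label_components(np.zeros((4, 4), bool), tag="Y"),
            )

    def test_matches_brute_force_oracle_and_partitions(self, rng):
        for _ in range(10):
            n_mask = rng.random((32, 32)) < 0.2
            c_mask = rng.random((32, 32)) < 0.5
            y_mask = rng.random((32, 32)) < 0.4
            n = label_components(n_mask)
            res = region_algebra(
                n, label_components(c_mask, tag="C"), label_components(y_mask, tag="Y")
            )
            assert res.category == brute_force_algebra(n, c_mask, y_mask)
            # B, D and P partition N at pixel level
            together = res.b.mask | res.d.mask | res.p.mask
            assert (together == n_mask).all()
            assert not (res.b.mask & res.d.mask).any()
            assert not (res.b.mask & res.p.mask).any()
            assert not (res.d.mask & res.p.mask).any()
            # A and M partition P
            assert (res.a.mask | res.m.mask == res.p.mask).all()
            assert not (res.a.mask & res.m.mask).any()

    def test_monotonicity(self, rng):
        n_mask = rng.random((32, 32)) < 0.2
        c_mask = rng.random((32, 32)) < 0.3
        y_mask = rng.random((32, 32)) < 0.3
        n = label_components(n_mask)
        res1 = region_algebra(
            n, label_components(c_mask, tag="C"), label_components(y_mask, tag="Y")
        )
        bigger_c = c_mask | (rng.random((32, 32)) < 0.3)
        res2 = region_algebra(
            n, label_components(bigger_c, tag="C"), label_components(y_mask, tag="Y")
        )
        assert res2.d.component_count <= res1.d.component_count
        bigger_y = y_mask | (rng.random((32, 32)) < 0.3)
        res3 = region_algebra(
            n, label_components(c_mask, tag="C"), label_components(bigger_y, tag="Y")
        )
        assert res3.m.component_count <= res1.m.component_count


class TestCounts:
    @pytest.mark.parametrize(
        "normal,abnormal,expected",
        [
            (29, 18, (61.7, 38.3)),
            (238, 38, (86.2, 13.8)),
            (489, 44, (91.7, 8.3)),
            (422, 163, (72.1, 27.9)),
            (1, 0, (100.0, 0.0)),
        ],
    )
    def test_ratio_split(self, normal, abnormal, expected):
        assert ratio_split(normal, abnormal) == expected

    def test_ratio_undefined_for_no_valid_nuclei(self):
        rn, ra = ratio_split(0, 0)
        assert math.isnan(rn) and math.isnan(ra)

    def test_within_image_arithmetic(self):
        report = CountsReport.build(
            detected=45, free_regions=25, boundary=7, invalid=23,
            normal=29, micronuclei=9, mitotic_or_micro=9,
        )
        assert report.total_regions == 70
        assert report.within_image == 38
        assert report.ratio_normal + report.ratio_abnormal == pytest.approx(100.0, abs=0.1)

    def test_count_report_buckets_every_component_once(self, rng):
        n_mask = rng.random((32, 32)) < 0.2
        c_mask = rng.random((32, 32)) < 0.5
        y_mask = rng.random((32, 32)) < 0.4
        n = label_components(n_mask)
        res = region_algebra(
            n, label_components(c_mask, tag="C"), label_components(y_mask, tag="Y")
        )
        calls = [
            MicronucleusCall(cid, cid % 2 == 0, (), math.nan, 4.0)
            for cid in res.ids("A")
        ]
        report = count_report(res, calls)
        total_bucketed = (
            report.boundary + report.invalid + report.normal
            + report.micronuclei + report.mitotic_or_micro
        )
        assert total_bucketed == n.component_count
        assert report.total_regions == n.component_count
        assert report.detected == len(res.detected_ids)
        assert report.within_image == report.detected - report.boundary
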