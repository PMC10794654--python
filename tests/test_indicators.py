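"""Geometry of the medical indicators: denoising, centers, decentration,
defocus zone, four-neighborhood boundaries and EDCR."""

import numpy as np
import pytest

import oktopo as ok
from oktopo.indicators import (
    UngradableRegionError,
    boundary_4n,
    compute_indicators,
    decentration,
    defocus_zone,
    edcr,
    largest_component,
    region_center,
)

from conftest import disk_mask


class TestLargestComponent:
    def test_single_blob_unchanged(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[5:10, 5:10] = 1
        assert np.array_equal(largest_component(m), m)

    def test_speckle_removed(self):
        m = np.zeros((40, 40), dtype=np.uint8)
        m[5:28, 5:28] = 1  # ~500 px blob
        m[35, 35] = m[35, 36] = m[36, 35] = 1  # 3 px speckle
        out = largest_component(m)
        assert out[35, 35] == 0 and out[5:28, 5:28].all()
        assert out.sum() == 23 * 23

    def test_equal_area_tie_break_is_scan_order(self):
        # two 2x2 blobs; the one whose first positive pixel comes first in
        # row-major order must win
        m = np.zeros((10, 10), dtype=np.uint8)
        m[1:3, 6:8] = 1  # first positive pixel (1, 6)
        m[2:4, 1:3] = 1  # first positive pixel (2, 1)
        out = largest_component(m)
        assert out[1, 6] == 1 and out[2, 1] == 0

    def test_empty_mask_passthrough(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        assert largest_component(m).sum() == 0

    def test_bad_connectivity(self):
        with pytest.raises(ValueError):
            largest_component(np.ones((4, 4), dtype=np.uint8), connectivity=6)


class TestRegionCenter:
    def test_disk_center_symmetry(self):
        geom = region_center(disk_mask((224, 224), (112, 112), 30).pixels)
        assert abs(geom.center_px[0] - 112) <= 0.5
        assert abs(geom.center_px[1] - 112) <= 0.5

    def test_rectangle_bbox_center(self):
        # rows 10..20, cols 30..50 -> center (x=40, y=15)
        m = np.zeros((60, 80), dtype=np.uint8)
        m[10:21, 30:51] = 1
        geom = region_center(m)
        assert geom.bbox == (30, 10, 50, 20)
        assert geom.center_px == (40.0, 15.0)

    def test_empty_mask_is_ungradable(self):
        with pytest.raises(UngradableRegionError):
            region_center(np.zeros((16, 16), dtype=np.uint8))


class TestDecentration:
    def test_identical_centers(self):
        g = region_center(disk_mask((64, 64), (32, 32), 10).pixels)
        assert decentration(g, g) == (0.0, 0.0)

    def test_3_4_5_triangle_at_50px_per_mm(self):
        # centers (100,100) and (130,140): distance 50 px = 1.0 mm
        a = region_center(disk_mask((256, 256), (100, 100), 8).pixels)
        b = region_center(disk_mask((256, 256), (130, 140), 8).pixels)
        d_px, d_mm = decentration(a, b, px_per_mm=50)
        assert d_px == pytest.approx(50.0, abs=1.0)
        assert d_mm == pytest.approx(1.0, abs=0.02)

    def test_linear_scale(self):
        a = region_center(disk_mask((128, 128), (30, 60), 6).pixels)
        b = region_center(disk_mask((128, 128), (55, 60), 6).pixels)
        d_px, d_mm = decentration(a, b, px_per_mm=50)
        assert d_px == pytest.approx(25.0, abs=1.0)
        assert d_mm == pytest.approx(0.5, abs=0.02)

    def test_invalid_scale(self):
        g = region_center(np.ones((8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            decentration(g, g, px_per_mm=0)


class TestDefocusZone:
    def test_full_coverage_empty(self):
        p = disk_mask((64, 64), (32, 32), 10).pixels
        t = disk_mask((64, 64), (32, 32), 20).pixels
        assert defocus_zone(p, t).sum() == 0

    def test_disjoint_equals_pupil(self):
        p = disk_mask((64, 64), (16, 16), 6).pixels
        t = disk_mask((64, 64), (48, 48), 6).pixels
        assert np.array_equal(defocus_zone(p, t), p)

    def test_set_arithmetic_areas(self):
        p = np.zeros((20, 20), dtype=np.uint8)
        p[0:10, 0:10] = 1  # 100 px
        t = np.zeros((20, 20), dtype=np.uint8)
        t[0:10, 6:16] = 1  # overlap 40 px
        dz = defocus_zone(p, t)
        assert dz.sum() == 60

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            defocus_zone(np.zeros((4, 4), dtype=np.uint8), np.zeros((5, 5), dtype=np.uint8))


class TestBoundary4N:
    def test_3x3_square_has_8_boundary_px(self):
        m = np.zeros((7, 7), dtype=np.uint8)
        m[2:5, 2:5] = 1
        b = boundary_4n(m)
        assert b.sum() == 8
        assert not b[3, 3]

    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        assert boundary_4n(m).sum() == 1

    def test_full_mask_boundary_is_image_border(self):
        m = np.ones((6, 9), dtype=np.uint8)
        b = boundary_4n(m)
        expected = np.zeros((6, 9), dtype=bool)
        expected[0, :] = expected[-1, :] = True
        expected[:, 0] = expected[:, -1] = True
        assert np.array_equal(b, expected)


class TestEdcr:
    def test_contained_pupil_zero(self):
        p = disk_mask((224, 224), (112, 112), 30).pixels
        t = disk_mask((224, 224), (112, 112), 45).pixels
        assert edcr(p, t).edcr == 0.0

    def test_disjoint_tz_one(self):
        p = disk_mask((128, 128), (40, 40), 20).pixels
        t = disk_mask((128, 128), (100, 100), 20).pixels
        frag = edcr(p, t)
        assert frag.edcr == 1.0
        assert frag.ecv_px == frag.pupil_boundary_len_px

    def test_offset_circles_match_analytic(self):
        # pupil radius >= 40 px: discretisation error must stay below 0.05
        for off in (30, 50, 70):
            p = disk_mask((320, 320), (150, 160), 45).pixels
            t = disk_mask((320, 320), (150 + off, 160), 55).pixels
            got = edcr(p, t).edcr
            want = ok.analytic_edcr((150, 160), 45, (150 + off, 160), 55)
            assert got == pytest.approx(want, abs=0.05)

    def test_empty_pupil_ungradable(self):
        with pytest.raises(UngradableRegionError):
            edcr(np.zeros((8, 8), dtype=np.uint8), np.ones((8, 8), dtype=np.uint8))

    def test_monotone_under_concentric_tz_growth(self):
        # growing the treatment zone over a fixed pupil can only reduce the
        # fraction of the pupil boundary left in the defocus region
        p = disk_mask((320, 320), (160, 160), 50).pixels
        values = []
        for rt in range(20, 120, 5):
            t = disk_mask((320, 320), (185, 160), rt).pixels
            values.append(edcr(p, t).edcr)
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestComputeIndicators:
    def test_matches_generator_truth(self, small_dataset):
        for case in small_dataset:
            ind = compute_indicators(case.pupil_mask, case.tz_mask,
                                     px_per_mm=case.image.px_per_mm)
            assert ind.decentration_px == pytest.approx(
                case.true_indicators.decentration_px, abs=1.0
            )
            assert ind.edcr == pytest.approx(case.true_indicators.edcr, abs=0.05)

    def test_denoising_idempotence(self):
        p = disk_mask((128, 128), (60, 60), 25).pixels.copy()
        t = disk_mask((128, 128), (70, 60), 30).pixels
        base = compute_indicators(p, t)
        p_noisy = p.copy()
        p_noisy[5, 5] = p_noisy[5, 6] = 1  # 2 px speckle far away
        noisy = compute_indicators(p_noisy, t)
        assert noisy.to_dict() == base.to_dict()

    def test_empty_tz_names_region(self):
        p = disk_mask((64, 64), (32, 32), 10).pixels
        with pytest.raises(UngradableRegionError) as exc:
            compute_indicators(p, np.zeros((64, 64), dtype=np.uint8))
        assert exc.value.region == ok.TREATMENT_ZONE

    def test_translation_invariance(self):
        p = disk_mask((256, 256), (80, 90), 30).pixels
        t = disk_mask((256, 256), (110, 100), 40).pixels
        a = compute_indicators(p, t)
        b = compute_indicators(np.roll(p, (37, -21), (0, 1)),
                               np.roll(t, (37, -21), (0, 1)))
        assert b.decentration_px == pytest.approx(a.decentration_px, abs=1e-9)
        assert b.edcr == pytest.approx(a.edcr, abs=1e-9)

    def test_rotation_equivariance(self):
        # a rigid 90-degree rotation of both masks preserves the distance
        p = disk_mask((256, 256), (80, 90), 30).pixels
        t = disk_mask((256, 256), (110, 100), 40).pixels
        a = compute_indicators(p, t)
        b = compute_indicators(np.rot90(p).copy(), np.rot90(t).copy())
        assert b.decentration_px == pytest.approx(a.decentration_px, abs=1e-9)
        assert b.edcr == pytest.approx(a.edcr, abs=1e-9)
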