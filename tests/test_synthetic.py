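"""The synthetic topography generator: analytic EDCR oracle, rendering
contracts, dataset sampling and determinism."""

import math

import numpy as np
import pytest

import oktopo as ok
from oktopo.synthetic import CaseParams, ParamRanges, analytic_edcr, generate_case, generate_dataset


def numeric_edcr(pc, rp, tc, rt, n=200_000):
    """Independent oracle: dense angular sampling of the pupil circle."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = pc[0] + rp * np.cos(th)
    y = pc[1] + rp * np.sin(th)
    outside = (x - tc[0]) ** 2 + (y - tc[1]) ** 2 > rt * rt
    return outside.mean()


class TestAnalyticEdcr:
    def test_pupil_contained_in_tz(self):
        assert analytic_edcr((112, 112), 30, (112, 112), 45) == 0.0

    def test_tz_contained_in_pupil(self):
        assert analytic_edcr((112, 112), 45, (112, 112), 30) == 1.0

    def test_external_tangency(self):
        assert analytic_edcr((0, 0), 30, (60, 0), 30) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_angular_sampling(self, seed):
        rng = np.random.default_rng(seed)
        pc = tuple(rng.uniform(-5, 5, 2))
        tc = tuple(rng.uniform(-60, 60, 2))
        rp = rng.uniform(20, 80)
        rt = rng.uniform(20, 80)
        got = analytic_edcr(pc, rp, tc, rt)
        want = numeric_edcr(pc, rp, tc, rt)
        assert got == pytest.approx(want, abs=2e-4)

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            analytic_edcr((0, 0), 0, (1, 1), 5)


class TestGenerateCase:
    def test_concentric_contained_pupil(self):
        # tz strictly covers the pupil: no defocus contact at all
        params = CaseParams(
            image_size_px=(224, 224), pupil_center_px=(112, 112), pupil_radius_px=30,
            tz_center_px=(112, 112), tz_radius_px=45,
        )
        case = generate_case(params)
        assert case.true_indicators.decentration_mm == 0.0
        assert case.true_indicators.edcr == 0.0
        assert case.true_class is ok.TopoClass.IV

    def test_offset_circles_derive_from_analytic_oracle(self):
        # 3-4-5 offset of 50 px = 1.0 mm at the 1:50 scale
        params = CaseParams(
            image_size_px=(224, 224), pupil_center_px=(112, 112), pupil_radius_px=40,
            tz_center_px=(142, 152), tz_radius_px=40,
        )
        case = generate_case(params)
        assert case.true_indicators.decentration_mm == pytest.approx(1.0)
        want = analytic_edcr((112, 112), 40, (142, 152), 40)
        assert case.true_indicators.edcr == pytest.approx(want)
        # and the pixel pipeline agrees with the continuum oracle
        est = ok.edcr(case.pupil_mask, case.tz_mask).edcr
        assert est == pytest.approx(want, abs=0.05)

    def test_masks_match_image_and_are_binary(self, small_dataset):
        for case in small_dataset:
            assert case.pupil_mask.shape == case.image.shape
            assert case.tz_mask.shape == case.image.shape
            assert set(np.unique(case.pupil_mask.pixels)) <= {0, 1}
            assert set(np.unique(case.tz_mask.pixels)) <= {0, 1}

    def test_class_label_invariant_under_noise(self):
        base = CaseParams(pupil_center_px=(150, 160), pupil_radius_px=50,
                          tz_center_px=(180, 160), tz_radius_px=60)
        labels = set()
        for rng_seed in (0, 1, 2):
            for noise in (0.0, 4.0, 12.0):
                p = CaseParams(**{**base.__dict__, "noise_sd": noise,
                                  "rng_seed": rng_seed})
                labels.add(generate_case(p).true_class)
        assert len(labels) == 1  # labels depend only on geometry

    def test_geometry_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_case(CaseParams(pupil_center_px=(10, 10), pupil_radius_px=30))

    def test_reproducible_from_seeds(self):
        p = CaseParams(pupil_center_px=(150, 150), pupil_radius_px=45,
                       tz_center_px=(170, 150), tz_radius_px=55,
                       background_seed=7, rng_seed=9)
        a, b = generate_case(p), generate_case(p)
        assert np.array_equal(a.image.pixels, b.image.pixels)


class TestGenerateDataset:
    def test_deterministic_given_seed(self):
        a = generate_dataset(12, seed=4)
        b = generate_dataset(12, seed=4)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.image.pixels, cb.image.pixels)
            assert np.array_equal(ca.pupil_mask.pixels, cb.pupil_mask.pixels)
            assert ca.true_class is cb.true_class

    def test_spans_all_four_classes(self, small_dataset):
        labels = {c.true_class.value for c in small_dataset}
        assert labels == {"I", "II", "III", "IV"}

    def test_restricted_decentration_yields_class_iii(self):
        ranges = ParamRanges(decentration_mm=(1.11, 1.45), class_targets=None,
                             edcr=(0.2, 0.8))
        cases = generate_dataset(10, ranges, seed=2)
        assert all(c.true_class is ok.TopoClass.III for c in cases)

    def test_gap_cases_when_requested(self):
        cases = generate_dataset(10, seed=0, include_gap=True)
        assert any(c.true_class is ok.TopoClass.UNCLASSIFIED for c in cases)

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(0)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(4, ParamRanges(pupil_radius_mm=(1.3, 0.8)))

    def test_true_indicators_match_mask_measurements(self, small_dataset):
        for case in small_dataset:
            ind = ok.compute_indicators(case.pupil_mask, case.tz_mask,
                                        px_per_mm=case.image.px_per_mm)
            assert abs(ind.decentration_px
                       - case.true_indicators.decentration_px) <= 1.0
            assert abs(ind.edcr - case.true_indicators.edcr) <= 0.05
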