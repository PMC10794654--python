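"""Loss, metrics, augmentation, training mechanics and the k-fold harness."""

import math

import numpy as np
import pytest

import oktopo as ok
from oktopo.segmentation import (
    SegMetrics,
    TrainConfig,
    augment,
    ce_loss,
    kfold_evaluate,
    kfold_split,
    predict_masks,
    seg_metrics,
    train,
    train_test_split,
)

from conftest import disk_mask


class TestCeLoss:
    def test_uniform_half_prediction_is_ln2(self):
        pred = np.full((2, 16, 16), 0.5)
        target = np.random.default_rng(0).integers(0, 2, (2, 16, 16))
        assert ce_loss(pred, target) == pytest.approx(math.log(2), abs=1e-9)

    def test_single_pixel_closed_form(self):
        assert ce_loss(np.array([0.25]), np.array([1.0])) == pytest.approx(
            -math.log(0.25), abs=1e-9
        )

    def test_perfect_prediction_near_zero(self):
        target = np.zeros((2, 8, 8))
        target[0, :4] = 1.0
        assert ce_loss(target, target) < 1e-5

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ce_loss(np.zeros((2, 4, 4)), np.zeros((2, 5, 5)))


class TestSegMetrics:
    def test_perfect_prediction(self):
        m = disk_mask((64, 64), (32, 32), 12).pixels
        got = seg_metrics(m, m)
        assert (got.precision, got.recall, got.f1, got.iou) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_nonempty_all_zero(self):
        a = np.zeros((10, 10), dtype=np.uint8)
        b = np.zeros((10, 10), dtype=np.uint8)
        a[:2], b[8:] = 1, 1
        got = seg_metrics(a, b)
        assert (got.precision, got.recall, got.f1, got.iou) == (0.0, 0.0, 0.0, 0.0)

    def test_count_arithmetic_example(self):
        # truth 100 px, pred 80 px, 60 overlapping
        truth = np.zeros((20, 20), dtype=np.uint8)
        truth[:5, :20] = 1
        pred = np.zeros((20, 20), dtype=np.uint8)
        pred[:3, :20] = 1  # 60 overlap
        pred[10:11, :20] = 1  # 20 outside
        got = seg_metrics(pred, truth)
        assert got.precision == pytest.approx(0.75)
        assert got.recall == pytest.approx(0.60)
        assert got.f1 == pytest.approx(2 / 3, abs=1e-4)
        assert got.iou == pytest.approx(0.5)

    def test_both_empty_convention(self):
        z = np.zeros((8, 8), dtype=np.uint8)
        got = seg_metrics(z, z)
        assert (got.precision, got.recall, got.iou) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_swap_symmetry_and_dice_jaccard_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((32, 32)) > 0.6).astype(np.uint8)
        b = (rng.random((32, 32)) > 0.6).astype(np.uint8)
        ab, ba = seg_metrics(a, b), seg_metrics(b, a)
        assert ab.precision == ba.recall and ab.recall == ba.precision
        assert ab.f1 == pytest.approx(ba.f1) and ab.iou == pytest.approx(ba.iou)
        if ab.f1 > 0:
            assert ab.iou == pytest.approx(ab.f1 / (2 - ab.f1), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            seg_metrics(np.zeros((4, 4)), np.zeros((4, 5)))


class TestAugment:
    def _sample(self):
        case = ok.generate_case(ok.CaseParams(
            pupil_center_px=(150, 160), pupil_radius_px=50,
            tz_center_px=(180, 160), tz_radius_px=60,
        ))
        masks = np.stack([case.pupil_mask.pixels, case.tz_mask.pixels])
        return case.image.pixels, masks

    def test_identity_parameters(self):
        img, masks = self._sample()
        out_img, out_masks = augment(img, masks, seed=0, max_rot_deg=0,
                                     min_area_frac=1.0, noise_sd=0)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_masks, masks)

    def test_seeded_determinism(self):
        img, masks = self._sample()
        a = augment(img, masks, seed=7)
        b = augment(img, masks, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    @pytest.mark.parametrize("seed", range(4))
    def test_mask_area_roughly_preserved(self, seed):
        img, masks = self._sample()
        _, out_masks = augment(img, masks, seed=seed)
        for before, after in zip(masks, out_masks):
            assert abs(int(after.sum()) - int(before.sum())) < 0.3 * before.sum()


class TestTrainMechanics:
    def test_empty_dataset_rejected(self):
        model = ok.build_model(ok.SegModelConfig(arch="unet", base_width=4))
        with pytest.raises(ValueError):
            train([], model, TrainConfig(batch_size=1, epochs=1, input_size_px=32))

    def test_zero_batch_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)

    def test_batch_larger_than_dataset_rejected(self, small_dataset):
        model = ok.build_model(ok.SegModelConfig(arch="unet", base_width=4))
        with pytest.raises(ValueError):
            train(small_dataset[:4], model,
                  TrainConfig(batch_size=8, epochs=1, input_size_px=32))

    def test_seeded_training_reproducible(self, small_dataset, tiny_train_cfg):
        histories = []
        for _ in range(2):
            model = ok.build_model(ok.SegModelConfig(arch="unet", base_width=4), seed=2)
            histories.append(train(small_dataset[:8], model, tiny_train_cfg).loss_history)
        assert histories[0] == histories[1]

    def test_loss_decreases_on_easy_cases(self):
        # convergence smoke test: a small net on high-contrast synthetic
        # disks must cut the untrained loss by an order of magnitude
        from oktopo.segmentation import _prepare, _sigmoid

        ranges = ok.ParamRanges(noise_sd=(0.0, 2.0))
        cases = ok.generate_dataset(60, ranges, seed=6)
        model = ok.build_model(ok.SegModelConfig(arch="unet", base_width=8), seed=0)
        X, Y = _prepare(cases, 32)
        initial = ce_loss(_sigmoid(model.forward(X[:16])[0].data), Y[:16])
        tc = TrainConfig(batch_size=4, epochs=30, input_size_px=32, seed=0)
        history = train(cases, model, tc).loss_history
        assert history[-1] < initial / 10

    def test_split_is_seeded_and_disjoint(self, small_dataset):
        tr1, te1 = train_test_split(small_dataset, 0.25, seed=3)
        tr2, te2 = train_test_split(small_dataset, 0.25, seed=3)
        assert len(te1) == 6 and len(tr1) == 18
        assert [id(s) for s in te1] == [id(s) for s in te2]


class TestPredictMasks:
    def test_threshold_one_gives_empty_masks(self, small_dataset):
        model = ok.build_model(ok.SegModelConfig(arch="unet", base_width=4), seed=0)
        model.input_size_px = 32
        pup, tz = predict_masks(model, small_dataset[0].image, threshold=1.0)
        assert pup.area == 0 and tz.area == 0

    def test_output_matches_native_resolution(self, small_dataset):
        model = ok.build_model(ok.SegModelConfig(arch="unet", base_width=4), seed=0)
        pup, tz = predict_masks(model, small_dataset[0].image, input_size=32)
        assert pup.shape == small_dataset[0].image.shape
        assert tz.shape == small_dataset[0].image.shape

    def test_missing_input_size_is_an_error(self, small_dataset):
        model = ok.build_model(ok.SegModelConfig(arch="unet", base_width=4), seed=0)
        with pytest.raises(ValueError):
            predict_masks(model, small_dataset[0].image)


class TestKFold:
    def test_partition_property(self):
        folds = kfold_split(100, 10, seed=0)
        assert [len(f) for f in folds] == [10] * 10
        seen = np.concatenate(folds)
        assert sorted(seen.tolist()) == list(range(100))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, 10)
        with pytest.raises(ValueError):
            kfold_split(10, 1)

    def test_kfold_evaluate_reports_table(self, small_dataset, tiny_train_cfg):
        df = kfold_evaluate(small_dataset[:12], k=3,
                            model_cfg=ok.SegModelConfig(arch="unet", base_width=4),
                            train_cfg=tiny_train_cfg)
        assert list(df.index) == [1, 2, 3, "mean"]
        assert df.notna().all().all()
        assert ((df >= 0) & (df <= 1)).all().all()
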