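import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfanet.metrics import (
    BinaryMask,
    dsc,
    evaluate_dataset,
    hausdorff,
    soft_dice_loss,
)
from cfanet.nn.autograd import Tensor


def brute_force_hausdorff(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0)) -> float:
    """O(|A| * |B|) pairwise oracle."""
    pa = np.argwhere(a > 0) * np.asarray(spacing)
    pb = np.argwhere(b > 0) * np.asarray(spacing)
    if len(pa) == 0 or len(pb) == 0:
        return math.nan
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestSoftDiceLoss:
    def test_perfect_prediction_is_zero(self, rng):
        t = (rng.random((6, 6)) < 0.3).astype(np.float32)
        assert soft_dice_loss(t, t, smooth=1.0) == pytest.approx(0.0, abs=1e-6)

    def test_worked_four_pixel_example(self):
        pred = np.full((2, 2), 0.5, dtype=np.float32)
        target = np.zeros((2, 2), dtype=np.float32)
        assert soft_dice_loss(pred, target, smooth=1.0) == pytest.approx(0.5)

    def test_disjoint_limit_approaches_one(self):
        pred = np.array([1.0, 0.0], dtype=np.float32)
        target = np.array([0.0, 1.0], dtype=np.float32)
        assert soft_dice_loss(pred, target, smooth=1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_loss_in_unit_interval(self, rng):
        for _ in range(20):
            p = rng.random((5, 5)).astype(np.float32)
            t = (rng.random((5, 5)) < 0.4).astype(np.float32)
            loss = soft_dice_loss(p, t)
            assert 0.0 <= loss < 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_differentiable_path_matches_numpy(self, rng):
        p = rng.random((2, 1, 4, 4)).astype(np.float32)
        t = (rng.random((2, 1, 4, 4)) < 0.3).astype(np.float32)
        tensor_loss = soft_dice_loss(Tensor(p, requires_grad=True), t)
        assert float(tensor_loss.data) == pytest.approx(soft_dice_loss(p, t), rel=1e-5)

    def test_gradient_finite_difference(self, rng):
        p = Tensor(rng.uniform(0.2, 0.8, (1, 1, 3, 3)).astype(np.float32),
                   requires_grad=True)
        t = (rng.random((1, 1, 3, 3)) < 0.5).astype(np.float32)
        loss = soft_dice_loss(p, t)
        loss.backward()
        eps = 1e-3
        for idx in [(0, 0, 0, 0), (0, 0, 1, 2), (0, 0, 2, 2)]:
            p.data[idx] += eps
            up = soft_dice_loss(p.data, t)
            p.data[idx] -= 2 * eps
            dn = soft_dice_loss(p.data, t)
            p.data[idx] += eps
            assert p.grad[idx] == pytest.approx((up - dn) / (2 * eps), abs=2e-2)


class TestDsc:
    def test_identical_nonempty(self):
        m = np.eye(4, dtype=np.uint8)
        assert dsc(m, m) == 1.0

    def test_disjoint_nonempty(self):
        a = np.zeros((3, 3), dtype=np.uint8); a[0, 0] = 1
        b = np.zeros((3, 3), dtype=np.uint8); b[2, 2] = 1
        assert dsc(a, b) == 0.0

    def test_partial_overlap_two_thirds(self):
        a = np.zeros((3, 3), dtype=np.uint8); a[0, 0] = 1
        b = np.zeros((3, 3), dtype=np.uint8); b[0, 0] = 1; b[0, 1] = 1
        assert dsc(a, b) == pytest.approx(2 / 3)

    def test_both_empty_returns_one(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        assert dsc(z, z) == 1.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a = (r.random((6, 6)) < 0.3).astype(np.uint8)
        b = (r.random((6, 6)) < 0.3).astype(np.uint8)
        assert dsc(a, b) == dsc(b, a)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_dsc_equals_one_minus_soft_dice_in_limit(self, seed):
        """For binary masks with smooth -> 0, 1 - soft dice loss reduces to DSC."""
        r = np.random.default_rng(seed)
        a = (r.random((8, 8)) < 0.35).astype(np.float32)
        b = (r.random((8, 8)) < 0.35).astype(np.float32)
        if a.sum() + b.sum() == 0:
            return
        assert dsc(a.astype(np.uint8), b.astype(np.uint8)) == pytest.approx(
            1.0 - soft_dice_loss(a, b, smooth=1e-12), abs=1e-5
        )


class TestHausdorff:
    def test_identical_masks_zero(self):
        m = np.zeros((5, 5), dtype=np.uint8); m[1:3, 2] = 1
        assert hausdorff(m, m) == 0.0

    def test_three_four_five_triangle(self):
        a = np.zeros((6, 6), dtype=np.uint8); a[0, 0] = 1
        b = np.zeros((6, 6), dtype=np.uint8); b[3, 4] = 1
        assert hausdorff(a, b) == pytest.approx(5.0)
        assert brute_force_hausdorff(a, b) == pytest.approx(5.0)

    def test_spacing_scales_distance(self):
        a = np.zeros((4, 4), dtype=np.uint8); a[0, 0] = 1
        b = np.zeros((4, 4), dtype=np.uint8); b[0, 2] = 1
        d = hausdorff(BinaryMask(a, spacing=(1.0, 2.5)), BinaryMask(b, spacing=(1.0, 2.5)))
        assert d == pytest.approx(5.0)

    def test_empty_mask_is_nan(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        m = np.ones((4, 4), dtype=np.uint8)
        assert math.isnan(hausdorff(z, m))
        assert math.isnan(hausdorff(m, z))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        a = (r.random((15, 20)) < 0.1).astype(np.uint8)
        b = (r.random((15, 20)) < 0.1).astype(np.uint8)
        if a.sum() == 0 or b.sum() == 0:
            return
        assert hausdorff(a, b) == pytest.approx(brute_force_hausdorff(a, b))
        assert hausdorff(b, a) == pytest.approx(hausdorff(a, b))


class TestBinaryMask:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            BinaryMask(np.array([[0, 2]]))

    def test_rejects_bad_spacing(self):
        with pytest.raises(ValueError):
            BinaryMask(np.zeros((2, 2), dtype=np.uint8), spacing=(0.0, 1.0))


class TestEvaluateDataset:
    def test_perfect_predictions(self, rng):
        masks = [(rng.random((8, 8)) < 0.2).astype(np.uint8) for _ in range(4)]
        masks = [m if m.sum() else np.eye(8, dtype=np.uint8) for m in masks]
        report = evaluate_dataset(masks, masks)
        assert report.mean_dsc == 1.0
        assert report.mean_hd == 0.0
        assert report.n_excluded_from_hd == 0

    def test_empty_prediction_excluded_from_hd(self):
        gt = np.ones((4, 4), dtype=np.uint8)
        empty = np.zeros((4, 4), dtype=np.uint8)
        report = evaluate_dataset([empty, gt], [gt, gt])
        assert report.n_excluded_from_hd == 1
        assert report.per_case[0]["pred_empty"] is True

    def test_means_recomputed_from_per_case(self, rng):
        preds = [(rng.random((6, 6)) < 0.3).astype(np.uint8) for _ in range(5)]
        gts = [(rng.random((6, 6)) < 0.3).astype(np.uint8) for _ in range(5)]
        report = evaluate_dataset(preds, gts)
        assert report.mean_dsc == pytest.approx(
            np.mean([r["dsc"] for r in report.per_case])
        )
        hds = [r["hd_mm"] for r in report.per_case if not math.isnan(r["hd_mm"])]
        if hds:
            assert report.mean_hd == pytest.approx(np.mean(hds))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_dataset([np.zeros((2, 2))], [])

    def test_csv_export(self, tmp_path, rng):
        m = (rng.random((5, 5)) < 0.3).astype(np.uint8)
        report = evaluate_dataset([m], [m])
        out = tmp_path / "report.csv"
        report.to_csv(out)
        import pandas as pd
        df = pd.read_csv(out)
        assert list(df.columns[:3]) == ["case_id", "dsc", "hd_mm"]
        assert df.iloc[-1]["case_id"] == "mean"
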