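"""Metric suite vs independent brute-force oracles and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from hrunet.metrics import (accuracy, bland_altman, dice, evaluate_pair,
                            extract_boundary, iou, mhd, mhd_masks,
                            paired_ttest_bonferroni, plaque_area,
                            summarize_records)

rng = np.random.default_rng(5)

mask_pairs = st.tuples(
    hnp.arrays(np.uint8, (7, 7), elements=st.integers(0, 1)),
    hnp.arrays(np.uint8, (7, 7), elements=st.integers(0, 1)),
)


class TestOverlapMetrics:
    def test_identical_masks(self):
        m = rng.integers(0, 2, (9, 9)).astype(np.uint8)
        m[0, 0] = 1
        assert dice(m, m) == 1.0
        assert iou(m, m) == 1.0
        assert accuracy(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        b = np.zeros((6, 6), dtype=np.uint8)
        a[0, 0] = b[5, 5] = 1
        assert dice(a, b) == 0.0
        assert iou(a, b) == 0.0

    def test_half_overlap_example(self):
        # |L|=4, |S|=4, |L∩S|=2 on a 3x3 grid
        L = np.zeros((3, 3), dtype=np.uint8)
        S = np.zeros((3, 3), dtype=np.uint8)
        L.flat[[0, 1, 2, 3]] = 1
        S.flat[[2, 3, 4, 5]] = 1
        assert dice(L, S) == pytest.approx(0.5)
        assert iou(L, S) == pytest.approx(1 / 3)

    def test_complement_accuracy_zero(self):
        L = rng.integers(0, 2, (10, 10)).astype(np.uint8)
        assert accuracy(L, 1 - L) == 0.0

    def test_three_disagreements_on_100_pixels(self):
        L = np.zeros((10, 10), dtype=np.uint8)
        S = L.copy()
        S.flat[[3, 50, 99]] = 1
        assert accuracy(L, S) == pytest.approx(0.97)

    def test_empty_conventions(self):
        z = np.zeros((5, 5), dtype=np.uint8)
        nz = z.copy()
        nz[2, 2] = 1
        assert dice(z, z) == iou(z, z) == accuracy(z, z) == 1.0
        assert dice(z, nz) == iou(z, nz) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3)), np.zeros((4, 4)))

    @settings(derandomize=True, max_examples=200)
    @given(mask_pairs)
    def test_iou_dice_identity(self, pair):
        """IoU = Dice / (2 - Dice) on arbitrary mask pairs."""
        L, S = pair
        d = dice(L, S)
        assert iou(L, S) == pytest.approx(d / (2.0 - d), abs=1e-12)

    def test_invariant_under_joint_transform(self):
        L = rng.integers(0, 2, (8, 8)).astype(np.uint8)
        S = rng.integers(0, 2, (8, 8)).astype(np.uint8)
        for t in (lambda m: m[::-1], lambda m: m[:, ::-1], lambda m: m.T):
            assert dice(t(L), t(S)) == pytest.approx(dice(L, S))
            assert iou(t(L), t(S)) == pytest.approx(iou(L, S))


def brute_force_mhd(A, B):
    d_ab = np.mean([min(np.hypot(*(a - b)) for b in B) for a in A])
    d_ba = np.mean([min(np.hypot(*(a - b)) for a in A) for b in B])
    return max(d_ab, d_ba)


class TestBoundaryAndMHD:
    def test_single_pixel_boundary(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 3] = 1
        np.testing.assert_array_equal(extract_boundary(m), [[2, 3]])

    def test_filled_square_perimeter(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[1:4, 1:4] = 1
        b = extract_boundary(m)
        assert len(b) == 8
        assert [2, 2] not in b.tolist()  # center excluded

    def test_full_frame_boundary_ring(self):
        m = np.ones((6, 8), dtype=np.uint8)
        b = extract_boundary(m)
        assert len(b) == 2 * 6 + 2 * 8 - 4

    def test_empty_mask_empty_boundary(self):
        assert extract_boundary(np.zeros((4, 4))).shape == (0, 2)

    def test_identical_point_sets_zero(self):
        pts = np.argwhere(rng.random((6, 6)) > 0.5)
        assert mhd(pts, pts) == 0.0

    def test_shifted_block_example(self):
        A = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        B = A + [0, 2]
        assert mhd(A, B) == pytest.approx(1.5)
        assert brute_force_mhd(A, B) == pytest.approx(1.5)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_and_symmetric(self, seed):
        r = np.random.default_rng(seed)
        A = r.integers(0, 12, (r.integers(1, 8), 2))
        B = r.integers(0, 12, (r.integers(1, 8), 2))
        got = mhd(A, B)
        assert got == pytest.approx(brute_force_mhd(A, B), abs=1e-12)
        assert mhd(B, A) == pytest.approx(got)

    def test_long_parallel_segments_approach_shift(self):
        n = 400
        A = np.stack([np.zeros(n, dtype=int), np.arange(n)], axis=1)
        B = A + [3, 0]
        assert mhd(A, B) == pytest.approx(3.0, rel=1e-6)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mhd(np.empty((0, 2)), np.array([[0, 0]]))

    def test_mask_level_nan_on_empty(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        nz = z.copy()
        nz[1, 1] = 1
        with pytest.warns(UserWarning):
            assert np.isnan(mhd_masks(z, nz))


class TestAreasAndAgreement:
    def test_plaque_area_examples(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        assert plaque_area(m) == 0.0
        m.flat[:100] = 1
        assert plaque_area(m) == 100.0
        assert plaque_area(m, pixel_spacing=0.1) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            plaque_area(m, pixel_spacing=0.0)

    def test_bland_altman_identical(self):
        bias, loa, ape = bland_altman([5.0, 7.0, 9.0], [5.0, 7.0, 9.0])
        assert bias == 0.0 and loa == (0.0, 0.0)
        np.testing.assert_array_equal(ape, [0, 0, 0])

    def test_bland_altman_constant_offset(self):
        bias, (lo, hi), _ = bland_altman([10, 20, 30], [13, 23, 33])
        assert bias == pytest.approx(3.0)
        assert lo == hi == pytest.approx(3.0)

    def test_bland_altman_worked_example(self):
        bias, _, ape = bland_altman([10, 20, 30], [12, 19, 33])
        assert bias == pytest.approx(4 / 3)
        np.testing.assert_allclose(ape, [0.2, 0.05, 0.1])

    def test_zero_gt_area_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            _, _, ape = bland_altman([0.0, 10.0], [1.0, 11.0])
        assert len(ape) == 1

    def test_record_iou_le_dice_and_delta(self, rng):
        L = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        S = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        rec = evaluate_pair(L, S)
        assert rec.iou <= rec.dice
        assert rec.delta_tpa == rec.area_pred - rec.area_gt
        summ = summarize_records([rec, rec])
        assert summ["dice"][1] == pytest.approx(0.0)


class TestPairedTTest:
    def test_identical_samples_capped_at_one(self):
        a = [0.8, 0.81, 0.79, 0.82]
        assert paired_ttest_bonferroni(a, a, n_comparisons=7) == 1.0

    def test_single_comparison_matches_scipy(self):
        a = rng.normal(0.8, 0.05, 12)
        b = rng.normal(0.75, 0.05, 12)
        assert paired_ttest_bonferroni(a, b, 1) == \
            pytest.approx(stats.ttest_rel(a, b).pvalue)

    def test_hand_computed_example(self):
        """differences (1,1,1,1,-1): t = 1.5 on 4 df, p = 2*sf(1.5, 4)."""
        b = np.zeros(5)
        a = np.array([1.0, 1.0, 1.0, 1.0, -1.0])
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(1.5)
        want = 2 * stats.t.sf(abs(t), 4)
        assert paired_ttest_bonferroni(a, b, 1) == pytest.approx(want)

    def test_bonferroni_multiplies_and_caps(self):
        a = rng.normal(0.8, 0.05, 10)
        b = a + rng.normal(0.01, 0.02, 10)
        p1 = paired_ttest_bonferroni(a, b, 1)
        p3 = paired_ttest_bonferroni(a, b, 3)
        assert p3 == pytest.approx(min(1.0, 3 * p1))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest_bonferroni([1.0], [2.0])
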