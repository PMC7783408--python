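"""Metric correctness against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from lesionseg.errors import GeometryError, InvalidConfigError, UndefinedMetricError
from lesionseg.metrics import (
    boundary_voxels,
    compactness,
    dice,
    evaluate_set,
    hausdorff,
    paired_permutation_test,
    surface_area,
)
from tests.conftest import make_mask


def _random_mask_pair(seed, shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0)):
    rng = np.random.default_rng(seed)
    a = np.zeros(shape, dtype=bool)
    b = np.zeros(shape, dtype=bool)
    for m in (a, b):
        c = rng.integers(2, np.array(shape) - 2)
        r = rng.integers(1, 4)
        xx, yy, zz = np.mgrid[: shape[0], : shape[1], : shape[2]]
        m[(xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= r**2] = True
        extra = rng.random(shape) > 0.97
        m |= extra
    return make_mask(a, spacing), make_mask(b, spacing)


class TestDice:
    def test_identity(self, ball_mask):
        assert dice(ball_mask, ball_mask) == 1.0

    def test_disjoint(self):
        a = np.zeros((6, 6, 6)); a[:2] = 1
        b = np.zeros((6, 6, 6)); b[4:] = 1
        assert dice(make_mask(a), make_mask(b)) == 0.0

    def test_half_overlap_counts(self):
        a = np.zeros((4, 4, 4)); a[0, 0, :4] = 1
        b = np.zeros((4, 4, 4)); b[0, 0, 2:4] = 1; b[1, 1, :2] = 1
        # |A|=4, |B|=4, |A n B|=2 -> 0.5
        assert dice(make_mask(a), make_mask(b)) == 0.5

    def test_both_empty_is_one(self):
        e = make_mask(np.zeros((3, 3, 3)))
        assert dice(e, e) == 1.0

    def test_empty_vs_nonempty_is_zero(self, ball_mask):
        e = make_mask(np.zeros(ball_mask.shape))
        assert dice(e, ball_mask) == 0.0

    def test_geometry_mismatch(self, ball_mask):
        with pytest.raises(GeometryError):
            dice(ball_mask, make_mask(np.zeros((4, 4, 4))))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_set_counting(self, seed):
        a, b = _random_mask_pair(seed)
        am, bm = a.bool(), b.bool()
        expect = (
            1.0
            if not (am.any() or bm.any())
            else 2 * np.count_nonzero(am & bm) / (am.sum() + bm.sum())
        )
        assert dice(a, b) == pytest.approx(expect, abs=1e-12)
        assert dice(a, b) == dice(b, a)


class TestSurfaceAndCompactness:
    def test_single_voxel_isotropic(self):
        m = make_mask(np.eye(1).reshape(1, 1, 1))
        assert surface_area(m) == pytest.approx(6.0)
        assert compactness(m) == pytest.approx(6.0**1.5, rel=1e-12)

    def test_single_voxel_anisotropic(self):
        m = make_mask(np.ones((1, 1, 1)), spacing=(0.117, 0.117, 1.0))
        area = 2 * (0.117 * 1.0) + 2 * (0.117 * 1.0) + 2 * (0.117 * 0.117)
        assert surface_area(m) == pytest.approx(area, rel=1e-12)
        assert compactness(m) == pytest.approx(area**1.5 / (0.117 * 0.117 * 1.0), rel=1e-9)

    def test_cube_2x2x2(self):
        data = np.zeros((4, 4, 4)); data[1:3, 1:3, 1:3] = 1
        m = make_mask(data)
        assert surface_area(m) == pytest.approx(24.0)
        assert compactness(m) == pytest.approx(24.0**1.5 / 8.0)
        # cubes are scale-invariant under this measure
        assert compactness(m) == pytest.approx(6.0**1.5)

    def test_border_faces_count_as_exposed(self):
        m = make_mask(np.ones((2, 2, 2)))
        assert surface_area(m) == pytest.approx(24.0)

    def test_isotropic_spacing_invariance(self, ball_mask):
        vals = []
        for s in (0.25, 1.0, 3.7):
            m = make_mask(ball_mask.data, spacing=(s, s, s))
            vals.append(compactness(m))
        assert vals[0] == pytest.approx(vals[1], rel=1e-9)
        assert vals[1] == pytest.approx(vals[2], rel=1e-9)

    def test_digitized_ball_sits_at_face_counting_limit(self):
        """Face-counted areas overestimate curved surfaces by 3/2 in the
        fine-resolution limit, so a digitized ball's compactness converges to
        (6 pi)^1.5 / (4 pi / 3) ~ 19.55 — above the smooth-sphere minimum
        6 sqrt(pi) ~ 10.63 — rather than decreasing toward it."""
        limit = (6 * np.pi) ** 1.5 / (4 * np.pi / 3)
        vals = []
        for n, r in ((8, 3.2), (16, 6.4), (32, 12.8)):
            xx, yy, zz = np.mgrid[: 2 * n, : 2 * n, : 2 * n]
            ball = (xx - n + 0.5) ** 2 + (yy - n + 0.5) ** 2 + (zz - n + 0.5) ** 2 <= r**2
            vals.append(compactness(make_mask(ball)))
        assert all(v > 6 * np.sqrt(np.pi) for v in vals)
        # the finest digitization is within a few percent of the limit
        assert vals[2] == pytest.approx(limit, rel=0.05)

    def test_empty_mask_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compactness(make_mask(np.zeros((3, 3, 3))))


class TestBoundary:
    def test_single_voxel_is_its_own_boundary(self):
        m = make_mask(np.ones((1, 1, 1)))
        assert len(boundary_voxels(m)) == 1

    def test_cube_3x3x3_sheds_center(self):
        data = np.zeros((5, 5, 5)); data[1:4, 1:4, 1:4] = 1
        bv = boundary_voxels(make_mask(data))
        assert len(bv) == 26
        assert [2, 2, 2] not in bv.tolist()

    def test_thin_sheet_all_boundary(self):
        data = np.zeros((5, 5, 5)); data[:, :, 2] = 1
        assert len(boundary_voxels(make_mask(data))) == 25


class TestHausdorff:
    def test_identical_masks_zero(self, ball_mask):
        assert hausdorff(ball_mask, ball_mask) == 0.0

    def test_two_voxels_along_anisotropic_axis(self):
        a = np.zeros((8, 4, 4)); a[2, 1, 1] = 1
        b = np.zeros((8, 4, 4)); b[5, 1, 1] = 1
        sp = (0.117, 1.0, 1.0)
        assert hausdorff(make_mask(a, sp), make_mask(b, sp)) == pytest.approx(0.351, abs=1e-9)

    def test_empty_mask_undefined(self, ball_mask):
        with pytest.raises(UndefinedMetricError):
            hausdorff(ball_mask, make_mask(np.zeros(ball_mask.shape)))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_all_pairs_oracle(self, seed):
        """Distance-transform implementation equals the exhaustive
        O(|dA| * |dB|) boundary-distance computation."""
        spacing = (0.5, 0.7, 1.3) if seed % 2 else (1.0, 1.0, 1.0)
        a, b = _random_mask_pair(seed, spacing=spacing)
        ba = boundary_voxels(a) * np.array(spacing)
        bb = boundary_voxels(b) * np.array(spacing)
        dm = cdist(ba, bb)
        brute = max(dm.min(axis=1).max(), dm.min(axis=0).max())
        assert hausdorff(a, b) == pytest.approx(brute, abs=1e-9)
        assert hausdorff(a, b) == hausdorff(b, a)


class TestPairedPermutationTest:
    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert paired_permutation_test(x, x) == 1.0

    def test_three_unit_differences_exact(self):
        """n=3, all differences 1: only the all-plus and all-minus sign
        patterns reach |mean| = 1, so p = 2/8."""
        p = paired_permutation_test([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert p == pytest.approx(0.25)

    def test_exact_branch_consistent_with_sampled_branch(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 1.0, size=10)
        y = rng.normal(0.0, 1.0, size=10)
        p_exact = paired_permutation_test(x, y, iterations=2**10)
        p_mc = paired_permutation_test(x, y, iterations=20000, seed=1)
        assert p_exact == pytest.approx(p_mc, abs=0.02)

    def test_length_mismatch(self):
        with pytest.raises(InvalidConfigError):
            paired_permutation_test([1.0], [1.0, 2.0])

    def test_p_values_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            p = paired_permutation_test(x, y)
            assert 0.0 < p <= 1.0


class TestEvaluateSet:
    def test_perfect_predictions(self, ball_mask):
        report = evaluate_set([ball_mask] * 3, [ball_mask] * 3)
        assert report.aggregates.loc["dice", "mean"] == 1.0
        assert report.aggregates.loc["hausdorff_mm", "mean"] == 0.0

    def test_sham_rows_undefined_but_dice_one(self, ball_mask):
        empty = make_mask(np.zeros(ball_mask.shape))
        report = evaluate_set([ball_mask, empty], [ball_mask, empty])
        sham = report.per_scan.iloc[1]
        assert sham["dice"] == 1.0
        assert np.isnan(sham["compactness"]) and np.isnan(sham["hausdorff_mm"])
        # aggregates ignore undefined rows
        assert report.aggregates.loc["compactness", "n"] == 1

    def test_spurious_prediction_on_sham_scan_excluded_from_surface_metrics(
        self, ball_mask
    ):
        empty = make_mask(np.zeros(ball_mask.shape))
        report = evaluate_set([ball_mask], [empty])  # false positive on a sham
        row = report.per_scan.iloc[0]
        assert row["dice"] == 0.0
        assert np.isnan(row["compactness"]) and np.isnan(row["hausdorff_mm"])

    def test_aggregates_recomputable_from_rows(self, ball_mask):
        preds = []
        rng = np.random.default_rng(1)
        for _ in range(4):
            noisy = ball_mask.data.copy()
            flips = rng.random(noisy.shape) > 0.995
            noisy = np.logical_xor(noisy, flips)
            preds.append(make_mask(noisy))
        report = evaluate_set(preds, [ball_mask] * 4)
        for metric in ("dice", "compactness", "hausdorff_mm"):
            vals = report.per_scan[metric].dropna()
            assert report.aggregates.loc[metric, "mean"] == pytest.approx(vals.mean())
            assert report.aggregates.loc[metric, "std"] == pytest.approx(vals.std(ddof=0))

    def test_list_mismatch(self, ball_mask):
        with pytest.raises(InvalidConfigError):
            evaluate_set([ball_mask], [ball_mask, ball_mask])
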