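"""Tests for the metric suite, against brute-force loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petdeblur.anatomy import CODE, LabelVolume
from petdeblur.errors import ConfigurationError, GridMismatchError
from petdeblur.evaluation import (
    cov,
    evaluate_pair,
    make_rois,
    psnr,
    recovery_coefficient,
    relative_lesion_activity,
    relative_rla_error,
    rmse,
    ssim,
)

from oracles import (
    cov_loop,
    erode_ball_loop,
    psnr_loop,
    rc_loop,
    rmse_loop,
    ssim_loop,
)


def _pair_5cubed(seed):
    rng = np.random.default_rng(seed)
    x = rng.random((5, 5, 5)) * 10.0
    y = rng.random((5, 5, 5)) * 10.0
    mask = rng.random((5, 5, 5)) > 0.3
    mask[2, 2, 2] = True  # never empty
    return x, y, mask


class TestAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_metrics_match_loops(self, seed):
        x, y, mask = _pair_5cubed(seed)
        assert rmse(x, y, mask) == pytest.approx(rmse_loop(x, y, mask),
                                                 abs=1e-10)
        assert psnr(x, y, mask) == pytest.approx(psnr_loop(x, y, mask),
                                                 abs=1e-10)
        assert ssim(x, y, mask) == pytest.approx(ssim_loop(x, y, mask),
                                                 abs=1e-10)
        assert recovery_coefficient(y, x, mask) == pytest.approx(
            rc_loop(y, x, mask), abs=1e-10
        )
        assert cov(x, mask) == pytest.approx(cov_loop(x, mask), abs=1e-10)


class TestWorkedExamples:
    def test_psnr_two_voxel_example(self):
        # Max = 2, RMSE = 1 -> 20 log10(2) = 6.0206 dB.
        x = np.array([2.0, 2.0]).reshape(1, 1, 2)
        y = np.array([1.0, 3.0]).reshape(1, 1, 2)
        mask = np.ones_like(x, dtype=bool)
        assert psnr(x, y, mask) == pytest.approx(6.0206, abs=1e-4)

    def test_psnr_mse_denominator_variant(self):
        x = np.array([2.0, 2.0]).reshape(1, 1, 2)
        y = np.array([1.0, 3.0]).reshape(1, 1, 2)
        mask = np.ones_like(x, dtype=bool)
        # MSE = 1 as well here, so the printed-form value coincides.
        assert psnr(x, y, mask, denominator="mse") == pytest.approx(6.0206,
                                                                    abs=1e-4)

    def test_rmse_three_four_five(self):
        x = np.zeros((1, 1, 2))
        y = np.array([3.0, 4.0]).reshape(1, 1, 2)
        mask = np.ones_like(x, dtype=bool)
        assert rmse(x, y, mask) == pytest.approx(np.sqrt(12.5), abs=1e-10)
        assert rmse(x, y, mask) == pytest.approx(3.5355, abs=1e-4)

    def test_ssim_hand_computed(self):
        # mu_x = mu_y = 1, var_x = 1, var_y = 0, cov = 0
        # -> (2*1+0.01)(0+0.03) / ((1+1+0.01)(1+0+0.03)) = 0.0603/2.0703.
        x = np.array([0.0, 2.0]).reshape(1, 1, 2)
        y = np.array([1.0, 1.0]).reshape(1, 1, 2)
        mask = np.ones_like(x, dtype=bool)
        assert ssim(x, y, mask) == pytest.approx(0.0603 / 2.0703, abs=1e-10)

    def test_cov_population_convention(self):
        img = np.array([1.0, 3.0]).reshape(1, 1, 2)
        mask = np.ones_like(img, dtype=bool)
        assert cov(img, mask) == pytest.approx(50.0, abs=1e-10)

    def test_relative_rla_error_table_values(self):
        # Printed subgroup means are reproduced by (measured-truth)/truth.
        assert relative_rla_error(0.80, 0.3) == pytest.approx(1.667, abs=1e-3)
        assert relative_rla_error(0.86, 0.6) == pytest.approx(0.433, abs=1e-3)
        assert relative_rla_error(0.5, 0.5) == 0.0
        assert relative_rla_error(0.2, 0.4, absolute=True) == pytest.approx(0.5)


class TestMetricProperties:
    @given(st.integers(0, 1000), st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_psnr_and_cov_scale_invariant(self, seed, a):
        x, y, mask = _pair_5cubed(seed)
        assert psnr(a * x, a * y, mask) == pytest.approx(psnr(x, y, mask),
                                                         rel=1e-9)
        assert cov(a * x, mask) == pytest.approx(cov(x, mask), rel=1e-9)

    @given(st.integers(0, 1000), st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_rmse_homogeneous(self, seed, a):
        x, y, mask = _pair_5cubed(seed)
        assert rmse(a * x, a * y, mask) == pytest.approx(a * rmse(x, y, mask),
                                                         rel=1e-9)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_ssim_symmetric_and_bounded(self, seed):
        x, y, mask = _pair_5cubed(seed)
        s = ssim(x, y, mask)
        assert s == pytest.approx(ssim(y, x, mask), abs=1e-12)
        assert -1.0 <= s <= 1.0
        assert ssim(x, x, mask) == pytest.approx(1.0, abs=1e-12)

    def test_identity_cases(self):
        x, _, mask = _pair_5cubed(3)
        assert psnr(x, x, mask) == np.inf
        assert rmse(x, x, mask) == 0.0
        assert recovery_coefficient(x, x, mask) == 1.0
        assert relative_lesion_activity(x, x, mask) == 1.0

    def test_rc_linear_in_measured(self):
        x, _, mask = _pair_5cubed(4)
        assert recovery_coefficient(0.5 * x, x, mask) == pytest.approx(0.5)

    def test_empty_mask_raises(self):
        x, y, _ = _pair_5cubed(5)
        empty = np.zeros_like(x, dtype=bool)
        for fn in (lambda: rmse(x, y, empty), lambda: psnr(x, y, empty),
                   lambda: ssim(x, y, empty), lambda: cov(x, empty)):
            with pytest.raises(ValueError):
                fn()


class TestROIs:
    def test_erosion_radius_zero_is_identity(self, small_anatomy):
        rois = make_rois(small_anatomy, erosion_radius_vox=0)
        assert np.array_equal(rois.wm_mask_eroded, rois.wm_mask)

    def test_slab_erosion_matches_brute_force(self):
        # 13-voxel WM slab eroded by a radius-6 ball leaves a 1-voxel sheet.
        grid = np.zeros((20, 16, 16), dtype=np.int16)
        grid[3:16, 1:15, 1:15] = CODE["WM"]
        vol = LabelVolume(grid=grid, voxel_size_mm=(1.0, 1.0, 1.0),
                          anatomy_id="slab")
        rois = make_rois(vol, erosion_radius_vox=6)
        expected = erode_ball_loop(grid == CODE["WM"], 6)
        assert np.array_equal(rois.wm_mask_eroded, expected)
        core = np.argwhere(rois.wm_mask_eroded)
        assert core.size > 0
        assert set(core[:, 0].tolist()) == {9}

    def test_erosion_strictly_shrinks(self, small_anatomy):
        rois = make_rois(small_anatomy, erosion_radius_vox=2)
        assert rois.wm_mask_eroded.sum() < rois.wm_mask.sum()
        assert np.all(rois.wm_mask[rois.wm_mask_eroded])

    def test_brain_mask_composition(self, small_anatomy):
        rois = make_rois(small_anatomy, erosion_radius_vox=2)
        expected = np.isin(
            small_anatomy.grid,
            [CODE[n] for n in ("GM", "WM", "CEREB_GM", "CEREB_WM", "BG", "CSF")],
        )
        assert np.array_equal(rois.brain_mask, expected)

    def test_over_erosion_raises(self, small_anatomy):
        with pytest.raises(ConfigurationError, match="smaller radius"):
            make_rois(small_anatomy, erosion_radius_vox=30)


class TestEvaluatePair:
    def test_composite_identity(self, small_anatomy, small_phantom):
        from petdeblur.phantom import choose_lesion_center, insert_lesion
        from petdeblur.phantom import make_lesion_roi

        rois = make_rois(small_anatomy, erosion_radius_vox=3)
        c = choose_lesion_center(small_anatomy, "right_frontal",
                                 np.random.default_rng(8))
        roi = make_lesion_roi(small_anatomy, c, 612.0)
        lesioned = insert_lesion(small_phantom, roi, 0.3)
        report = evaluate_pair(
            lesioned.values,
            lesioned.values,
            rois,
            lesions=lesioned.lesions,
            unlesioned_test=small_phantom.values,
        )
        assert report.psnr_db == np.inf
        assert report.ssim == pytest.approx(1.0, abs=1e-12)
        assert report.rmse == 0.0
        assert report.rc["gm"] == pytest.approx(1.0, rel=1e-12)
        assert report.rc["wm"] == pytest.approx(1.0, rel=1e-12)
        row = report.lesions.iloc[0]
        assert row.rla == pytest.approx(0.3, rel=1e-12)
        assert row.relative_rla_error == pytest.approx(0.0, abs=1e-12)

    def test_one_rc_and_cov_per_roi(self, small_anatomy, small_phantom):
        rois = make_rois(small_anatomy, erosion_radius_vox=3)
        report = evaluate_pair(small_phantom.values,
                               0.9 * small_phantom.values, rois)
        assert set(report.rc) == {"gm", "wm"}
        assert set(report.cov_percent) == {"gm", "wm"}
        row = report.to_row()
        for col in ("psnr_db", "ssim", "rmse", "rc_gm", "rc_wm",
                    "cov_gm_pct", "cov_wm_pct"):
            assert col in row

    def test_swap_gives_reciprocal_rc_for_proportional_images(
        self, small_anatomy, small_phantom
    ):
        rois = make_rois(small_anatomy, erosion_radius_vox=3)
        a = evaluate_pair(small_phantom.values, 0.5 * small_phantom.values,
                          rois)
        b = evaluate_pair(0.5 * small_phantom.values, small_phantom.values,
                          rois)
        assert a.rc["gm"] == pytest.approx(1.0 / b.rc["gm"], rel=1e-9)

    def test_grid_mismatch_raises(self, small_anatomy, small_phantom):
        rois = make_rois(small_anatomy, erosion_radius_vox=3)
        with pytest.raises(GridMismatchError):
            evaluate_pair(small_phantom.values,
                          small_phantom.values[:-1], rois)

    def test_lesions_without_unlesioned_reference_raise(
        self, small_anatomy, small_phantom
    ):
        from petdeblur.phantom import choose_lesion_center, insert_lesion
        from petdeblur.phantom import make_lesion_roi

        rois = make_rois(small_anatomy, erosion_radius_vox=3)
        c = choose_lesion_center(small_anatomy, "right_frontal",
                                 np.random.default_rng(8))
        roi = make_lesion_roi(small_anatomy, c, 612.0)
        lesioned = insert_lesion(small_phantom, roi, 0.3)
        with pytest.raises(ConfigurationError, match="unlesioned"):
            evaluate_pair(lesioned.values, lesioned.values, rois,
                          lesions=lesioned.lesions)
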