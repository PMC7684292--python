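"""Redox pipeline: voxel ratio, segmentation, projection, Eq-style mean."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retinodex import phantom, redox3d
from retinodex.errors import AnalysisError, InputError
from retinodex.redox3d import (FluorescenceVolume, MaxProjection,
                               RedoxPipelineConfig, analyze_cryo_volumes,
                               compute_redox_volume, max_project, mean_redox,
                               oxidative_shift, run_redox_pipeline,
                               segment_shell)

from conftest import dice


def _vol(arr, channel):
    return FluorescenceVolume(voxels=np.asarray(arr, dtype=float),
                              channel=channel)


# ---------------------------------------------------------------------------
# voxelwise ratio
# ---------------------------------------------------------------------------

def test_voxel_ratio_is_direct_quotient():
    nadh = _vol(np.full((2, 2, 2), 92.0), "NADH")
    fad = _vol(np.full((2, 2, 2), 100.0), "FAD")
    rv = compute_redox_volume(nadh, fad, fad_floor=1.0)
    assert np.all(rv.valid_mask)
    assert np.allclose(rv.ratio, 0.92)


def test_equal_channels_give_unit_ratio():
    x = np.random.default_rng(0).uniform(10, 100, (3, 4, 5))
    rv = compute_redox_volume(_vol(x, "NADH"), _vol(x, "FAD"), fad_floor=1.0)
    assert np.allclose(rv.ratio, 1.0)


def test_fad_below_floor_excluded_without_error():
    fad = np.full((1, 2, 2), 100.0)
    fad[0, 0, 0] = 0.0
    rv = compute_redox_volume(_vol(np.full((1, 2, 2), 50.0), "NADH"),
                              _vol(fad, "FAD"), fad_floor=1.0)
    assert not rv.valid_mask[0, 0, 0]
    assert rv.ratio[0, 0, 0] == 0.0
    assert rv.valid_mask.sum() == 3


def test_ratio_input_errors():
    a = _vol(np.ones((2, 2, 2)), "NADH")
    b = _vol(np.ones((2, 2, 3)), "FAD")
    with pytest.raises(InputError):
        compute_redox_volume(a, b, 1.0)             # shape mismatch
    with pytest.raises(InputError):
        compute_redox_volume(_vol(np.ones((2, 2, 2)), "FAD"), a, 1.0)  # swapped
    with pytest.raises(InputError):
        compute_redox_volume(a, _vol(np.ones((2, 2, 2)), "FAD"), 0.0)  # floor


# ---------------------------------------------------------------------------
# shell segmentation
# ---------------------------------------------------------------------------

def test_noiseless_segmentation_recovers_truth_exactly(small_cryo_factory):
    nadh, fad, truth = small_cryo_factory(noise_cv=0.0)
    shell = segment_shell(nadh, fad)
    assert np.array_equal(shell.mask, truth.shell_mask)
    assert dice(shell.mask, truth.shell_mask) == 1.0
    assert shell.n_voxels == truth.shell_mask.sum()


def test_noisy_segmentation_dice_above_090(small_cryo_factory):
    nadh, fad, truth = small_cryo_factory(noise_cv=0.05)
    shell = segment_shell(nadh, fad)
    assert dice(shell.mask, truth.shell_mask) >= 0.9


def test_all_background_volume_is_analysis_error():
    rng = np.random.default_rng(4)
    flat = rng.normal(5.0, 0.1, (20, 20, 20)).clip(0)
    with pytest.raises(AnalysisError):
        segment_shell(_vol(flat, "NADH"), _vol(flat, "FAD"))
    const = np.full((10, 10, 10), 7.0)
    with pytest.raises(AnalysisError):
        segment_shell(_vol(const, "NADH"), _vol(const, "FAD"))


# ---------------------------------------------------------------------------
# max projection
# ---------------------------------------------------------------------------

def _shell_of(mask):
    return redox3d.ShellMask(mask=mask, n_voxels=int(mask.sum()))


def test_single_slice_projection_is_identity():
    ratio = np.array([[[0.5, 0.8], [0.2, 1.1]]])
    rv = redox3d.RedoxVolume(ratio=ratio, valid_mask=np.ones_like(ratio, bool))
    mp = max_project(rv, _shell_of(np.ones_like(ratio, bool)))
    assert np.array_equal(mp.image, ratio[0])


def test_projection_takes_column_maximum_and_excludes_empty_columns():
    ratio = np.zeros((3, 1, 2))
    ratio[:, 0, 0] = [0.5, 0.9, 0.7]
    mask = np.zeros((3, 1, 2), bool)
    mask[:, 0, 0] = True                   # second column has no shell voxel
    rv = redox3d.RedoxVolume(ratio=ratio, valid_mask=np.ones_like(mask))
    mp = max_project(rv, _shell_of(mask))
    assert mp.image[0, 0] == pytest.approx(0.9)
    assert not mp.foreground[0, 1]
    assert mp.image[0, 1] == 0.0


def test_constant_shell_projects_constant(small_cryo_factory):
    nadh, fad, truth = small_cryo_factory(noise_cv=0.0, nadh_mean=97.0)
    rv = compute_redox_volume(nadh, fad, fad_floor=1.0)
    mp = max_project(rv, _shell_of(truth.shell_mask))
    assert np.all(mp.image[mp.foreground] == pytest.approx(0.97))


# ---------------------------------------------------------------------------
# mean of the projection
# ---------------------------------------------------------------------------

def _mp(image, foreground):
    image = np.asarray(image, dtype=float)
    return MaxProjection(image=image, Nx=image.shape[1], Ny=image.shape[0],
                         foreground=np.asarray(foreground, bool))


def test_full_frame_mean_on_constant_image():
    mp = _mp([[1.0, 1.0], [1.0, 1.0]], np.ones((2, 2)))
    assert mean_redox(mp, "full_frame").mean_rr == pytest.approx(1.0)


def test_foreground_mean_on_constant_foreground():
    mp = _mp([[0.66, 0.0], [0.66, 0.0]], [[True, False], [True, False]])
    assert mean_redox(mp, "foreground").mean_rr == pytest.approx(0.66)


def test_scope_distinction_hand_arithmetic():
    mp = _mp([[2.0, 0.0], [0.0, 0.0]], [[True, False], [False, False]])
    assert mean_redox(mp, "full_frame").mean_rr == pytest.approx(0.5)
    assert mean_redox(mp, "foreground").mean_rr == pytest.approx(2.0)


def test_histogram_counts_sum_to_averaged_pixels():
    rng = np.random.default_rng(1)
    image = rng.uniform(0.2, 1.4, (13, 17))
    fg = rng.random((13, 17)) < 0.6
    image[~fg] = 0.0
    s_fg = mean_redox(_mp(image, fg), "foreground")
    assert s_fg.histogram[1].sum() == fg.sum()
    s_full = mean_redox(_mp(image, fg), "full_frame")
    assert s_full.histogram[1].sum() == image.size


def test_zero_foreground_is_analysis_error():
    with pytest.raises(AnalysisError):
        mean_redox(_mp(np.zeros((2, 2)), np.zeros((2, 2), bool)), "foreground")


def test_full_frame_mean_matches_brute_force_double_loop():
    """Frame-normalised mean must equal the literal double sum over pixels."""
    rng = np.random.default_rng(2)
    image = rng.uniform(0.0, 1.5, (9, 11))
    fg = image > 0.3
    image[~fg] = 0.0
    total = 0.0
    ny, nx = image.shape
    for i in range(ny):
        for j in range(nx):
            total += image[i, j]
    expected = total / (nx * ny)
    got = mean_redox(_mp(image, fg), "full_frame").mean_rr
    assert got == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# oxidative shift
# ---------------------------------------------------------------------------

def test_oxidative_shift_printed_means():
    assert oxidative_shift(0.66, 0.92) == pytest.approx(28.26, abs=0.005)
    assert oxidative_shift(0.5, 0.5) == 0.0
    assert oxidative_shift(0.97, 0.92) == pytest.approx(-5.43, abs=0.005)


@settings(deadline=None, derandomize=True)
@given(a=st.floats(0.01, 10.0), b=st.floats(0.01, 10.0))
def test_oxidative_shift_algebraic_identity(a, b):
    assert oxidative_shift(a, b) == pytest.approx(100.0 * (1.0 - a / b),
                                                  rel=1e-9)


def test_oxidative_shift_requires_positive_reference():
    with pytest.raises(InputError):
        oxidative_shift(0.5, 0.0)


# ---------------------------------------------------------------------------
# pipeline properties
# ---------------------------------------------------------------------------

def test_scale_invariance_of_mean_ratio(small_cryo_factory):
    nadh, fad, _ = small_cryo_factory()
    s1, _ = analyze_cryo_volumes(nadh, fad)
    nadh.voxels = nadh.voxels * 3.7
    fad.voxels = fad.voxels * 3.7
    s2, _ = analyze_cryo_volumes(nadh, fad)
    assert s2.mean_rr == pytest.approx(s1.mean_rr, rel=1e-6)
    assert s2.n_foreground == s1.n_foreground


def test_mip_bias_nonnegative_and_monotone_in_noise(small_cryo_factory):
    """Max projection of noisy voxels biases the mean upward, increasingly
    so with noise; the zero-noise phantom is recovered exactly."""
    means = []
    for cv in (0.0, 0.02, 0.05):
        nadh, fad, truth = small_cryo_factory(noise_cv=cv)
        summary, _ = analyze_cryo_volumes(nadh, fad)
        means.append(summary.mean_rr)
        assert summary.mean_rr >= truth.true_ratio - 1e-12
    assert means[0] == pytest.approx(0.92)
    assert means[0] <= means[1] <= means[2]


def test_pipeline_zero_noise_recovers_configured_ratio_exactly(
        small_cryo_factory, tmp_path):
    from retinodex import cli_io

    nadh, fad, truth = small_cryo_factory(noise_cv=0.0)
    np_path = cli_io.write_volume_tiff(tmp_path / "nadh.tif", nadh.voxels)
    fp_path = cli_io.write_volume_tiff(tmp_path / "fad.tif", fad.voxels)
    s1 = run_redox_pipeline(np_path, fp_path, out_dir=tmp_path / "out")
    assert s1.mean_rr == pytest.approx(truth.true_ratio, abs=1e-12)
    s2 = run_redox_pipeline(np_path, fp_path)
    assert s2.mean_rr == s1.mean_rr          # deterministic for fixed inputs
    assert (tmp_path / "out" / "redox_mip.tif").exists()
    assert (tmp_path / "out" / "summary.csv").exists()


def test_pipeline_errors_are_stage_tagged(tmp_path):
    from retinodex import cli_io

    rng = np.random.default_rng(0)
    flat = rng.normal(50.0, 1.0, (16, 16, 16)).clip(0)
    p1 = cli_io.write_volume_tiff(tmp_path / "a.tif", flat)
    p2 = cli_io.write_volume_tiff(tmp_path / "b.tif", flat)
    with pytest.raises(AnalysisError, match=r"\[segment_shell\]"):
        run_redox_pipeline(p1, p2)


def test_project_then_ratio_variant_close_to_truth(small_cryo_factory):
    nadh, fad, truth = small_cryo_factory()
    cfg = RedoxPipelineConfig(order="project_then_ratio")
    summary, _ = analyze_cryo_volumes(nadh, fad, cfg)
    assert summary.mean_rr == pytest.approx(truth.true_ratio, abs=0.05)
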