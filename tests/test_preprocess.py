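"""Equalization, Laplacian focus, orientation, inversion, and the pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from roentgan.phantom import CohortMix, PhantomParams, generate_cohort
from roentgan.preprocess import (
    LAPLACE_KERNEL,
    PreprocessConfig,
    detect_and_invert_negative,
    equalize_histogram,
    grid_search_threshold,
    laplace_focus,
    normalize_orientation,
    run_preprocess,
)


# -- histogram equalization ------------------------------------------------

def test_equalization_two_pixel_oracle():
    # cdf(0)=1, cdf(255)=2, cdf_min=1: h(0)=0, h(255)=255*(2-1)/(2-1)=255
    img = np.array([[0, 255]], dtype=np.uint8)
    np.testing.assert_array_equal(equalize_histogram(img),
                                  np.array([[0, 255]], dtype=np.uint8))


def test_equalization_hand_oracle_three_levels():
    # 2x2 image [10,10,20,30]: cdf(10)=2, cdf(20)=3, cdf(30)=4, cdf_min=2
    # h(10)=0, h(20)=255*1/2=127.5 -> 128 (half-up), h(30)=255
    img = np.array([[10, 10], [20, 30]], dtype=np.uint8)
    out = equalize_histogram(img)
    np.testing.assert_array_equal(out, np.array([[0, 0], [128, 255]]))


def test_equalization_constant_image_unchanged_with_warning():
    img = np.full((5, 5), 99, dtype=np.uint8)
    with pytest.warns(RuntimeWarning):
        out = equalize_histogram(img)
    np.testing.assert_array_equal(out, img)


@given(st.integers(0, 2 ** 32 - 1))
@settings(max_examples=50, deadline=None)
def test_equalization_monotone_and_full_range(seed):
    """For any image with >= 2 distinct values the mapping is monotone
    non-decreasing in the input value and the output spans exactly [0, 255]."""
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
    if img.min() == img.max():
        img[0, 0] = (int(img[0, 0]) + 1) % 256
    out = equalize_histogram(img)
    assert out.min() == 0 and out.max() == 255
    pairs = sorted(zip(img.ravel().tolist(), out.ravel().tolist()))
    assert all(b1 <= b2 for (_, b1), (_, b2) in zip(pairs, pairs[1:]))


# -- Laplacian focus metric ------------------------------------------------

def test_focus_variance_zero_on_constant_image():
    score = laplace_focus(np.full((9, 9), 120, dtype=np.uint8))
    assert score.variance == 0.0
    assert not score.is_focused and score.threshold == 350.0


def test_focus_single_pixel_hand_convolution_oracle():
    """5x5 zero image, centre pixel 1: the valid 3x3 response is
    [[0,-1,0],[-1,4,-1],[0,-1,0]]; Eqs. for mean and sum-of-squared
    deviations are evaluated by hand."""
    img = np.zeros((5, 5))
    img[2, 2] = 1.0
    score = laplace_focus(img)
    resp_abs = np.abs(np.array([[0, -1, 0], [-1, 4, -1], [0, -1, 0]], float))
    mu = resp_abs.mean()            # 8/9
    expected = ((resp_abs - mu) ** 2).sum()
    assert score.mean_abs == pytest.approx(mu)
    assert score.variance == pytest.approx(expected)


def test_focus_same_mode_uses_full_response():
    img = np.zeros((5, 5))
    img[2, 2] = 1.0
    valid = laplace_focus(img, mode="valid")
    same = laplace_focus(img, mode="same")
    # same-mode mean divides by 25 instead of 9
    assert same.mean_abs == pytest.approx(8.0 / 25.0)
    assert same.variance != valid.variance


def test_focus_rejects_images_smaller_than_kernel():
    with pytest.raises(ValueError):
        laplace_focus(np.zeros((2, 5)))


def test_focus_kernel_matches_discrete_laplacian():
    np.testing.assert_array_equal(LAPLACE_KERNEL,
                                  [[0, -1, 0], [-1, 4, -1], [0, -1, 0]])


def test_focus_translation_invariant_away_from_borders():
    rng = np.random.default_rng(0)
    patch = rng.integers(0, 256, (5, 5))
    a = np.zeros((21, 21))
    b = np.zeros((21, 21))
    a[4:9, 4:9] = patch
    b[10:15, 10:15] = patch
    assert laplace_focus(a).variance == pytest.approx(
        laplace_focus(b).variance, rel=1e-12)


# -- threshold grid search -------------------------------------------------

def test_grid_candidates_inclusive_arithmetic_sequence():
    out = grid_search_threshold([1.0, 2.0], (0, 525, 175))
    assert [t for t, _, _ in out] == [0.0, 175.0, 350.0, 525.0]


def test_grid_threshold_zero_counts_nothing_below():
    out = grid_search_threshold([0.0, 5.0, 10.0], (0, 10, 5))
    t0 = out[0]
    assert t0 == (0.0, 0, 3)


def test_grid_two_cluster_partition():
    scores = [100.0] * 10 + [700.0] * 10
    out = dict((t, (b, a)) for t, b, a in grid_search_threshold(scores))
    assert out[350.0] == (10, 10)


def test_grid_empty_scores_raise():
    with pytest.raises(ValueError):
        grid_search_threshold([])


# -- orientation and polarity ---------------------------------------------

def test_orientation_identity_and_involution():
    rng = np.random.default_rng(1)
    img = rng.integers(0, 256, (6, 7)).astype(np.uint8)
    np.testing.assert_array_equal(normalize_orientation(img, "left", "left"), img)
    flipped = normalize_orientation(img, "right", "left")
    np.testing.assert_array_equal(normalize_orientation(flipped, "right", "left"), img)
    assert not np.array_equal(flipped, img)


def test_negative_phantom_detected_and_restored():
    from roentgan.phantom import generate_phantom
    from dataclasses import replace
    base = PhantomParams(image_size=64, joint_gap=10.0, noise_sd=2.0, seed=3)
    pos = generate_phantom(base)
    neg = generate_phantom(replace(base, invert=True))
    restored, flagged = detect_and_invert_negative(neg)
    assert flagged
    assert np.abs(restored.astype(int) - pos.astype(int)).mean() < 10
    same, flagged2 = detect_and_invert_negative(pos)
    assert not flagged2
    np.testing.assert_array_equal(same, pos)


def test_negative_detection_is_an_involution():
    base = PhantomParams(image_size=64, joint_gap=10.0, noise_sd=0.0, seed=3)
    from roentgan.phantom import generate_phantom
    from dataclasses import replace
    neg = generate_phantom(replace(base, invert=True))
    once, f1 = detect_and_invert_negative(neg)
    twice, f2 = detect_and_invert_negative(once)
    assert f1 and not f2
    np.testing.assert_array_equal(twice, once)


# -- full pipeline ---------------------------------------------------------

@pytest.fixture(scope="module")
def cohort():
    base = PhantomParams(image_size=96, joint_gap=12.0, noise_sd=3.0)
    mix = CohortMix(right=0.3, inverted=0.2, artifact=0.15)
    manifest, images = generate_cohort(10, mix=mix, seed=2, base=base)
    return manifest, {p: im for p, im in zip(manifest["path"], images)}


def test_pipeline_conserves_rows_and_drops_artifacts(cohort):
    manifest, images = cohort
    cfg = PreprocessConfig(target_size=48, focus_threshold=350.0)
    res = run_preprocess(manifest, cfg, images=images)
    n_artifact = int(manifest["artifact"].sum())
    assert len(res.dropped) == n_artifact
    assert res.conserves(len(manifest))
    assert (res.dropped["status"] == "dropped_artifact").all()


def test_pipeline_outputs_uniform_target_size(cohort):
    manifest, images = cohort
    cfg = PreprocessConfig(target_size=48)
    res = run_preprocess(manifest, cfg, images=images)
    assert all(im.shape == (48, 48) for im in res.images.values())


def test_pipeline_accepts_all_sharp_phantoms(cohort):
    """Sharp noiseless-to-mildly-noisy phantoms all clear the default
    focus threshold after equalization."""
    manifest, images = cohort
    cfg = PreprocessConfig(target_size=48)
    res = run_preprocess(manifest, cfg, images=images)
    assert len(res.rejected) == 0
    assert len(res.accepted) == len(manifest) - len(res.dropped)


def test_pipeline_missing_files_raise():
    manifest = pd.DataFrame({
        "path": ["does_not_exist.png"], "class": ["A"], "laterality": ["left"],
        "inverted": [False], "blur_sigma": [0.0], "artifact": [False],
        "split": ["train"],
    })
    with pytest.raises(IOError):
        run_preprocess(manifest, PreprocessConfig(target_size=48))
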