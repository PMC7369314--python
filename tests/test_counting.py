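"""Cell-counting algorithm: each stage against oracles, plus end-to-end."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgquant.counting import (
    LUMINANCE_WEIGHTS,
    CountParams,
    binarize_and_filter,
    count_cells,
    estimate_background,
    pearson_r,
    subtract_and_enhance,
    to_grayscale,
)
from dgquant.synth import ImageSpec, generate_micrograph


def brute_force_opening(image: np.ndarray, radius: int) -> np.ndarray:
    """Shift-and-stack min-then-max filter over a disk: the opening oracle.

    Erosion pads with +inf (outside pixels never set the minimum), dilation
    with -inf, matching the standard boundary convention for grayscale
    morphology.
    """
    from skimage.morphology import disk

    fp = disk(radius).astype(bool)
    r = radius

    def sweep(img, reduce_fn, pad_val):
        p = np.pad(img.astype(float), r, mode="constant", constant_values=pad_val)
        stack = [
            p[r + dy : r + dy + img.shape[0], r + dx : r + dx + img.shape[1]]
            for dy in range(-r, r + 1)
            for dx in range(-r, r + 1)
            if fp[dy + r, dx + r]
        ]
        return reduce_fn(stack, axis=0)

    eroded = sweep(image, np.min, np.inf)
    return sweep(eroded, np.max, -np.inf)


# --- grayscale conversion ---------------------------------------------------


def test_grayscale_passthrough_and_black_rgb():
    gray = np.full((8, 8), 77.0)
    assert np.array_equal(to_grayscale(gray), gray)
    assert np.all(to_grayscale(np.zeros((8, 8, 3))) == 0)


def test_grayscale_pure_red_uses_documented_weight():
    rgb = np.zeros((4, 4, 3))
    rgb[..., 0] = 200
    expected = 200 * LUMINANCE_WEIGHTS[0]
    assert np.allclose(to_grayscale(rgb), expected)


def test_grayscale_rejects_odd_channel_counts():
    with pytest.raises(ValueError, match="shape"):
        to_grayscale(np.zeros((4, 4, 2)))


# --- background estimation --------------------------------------------------


def test_opening_is_identity_on_constant_image():
    img = np.full((64, 64), 50.0)
    assert np.array_equal(estimate_background(img, 10), img)


def test_opening_removes_subdisk_spot_and_keeps_plateau():
    img = np.full((128, 128), 50.0)
    yy, xx = np.mgrid[0:128, 0:128]
    img[(xx - 30) ** 2 + (yy - 30) ** 2 <= 5**2] = 200  # radius-5 spot
    bg = estimate_background(img, 10)
    assert np.all(bg == 50.0)  # spot removed entirely

    img[(xx - 90) ** 2 + (yy - 90) ** 2 <= 30**2] = 200  # radius-30 plateau
    bg = estimate_background(img, 10)
    assert bg[90, 90] == 200.0  # plateau survives the opening


def test_opening_never_exceeds_input():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, (48, 48)).astype(float)
    bg = estimate_background(img, 3)
    assert np.all(bg <= img)


def test_opening_radius_larger_than_image_rejected():
    with pytest.raises(ValueError, match="radius"):
        estimate_background(np.zeros((16, 16)), 10)


@pytest.mark.parametrize("case", range(20))
def test_opening_matches_brute_force_oracle(case):
    rng = np.random.default_rng(case)
    h, w = rng.integers(8, 65, size=2)
    radius = int(rng.integers(1, 4))
    img = rng.integers(0, 256, (h, w)).astype(float)
    assert np.array_equal(
        estimate_background(img, radius), brute_force_opening(img, radius)
    )


# --- subtraction / enhancement ---------------------------------------------


def test_flat_field_subtracts_to_zero():
    img = np.full((32, 32), 120.0)
    out = subtract_and_enhance(img, img, n_subtractions=3)
    assert np.all(out == 0)


def test_zero_background_is_a_subtraction_no_op_preserving_cells():
    image, roi, truth = generate_micrograph(
        ImageSpec(n_cells=10, seed=2, n_small_artifacts=0, n_large_artifacts=0)
    )
    gray = to_grayscale(image)
    enhanced = subtract_and_enhance(gray, np.zeros_like(gray), 2, roi)
    # the result is just the contrast-stretched grayscale: cell peaks saturate
    for x, y in truth.cell_centers:
        assert enhanced[int(round(y)), int(round(x))] == 255.0
    # and ordering of ROI pixel intensities is preserved (monotone stretch)
    flat_g, flat_e = gray[roi], enhanced[roi]
    order = np.argsort(flat_g)
    assert np.all(np.diff(flat_e[order]) >= 0)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shapes differ"):
        subtract_and_enhance(np.zeros((8, 8)), np.zeros((9, 9)))


# --- binarization and size filtering ---------------------------------------


def test_blank_enhanced_image_yields_no_components():
    roi = np.ones((32, 32), dtype=bool)
    labels = binarize_and_filter(np.zeros((32, 32)), roi, CountParams())
    assert labels.max() == 0


def test_two_separated_nominal_spots_yield_two_components():
    img = np.zeros((128, 128))
    yy, xx = np.mgrid[0:128, 0:128]
    for cx, cy in ((30, 30), (90, 90)):
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= 10**2] = 255  # area ~ pi*10^2
    labels = binarize_and_filter(img, np.ones_like(img, dtype=bool), CountParams())
    assert labels.max() == 2


def test_oversize_artifact_removed_by_filter():
    img = np.zeros((128, 128))
    yy, xx = np.mgrid[0:128, 0:128]
    img[(xx - 64) ** 2 + (yy - 64) ** 2 <= 40**2] = 255  # ~5000 px
    params = CountParams(size_max_px=1000)
    labels = binarize_and_filter(img, np.ones_like(img, dtype=bool), params)
    assert labels.max() == 0


def test_empty_roi_is_an_error():
    with pytest.raises(ValueError, match="ROI"):
        binarize_and_filter(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool), CountParams())


def test_labels_are_compact_and_areas_in_bounds(image_suite_50):
    image, roi, _ = image_suite_50[0]
    res = count_cells(image, roi)
    labels = np.unique(res.label_map)
    assert np.array_equal(labels, np.arange(res.n_cells + 1))
    for lab in range(1, res.n_cells + 1):
        area = int((res.label_map == lab).sum())
        assert res.params.size_min_px <= area <= res.params.size_max_px
    assert res.cell_area_px <= res.roi_area_px


# --- end-to-end -------------------------------------------------------------


def test_blank_field_counts_zero():
    spec = ImageSpec(
        n_cells=0, noise_sd=0.0, n_small_artifacts=0, n_large_artifacts=0
    )
    image, roi, _ = generate_micrograph(spec)
    assert count_cells(image, roi).n_cells == 0


def test_easy_instance_counted_exactly_across_pass_sweep():
    """20 separated cells with gradient and noise: exact at 3, 4 and 5 passes."""
    image, roi, truth = generate_micrograph(ImageSpec(n_cells=20, seed=7))
    counts = [
        count_cells(image, roi, CountParams(n_subtractions=k)).n_cells
        for k in (3, 4, 5)
    ]
    assert counts == [20, 20, 20]


def test_counts_invariant_to_global_intensity_offset():
    spec = ImageSpec(
        n_cells=15, seed=9, cell_peak_intensity=180.0, background_level=30.0,
        gradient_amplitude=20.0, noise_sd=5.0,
    )
    image, roi, _ = generate_micrograph(spec)
    base = count_cells(image, roi).n_cells
    shifted = np.clip(image.astype(float) + 20.0, 0, 255)
    assert count_cells(shifted, roi).n_cells == base


def test_tightening_size_bounds_never_increases_count(image_suite_50):
    image, roi, _ = image_suite_50[1]
    prev = count_cells(image, roi, CountParams(size_min_px=20)).n_cells
    for smin in (31, 60, 100):
        cur = count_cells(image, roi, CountParams(size_min_px=smin)).n_cells
        assert cur <= prev
        prev = cur
    prev = count_cells(image, roi, CountParams(size_max_px=943)).n_cells
    for smax in (500, 200, 80):
        cur = count_cells(image, roi, CountParams(size_max_px=smax)).n_cells
        assert cur <= prev
        prev = cur


# --- correlation ------------------------------------------------------------


def test_pearson_r_reference_values():
    assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)
    assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.981980506, abs=1e-6)


def test_pearson_r_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        pearson_r([1, 1, 1], [1, 2, 3])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-100, 100), min_size=3, max_size=20),
    st.floats(0.1, 10),
    st.floats(-50, 50),
)
def test_pearson_r_invariant_to_affine_rescale(xs, scale, shift):
    x = np.asarray(xs)
    if np.ptp(x) == 0:
        return
    y = np.linspace(0, 1, x.size) + 0.01 * x
    if np.ptp(y) == 0:
        return
    r1 = pearson_r(x, y)
    r2 = pearson_r(scale * x + shift, y)
    assert r1 == pytest.approx(r2, abs=1e-9)
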