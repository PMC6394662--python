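"""Channel selection, calibrated defaults, blur, background, threshold, ROI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from colonykit import preprocess
from colonykit.errors import ValidationError
from colonykit.plate_io import PlateImage
from colonykit.preprocess import GrayImage


def _plate(r, g, b):
    return PlateImage(pixels=np.stack([r, g, b], axis=-1).astype(np.uint8))


class TestSelectChannel:
    def test_argmax_of_channel_standard_deviations(self, rng):
        # constructed spreads: R ~5, G ~40, B ~12 gray levels
        shape = (60, 60)
        r = rng.normal(128, 5, shape).clip(0, 255)
        g = rng.normal(128, 40, shape).clip(0, 255)
        b = rng.normal(128, 12, shape).clip(0, 255)
        plate = _plate(r, g, b)
        stds = plate.pixels.reshape(-1, 3).std(axis=0)
        assert np.argmax(stds) == 1  # sanity: construction worked
        gray = preprocess.select_channel(plate)
        assert gray.channel_origin == "G"
        assert np.array_equal(gray.pixels, plate.pixels[:, :, 1])

    def test_blue_objects_on_white_pick_green(self, disk):
        # blue-stained colonies on a near-white dish: blue stays high inside
        # the colony, red drops some, green drops most → green has the
        # largest spread
        shape = (80, 80)
        m = disk(shape, (40, 40), 12)
        r = np.where(m, 170, 240)
        g = np.where(m, 110, 240)
        b = np.where(m, 200, 240)
        assert preprocess.select_channel(_plate(r, g, b)).channel_origin == "G"

    def test_identical_channels_tie_breaks_to_red(self, rng):
        c = rng.integers(0, 256, (30, 30))
        assert preprocess.select_channel(_plate(c, c, c)).channel_origin == "R"


class TestCalibratedDefaults:
    @pytest.mark.parametrize(
        "dpi,expected",
        [(600, 2.362), (1200, 4.792), (1e-9, 1.3)],  # limit dpi→0 → constant term
    )
    def test_default_sigma_polynomial(self, dpi, expected):
        assert preprocess.default_sigma(dpi) == pytest.approx(expected, abs=1e-6)

    def test_default_sigma_monotone_in_dpi(self):
        dpis = np.linspace(50, 2400, 60)
        sigmas = [preprocess.default_sigma(d) for d in dpis]
        assert np.all(np.diff(sigmas) > 0)

    @pytest.mark.parametrize("dpi,expected", [(1000, 25), (600, 15), (10, 1)])
    def test_default_rolling_radius(self, dpi, expected):
        assert preprocess.default_rolling_radius(dpi) == expected

    def test_rolling_radius_proportionality(self):
        for dpi in (200, 600, 1200):
            assert preprocess.default_rolling_radius(dpi) / dpi == pytest.approx(0.025)

    @pytest.mark.parametrize("func", [preprocess.default_sigma,
                                      preprocess.default_rolling_radius])
    def test_non_positive_dpi_rejected(self, func):
        with pytest.raises(ValidationError):
            func(0)
        with pytest.raises(ValidationError):
            func(-300)


class TestGaussianBlur:
    def test_sigma_zero_is_identity(self, rng):
        img = GrayImage(rng.uniform(0, 255, (20, 20)))
        assert np.array_equal(preprocess.gaussian_blur(img, 0).pixels, img.pixels)

    def test_constant_image_unchanged(self):
        img = GrayImage(np.full((30, 30), 42.0))
        out = preprocess.gaussian_blur(img, 3.0)
        assert np.allclose(out.pixels, 42.0)

    def test_impulse_response_matches_discrete_kernel(self):
        # oracle: build the truncated normalized Gaussian kernel explicitly
        sigma = 2.0
        img = np.zeros((81, 81))
        img[40, 40] = 1.0
        out = preprocess.gaussian_blur(GrayImage(img), sigma).pixels
        radius = int(4 * sigma + 0.5)  # scipy's default truncation
        k = np.arange(-radius, radius + 1)
        g1 = np.exp(-(k**2) / (2 * sigma**2))
        g1 /= g1.sum()
        kernel2d = np.outer(g1, g1)
        assert out[40, 40] == pytest.approx(kernel2d[radius, radius], rel=1e-10)
        assert np.allclose(out[40 - radius : 41 + radius, 40 - radius : 41 + radius],
                           kernel2d, atol=1e-12)

    def test_total_intensity_preserved(self, rng):
        img = GrayImage(rng.uniform(0, 255, (64, 48)))
        out = preprocess.gaussian_blur(img, 5.0)
        assert out.pixels.sum() == pytest.approx(img.pixels.sum(), rel=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            preprocess.gaussian_blur(GrayImage(np.zeros((5, 5))), -1)


def _paraboloid_opening_oracle(px, radius):
    """Brute-force min-plus opening with the full 2-D paraboloid."""
    h, w = px.shape
    span = float(np.ptp(px))
    reach = int(np.ceil(np.sqrt(2 * radius * (span + 1)))) if span else 0
    ys, xs = np.mgrid[-reach : reach + 1, -reach : reach + 1]
    z = (ys**2 + xs**2) / (2.0 * radius)
    pad = np.pad(px, reach, mode="edge")
    ero = np.empty_like(px)
    for i in range(h):
        for j in range(w):
            ero[i, j] = np.min(pad[i : i + 2 * reach + 1, j : j + 2 * reach + 1] + z)
    pad = np.pad(ero, reach, mode="edge")
    dil = np.empty_like(px)
    for i in range(h):
        for j in range(w):
            dil[i, j] = np.max(pad[i : i + 2 * reach + 1, j : j + 2 * reach + 1] - z)
    return np.minimum(dil, px)


class TestSubtractBackground:
    def test_flat_image_fully_removed(self):
        out = preprocess.subtract_background(GrayImage(np.full((40, 40), 123.0)), 7)
        assert np.allclose(out.pixels, 0.0)

    def test_gradient_plus_small_disk(self, disk):
        # smooth tilt is background; a disk smaller than the ball radius
        # must survive nearly intact and the tilt must vanish
        yy, xx = np.mgrid[0:100, 0:100]
        tilt = 0.06 * xx  # range 6 gray levels
        m = disk((100, 100), (50, 50), 4)
        img = tilt + np.where(m, 90.0, 0.0)
        out = preprocess.subtract_background(GrayImage(img), 10).pixels
        assert out[50, 50] >= 0.9 * 90.0
        assert out[~m].max() < 0.05 * 6.0

    def test_oversized_object_amplitude_reduced(self, disk):
        # documented failure mode: object diameter 3× the ball radius
        m = disk((120, 120), (60, 60), 15)
        img = np.where(m, 100.0, 0.0)
        out = preprocess.subtract_background(GrayImage(img), 10).pixels
        assert out.max() < img.max()

    def test_matches_bruteforce_paraboloid_opening(self, rng):
        px = rng.uniform(0, 50, (28, 28))
        px[10:16, 8:14] += 60  # a bright block
        bg_fast = preprocess.estimate_background(GrayImage(px), 3)
        bg_slow = _paraboloid_opening_oracle(px, 3)
        assert np.allclose(bg_fast, bg_slow, atol=1e-9)

    def test_output_bounded_by_input_and_zero(self, rng):
        px = rng.uniform(0, 255, (50, 50))
        out = preprocess.subtract_background(GrayImage(px), 6).pixels
        assert (out >= 0).all()
        assert (out <= px + 1e-9).all()

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValidationError):
            preprocess.subtract_background(GrayImage(np.zeros((5, 5))), 0.5)


class TestBinarize:
    def test_all_zero_image_empty_mask(self):
        mask = preprocess.binarize(GrayImage(np.zeros((10, 10))), 10)
        assert mask.dtype == bool
        assert not mask.any()

    def test_separable_two_level_image(self, rng):
        px = np.where(rng.uniform(size=(40, 40)) < 0.3, 255.0, 0.0)
        mask = preprocess.binarize(GrayImage(px), 128)
        assert np.array_equal(mask, px == 255)

    def test_isodata_on_bimodal_image(self):
        # oracle: the intermeans iteration on a two-delta histogram at
        # {30, 200} with equal weight converges to the midpoint 115
        px = np.concatenate([np.full(800, 30.0), np.full(800, 200.0)])
        img = GrayImage(px.reshape(40, 40))
        t = preprocess.resolve_threshold(img, "auto")
        assert 30 < t < 200
        assert t == pytest.approx(115.0, abs=2.0)
        mask = preprocess.binarize(img, "auto")
        assert np.array_equal(mask, img.pixels == 200.0)

    def test_monotone_in_threshold(self, rng):
        img = GrayImage(rng.uniform(0, 255, (30, 30)))
        masks = [preprocess.binarize(img, t) for t in (40, 120, 200)]
        assert (masks[1] <= masks[0]).all()
        assert (masks[2] <= masks[1]).all()

    def test_out_of_range_threshold_rejected(self):
        img = GrayImage(np.zeros((5, 5)))
        for bad in (-1, 256):
            with pytest.raises(ValidationError):
                preprocess.binarize(img, bad)

    def test_noise_floor_tracks_noise_not_signal(self, rng, disk):
        # residual-like image: mostly zeros + noise bumps; the floor must
        # clear the noise yet stay far below a colony-scale amplitude
        px = np.clip(rng.normal(0, 1.0, (200, 200)), 0, None)
        floor = preprocess.noise_floor_threshold(GrayImage(px))
        assert floor > np.percentile(px, 99)
        px[disk((200, 200), (100, 100), 10)] = 120.0
        floor_with_colony = preprocess.noise_floor_threshold(GrayImage(px))
        assert floor_with_colony < 60.0


class TestApplyRoi:
    def test_no_margin_keeps_inscribed_circle(self):
        mask = np.ones((50, 50), dtype=bool)
        out = preprocess.apply_roi(mask, (24.5, 24.5), 25.0, 0.0)
        yy, xx = np.mgrid[0:50, 0:50]
        inside = (yy - 24.5) ** 2 + (xx - 24.5) ** 2 <= 25.0**2
        assert np.array_equal(out, inside)

    def test_rim_blob_removed(self, disk):
        # a blob hugging the rim lies entirely beyond the 5% margin ROI
        h = w = 200
        center, dish_r = (99.5, 99.5), 100.0
        blob = disk((h, w), (99, 198), 3)  # innermost pixel at 0.955·radius
        assert blob.any()
        out = preprocess.apply_roi(blob, center, dish_r, 0.05)
        assert not out.any()

    def test_interior_mask_unchanged(self, disk):
        blob = disk((100, 100), (50, 60), 8)  # well inside 0.5·radius
        out = preprocess.apply_roi(blob, (49.5, 49.5), 50.0, 0.2)
        assert np.array_equal(out, blob)

    def test_output_subset_of_input(self, rng):
        mask = rng.uniform(size=(60, 60)) < 0.4
        out = preprocess.apply_roi(mask, (29.5, 29.5), 30.0, 0.1)
        assert not (out & ~mask).any()

    @pytest.mark.parametrize("margin", [-0.1, 1.0, 2.0])
    def test_invalid_margin_rejected(self, margin):
        with pytest.raises(ValidationError):
            preprocess.apply_roi(np.ones((5, 5), bool), (2, 2), 2.0, margin)


class TestPolarity:
    def test_dark_colonies_on_light_dish_inverted(self, disk):
        px = np.where(disk((60, 60), (30, 30), 8), 60.0, 220.0)
        out, inverted = preprocess.normalize_polarity(GrayImage(px))
        assert inverted
        assert out.pixels.max() == pytest.approx(195.0)

    def test_bright_objects_left_alone(self, disk):
        px = np.where(disk((60, 60), (30, 30), 8), 220.0, 30.0)
        out, inverted = preprocess.normalize_polarity(GrayImage(px))
        assert not inverted
        assert np.array_equal(out.pixels, px)


class TestPipelineParams:
    def test_validation(self):
        with pytest.raises(ValidationError):
            preprocess.PipelineParams(sigma=-1)
        with pytest.raises(ValidationError):
            preprocess.PipelineParams(rolling_radius=0)
        with pytest.raises(ValidationError):
            preprocess.PipelineParams(threshold=300)
        with pytest.raises(ValidationError):
            preprocess.PipelineParams(circ_min=0.9, circ_max=0.5)
        with pytest.raises(ValidationError):
            preprocess.PipelineParams(min_area=50, max_area=10)

    def test_min_area_scales_with_dpi_squared(self):
        p = preprocess.PipelineParams()
        assert p.resolved_min_area(600) == pytest.approx(20.0)
        assert p.resolved_min_area(300) == pytest.approx(5.0)
        assert p.resolved_min_area(1200) == pytest.approx(80.0)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=50, max_value=2400))
def test_rolling_radius_within_half_pixel_of_formula(dpi):
    assert abs(preprocess.default_rolling_radius(dpi) - 0.025 * dpi) <= 0.5
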