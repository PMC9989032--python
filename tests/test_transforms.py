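"""Hand-oracle and property tests for the atomic manipulation operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestaug import (
    ImageRecord,
    LabeledDataset,
    MixupSpec,
    NoiseSpec,
    PCASpec,
    RotationSpec,
    ScaleSpec,
    ValidationError,
    flip,
    gaussian_noise,
    hist_equalize,
    mixup,
    pca_augment,
    rotate,
    scale_in,
    scale_out,
)
from pestaug.transforms import _equalize_channel, select_k_components

from conftest import make_record


class TestRotate:
    def test_theta_zero_is_identity(self, record):
        assert np.array_equal(rotate(record, 0.0).pixels, record.pixels)

    def test_theta_360_equals_theta_zero(self, record):
        assert np.array_equal(rotate(record, 360.0).pixels,
                              rotate(record, 0.0).pixels)

    def test_90_degrees_is_the_hand_derived_permutation(self):
        # center rotation of the 2x2 raster [[a,b],[c,d]] by +90° maps the
        # four center-relative coordinates to [[b,d],[a,c]]
        px = np.zeros((2, 2, 3), dtype=np.uint8)
        px[..., 0] = [[1, 2], [3, 4]]
        px[..., 1] = px[..., 0]
        px[..., 2] = px[..., 0]
        rec = ImageRecord(px, "AJ", "x")
        out = rotate(rec, RotationSpec(theta=90.0, interpolation="nearest"))
        assert out.pixels[..., 0].tolist() == [[2, 4], [1, 3]]

    def test_rotate_then_back_at_right_angles_recovers_exactly(self, record):
        there = rotate(record, RotationSpec(theta=90.0, interpolation="nearest"))
        back = rotate(there, RotationSpec(theta=-90.0, interpolation="nearest"))
        assert np.array_equal(back.pixels, record.pixels)

    def test_nonfinite_angle_rejected(self, record):
        with pytest.raises(ValidationError):
            rotate(record, float("nan"))

    @pytest.mark.parametrize("theta", [13.7, 45.0, 222.2])
    def test_canvas_size_and_range_preserved(self, record, theta):
        out = rotate(record, theta)
        assert out.pixels.shape == record.pixels.shape
        assert out.pixels.dtype == np.uint8


class TestFlip:
    @pytest.mark.parametrize("axis", ["horizontal", "vertical"])
    def test_double_flip_is_the_identity(self, record, axis):
        assert np.array_equal(flip(flip(record, axis), axis).pixels, record.pixels)

    def test_horizontal_flip_reverses_a_row(self):
        px = np.zeros((1, 3, 3), dtype=np.uint8)
        px[0, :, 0] = [10, 20, 30]
        out = flip(ImageRecord(px, "AJ", "x"), "horizontal")
        assert out.pixels[0, :, 0].tolist() == [30, 20, 10]

    def test_unknown_axis_rejected(self, record):
        with pytest.raises(ValidationError):
            flip(record, "diagonal")


class TestGaussianNoise:
    def test_sigma_zero_is_identity(self, record):
        out = gaussian_noise(record, NoiseSpec(sigma=0.0), 0)
        assert np.array_equal(out.pixels, record.pixels)

    def test_moment_recovery_on_large_constant_image(self):
        rec = ImageRecord(np.full((100, 100, 3), 128, dtype=np.uint8), "AJ", "c")
        out = gaussian_noise(rec, NoiseSpec(sigma=10.0), 42)
        vals = out.pixels.astype(float)
        assert abs(vals.mean() - 128.0) < 0.5
        assert abs(vals.std() - 10.0) < 1.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            NoiseSpec(sigma=-1.0)

    @pytest.mark.parametrize("sigma", [10.0, 100.0, 1000.0])
    def test_outputs_stay_in_range(self, record, sigma):
        out = gaussian_noise(record, NoiseSpec(sigma=sigma), 1)
        assert out.pixels.dtype == np.uint8  # uint8 <=> in [0, 255]


class TestHistEqualize:
    def test_four_pixel_hand_oracle(self):
        # cdf_min = 1, N = 4: out = round((cdf - 1) / 3 * 255)
        ch = np.array([[52, 55], [61, 59]], dtype=np.uint8)
        assert _equalize_channel(ch).tolist() == [[0, 85], [255, 170]]

    def test_constant_channel_unchanged(self):
        rec = ImageRecord(np.full((6, 6, 3), 77, dtype=np.uint8), "AJ", "c")
        assert np.array_equal(hist_equalize(rec).pixels, rec.pixels)

    def test_uniform_channel_maps_near_identity(self):
        ch = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = _equalize_channel(ch)
        assert np.max(np.abs(out.astype(int) - ch.astype(int))) <= 1

    def test_mapping_is_monotone_per_channel(self, record):
        out = hist_equalize(record)
        for c in range(3):
            src = record.pixels[..., c].ravel()
            dst = out.pixels[..., c].ravel()
            order = np.argsort(src, kind="stable")
            assert np.all(np.diff(dst[order].astype(int))[np.diff(src[order]) > 0] >= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_near_idempotence(self, seed):
        rec = make_record(seed, h=32, w=32)
        once = hist_equalize(rec)
        twice = hist_equalize(once)
        assert np.max(np.abs(twice.pixels.astype(int) - once.pixels.astype(int))) <= 1


class TestScale:
    def test_zoom_one_is_identity(self, record):
        assert np.array_equal(scale_in(record, 1.0).pixels, record.pixels)
        assert np.array_equal(scale_out(record, 1.0).pixels, record.pixels)

    def test_zoom_two_uses_only_the_central_block(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, size=(4, 4, 3), dtype=np.uint8)
        rec = ImageRecord(px, "AJ", "x")
        out1 = scale_in(rec, 2.0)
        # corrupt every pixel outside the central 2x2: output must not change
        px2 = px.copy()
        mask = np.ones((4, 4), dtype=bool)
        mask[1:3, 1:3] = False
        px2[mask] = 0
        out2 = scale_in(ImageRecord(px2, "AJ", "x"), 2.0)
        assert np.array_equal(out1.pixels, out2.pixels)

    def test_zoom_below_one_rejected(self, record):
        with pytest.raises(ValidationError):
            scale_in(record, 0.5)

    def test_crop_below_one_pixel_rejected(self):
        rec = make_record(0, h=4, w=4)
        with pytest.raises(ValidationError):
            scale_in(rec, 10.0)

    @pytest.mark.parametrize("zoom", [1.25, 2.0, 3.0])
    def test_dimensions_preserved(self, record, zoom):
        assert scale_in(record, zoom).pixels.shape == record.pixels.shape
        assert scale_out(record, zoom).pixels.shape == record.pixels.shape


class TestMixup:
    def test_endpoints(self):
        a = ImageRecord(np.full((4, 4, 3), 100, dtype=np.uint8), "AJ", "a")
        b = ImageRecord(np.full((4, 4, 3), 200, dtype=np.uint8), "AJ", "b")
        assert np.array_equal(mixup(a, b, 1.0).pixels, a.pixels)
        assert np.array_equal(mixup(a, b, 0.0).pixels, b.pixels)

    def test_lambda_point_two_hand_oracle(self):
        a = ImageRecord(np.full((4, 4, 3), 100, dtype=np.uint8), "AJ", "a")
        b = ImageRecord(np.full((4, 4, 3), 200, dtype=np.uint8), "AJ", "b")
        assert np.all(mixup(a, b, 0.2).pixels == 180)  # 0.2*100 + 0.8*200

    def test_output_bounded_by_pixelwise_extremes(self):
        a, b = make_record(1, label="AJ", source_id="AJ/a"), make_record(2, label="AJ", source_id="AJ/b")
        out = mixup(a, b, 0.3).pixels.astype(int)
        lo = np.minimum(a.pixels, b.pixels).astype(int)
        hi = np.maximum(a.pixels, b.pixels).astype(int)
        assert np.all(out >= lo) and np.all(out <= hi)

    def test_cross_class_pairs_rejected(self):
        a = make_record(1, label="AJ")
        b = make_record(2, label="TR")
        with pytest.raises(ValidationError):
            mixup(a, b, 0.2)

    def test_self_pairing_rejected(self, record):
        with pytest.raises(ValidationError):
            mixup(record, record, 0.2)

    def test_partner_resized_when_dimensions_differ(self):
        a = make_record(1, h=16, w=16, label="AJ", source_id="AJ/a")
        b = make_record(2, h=32, w=24, label="AJ", source_id="AJ/b")
        assert mixup(a, b, 0.5).pixels.shape == (16, 16, 3)


class TestPcaAugment:
    def _gray_dataset(self, n=5, side=24):
        recs = []
        for i in range(n):
            gray = np.random.default_rng(i).integers(0, 256, (side, side, 1),
                                                     dtype=np.uint8)
            recs.append(ImageRecord(np.repeat(gray, 3, axis=2), "AJ", f"AJ/g{i}"))
        return LabeledDataset(recs, ["AJ"])

    def test_rank_one_channel_covariance_selects_one_component(self):
        # grayscale replicated x3: the 3x3 covariance has a single nonzero
        # eigenvalue, so cumulative explained variance hits 1 at k = 1
        assert select_k_components(self._gray_dataset(), PCASpec()) == 1

    def test_threshold_one_keeps_full_component_count(self):
        recs = [make_record(i, label="AJ", source_id=f"AJ/{i}") for i in range(5)]
        ds = LabeledDataset(recs, ["AJ"])
        assert select_k_components(ds, PCASpec(variance_threshold=1.0)) == 3

    def test_zero_alpha_is_identity(self):
        ds = self._gray_dataset()
        out = pca_augment(ds, PCASpec(alpha_sigma=0.0), master_seed=0)
        assert all(np.array_equal(a.pixels, b.pixels) for a, b in zip(out, ds))

    def test_degenerate_covariance_rejected(self):
        rec = ImageRecord(np.full((16, 16, 3), 99, dtype=np.uint8), "AJ", "c")
        ds = LabeledDataset([rec], ["AJ"])
        with pytest.raises(ValidationError, match="covariance"):
            pca_augment(ds, PCASpec(), master_seed=0)

    def test_labels_and_count_preserved(self):
        ds = self._gray_dataset()
        out = pca_augment(ds, PCASpec(), master_seed=3)
        assert len(out) == len(ds)
        assert [r.label for r in out] == [r.label for r in ds]

    def test_mean_perturbation_averages_out_over_seeds(self):
        ds = self._gray_dataset(n=3, side=16)
        src_mean = np.mean([r.pixels.astype(float) for r in ds])
        aug_means = []
        for seed in range(30):
            out = pca_augment(ds, PCASpec(), master_seed=seed)
            aug_means.append(np.mean([r.pixels.astype(float) for r in out]))
        assert abs(np.mean(aug_means) - src_mean) < 1.5


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10 ** 6),
       op=st.sampled_from(["rotate", "flip_h", "flip_v", "noise", "equalize",
                           "scale_in", "scale_out"]))
def test_every_operator_preserves_label_shape_and_range(seed, op):
    """The augmentation contract: transformed image, unchanged label."""
    rec = make_record(seed, h=17, w=23)
    rng = np.random.default_rng(seed)
    if op == "rotate":
        out = rotate(rec, float(rng.uniform(0, 360)))
    elif op == "flip_h":
        out = flip(rec, "horizontal")
    elif op == "flip_v":
        out = flip(rec, "vertical")
    elif op == "noise":
        out = gaussian_noise(rec, NoiseSpec(sigma=float(rng.uniform(0, 40))), seed)
    elif op == "equalize":
        out = hist_equalize(rec)
    elif op == "scale_in":
        out = scale_in(rec, float(rng.uniform(1.0, 3.0)))
    else:
        out = scale_out(rec, float(rng.uniform(1.0, 3.0)))
    assert out.label == rec.label
    assert out.pixels.shape == rec.pixels.shape
    assert out.pixels.dtype == np.uint8
    assert len(out.transform_chain) == len(rec.transform_chain) + 1
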