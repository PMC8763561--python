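"""Grayscale conversion, CLAHE and gamma correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselseg import preprocessing as pp
from vesselseg.io import FundusSample


def _uniform_rgb(value, shape=(10, 12)):
    return np.full((*shape, 3), value, dtype=np.uint8)


class TestRgbToGray:
    @pytest.mark.parametrize("value,expected", [(255, 255), (100, 100), (0, 0)])
    def test_achromatic_identity(self, value, expected):
        out = pp.rgb_to_gray(_uniform_rgb(value))
        assert out.dtype == np.uint8
        assert np.all(out == expected)

    def test_pure_red_luminance(self):
        # 0.299 * 255 = 76.245 -> 76 after round-half-away
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[..., 0] = 255
        assert np.all(pp.rgb_to_gray(img) == 76)

    def test_green_channel_method(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[..., 1] = 201
        assert np.all(pp.rgb_to_gray(img, method="green") == 201)

    def test_rejects_non_rgb(self):
        with pytest.raises(pp.DimensionError):
            pp.rgb_to_gray(np.zeros((4, 4), dtype=np.uint8))


class TestClahe:
    def test_constant_image_stays_constant(self):
        out = pp.clahe(np.full((64, 64), 77, dtype=np.uint8))
        assert len(np.unique(out)) == 1

    def test_output_range_and_shape(self, rng):
        img = rng.integers(0, 256, size=(100, 90)).astype(np.uint8)
        out = pp.clahe(img)
        assert out.shape == img.shape
        assert out.min() >= 0 and out.max() <= 255

    def test_contrast_increases_on_low_contrast_image(self, rng):
        # narrow-band image: equalization must spread intensities, as a
        # reference CLAHE implementation does on the same input
        from skimage.exposure import equalize_adapthist

        img = (120 + 8 * rng.standard_normal((128, 128))).clip(0, 255)
        img = img.astype(np.uint8)
        out = pp.clahe(img, clip=10.0, grid=(8, 8))
        assert out.std() > img.std()
        ref = equalize_adapthist(img, kernel_size=16, clip_limit=0.9)
        assert ref.std() * 255 > img.std()  # reference agrees directionally

    def test_parameter_validation(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        with pytest.raises(pp.ParameterError):
            pp.clahe(img, clip=0.0)
        with pytest.raises(pp.ParameterError):
            pp.clahe(img, grid=(0, 8))


class TestGamma:
    def test_gamma_one_is_bitexact_identity(self, rng):
        img = rng.integers(0, 256, size=(37, 23)).astype(np.uint8)
        assert np.array_equal(pp.gamma_correct(img, 1.0), img)

    @pytest.mark.parametrize("value,gamma,expected", [
        (64, 2.0, 16),   # (0.25)^2   = 0.0625 -> 255*0.0625 ~ 16
        (64, 0.5, 128),  # sqrt(0.25) = 0.5    -> 127.5 rounds to 128
    ])
    def test_power_law_values(self, value, gamma, expected):
        img = np.full((2, 2), value, dtype=np.uint8)
        out = pp.gamma_correct(img, gamma)
        assert np.all(out == expected)

    @given(gamma=st.floats(0.1, 4.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_for_any_gamma(self, gamma):
        levels = np.arange(256, dtype=np.uint8)
        out = pp.gamma_correct(levels, gamma)
        assert np.all(np.diff(out.astype(int)) >= 0)

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(pp.ParameterError):
            pp.gamma_correct(np.zeros((2, 2), dtype=np.uint8), 0.0)


class TestPreprocessChain:
    @pytest.mark.parametrize("dims", [(584, 565), (999, 960)])
    def test_shape_preserved_at_dataset_geometry(self, rng, dims):
        img = rng.integers(0, 256, size=(*dims, 3)).astype(np.uint8)
        out = pp.preprocess(FundusSample(image=img, identifier="x"))
        assert out.shape == dims
        assert 0.0 <= out.min() and out.max() <= 1.0

    def test_default_gamma_is_identity_in_chain(self, rng):
        img = rng.integers(0, 256, size=(64, 48, 3)).astype(np.uint8)
        cfg = pp.PreprocessConfig(normalize=False)
        out = pp.preprocess(img, cfg)
        expected = pp.clahe(pp.rgb_to_gray(img), cfg.clahe_clip, cfg.clahe_grid)
        assert np.array_equal(out, expected)

    def test_invalid_config_rejected(self):
        with pytest.raises(pp.ParameterError):
            pp.preprocess(np.zeros((8, 8, 3), np.uint8),
                          pp.PreprocessConfig(clahe_clip=-1))
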