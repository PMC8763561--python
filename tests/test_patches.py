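"""Augmentation factors, patch sampling, grid slicing and stitching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselseg import patches as pm
from vesselseg.io import FundusSample


def _toy_samples(n, dims=(72, 70), seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        img = rng.integers(0, 256, size=(*dims, 3)).astype(np.uint8)
        lab = (rng.random(dims) > 0.9).astype(np.uint8)
        out.append(FundusSample(image=img, label=lab, identifier=f"s{i}"))
    return out


class TestAugment:
    def test_drive_factor_reaches_1200(self):
        out = pm.augment(_toy_samples(20), pm.DRIVE_AUGMENT)
        assert len(out) == 1200

    def test_chase_factor_reaches_1680(self):
        out = pm.augment(_toy_samples(14), pm.CHASE_AUGMENT)
        assert len(out) == 1680

    def test_identity_augmentation(self):
        samples = _toy_samples(3)
        out = pm.augment(samples, pm.AugmentConfig(rotation_angles=(0,),
                                                   mirror=False))
        assert len(out) == 3
        for a, b in zip(samples, out):
            assert np.array_equal(a.image, b.image)
            assert np.array_equal(a.label, b.label)

    def test_masks_stay_binary_and_congruent(self):
        out = pm.augment(_toy_samples(1), pm.AugmentConfig((0, 33, 90), True))
        assert len(out) == 6
        for s in out:
            assert set(np.unique(s.label)) <= {0, 1}

    def test_empty_angles_rejected(self):
        with pytest.raises(pm.ParameterError):
            pm.augment(_toy_samples(1), pm.AugmentConfig(rotation_angles=()))


def _gray_samples(n, dims=(48, 48), seed=0):
    rng = np.random.default_rng(seed)
    return [FundusSample(image=rng.random(dims),
                         label=(rng.random(dims) > 0.9).astype(np.uint8),
                         identifier=f"g{i}")
            for i in range(n)]


class TestSamplePatches:
    def test_exact_patch_quota(self):
        recs = pm.sample_patches(_gray_samples(5), per_image=7, size=16, seed=0)
        assert len(recs) == 35

    def test_seeded_determinism(self):
        a = pm.sample_patches(_gray_samples(3), per_image=5, size=16, seed=9)
        b = pm.sample_patches(_gray_samples(3), per_image=5, size=16, seed=9)
        assert [r.top_left for r in a] == [r.top_left for r in b]

    def test_containment_and_label_congruence(self):
        samples = _gray_samples(2)
        recs = pm.sample_patches(samples, per_image=20, size=16, seed=3)
        for r in recs:
            row, col = r.top_left
            src = samples[r.source_index]
            assert 0 <= row <= 48 - 16 and 0 <= col <= 48 - 16
            assert np.array_equal(
                r.label_patch, src.label[row:row + 16, col:col + 16])
            assert np.array_equal(
                r.image_patch, src.image[row:row + 16, col:col + 16])

    def test_oversized_patch_rejected(self):
        with pytest.raises(pm.DimensionError):
            pm.sample_patches(_gray_samples(1), per_image=1, size=64, seed=0)


class TestSplit:
    def test_80_20_sizes(self):
        recs = pm.sample_patches(_gray_samples(5), per_image=2, size=16, seed=0)
        train, val = pm.split_train_val(recs, 0.8, seed=0)
        assert (len(train), len(val)) == (8, 2)

    def test_conservation_as_multiset(self):
        recs = pm.sample_patches(_gray_samples(3), per_image=4, size=16, seed=0)
        train, val = pm.split_train_val(recs, 0.7, seed=1)
        assert sorted(id(r) for r in train + val) == sorted(id(r) for r in recs)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(pm.ParameterError):
            pm.split_train_val([], 1.0, seed=0)


class TestGridAndStitch:
    @pytest.mark.parametrize("dims,expected_tiles,padded", [
        ((584, 565), 90, (640, 576)),   # DRIVE geometry: 10 x 9
        ((999, 960), 240, (1024, 960)),  # CHASE geometry: 16 x 15
        ((64, 64), 1, (64, 64)),
    ])
    def test_tile_counts(self, dims, expected_tiles, padded):
        tiles, grid = pm.grid_patches(np.zeros(dims), size=64)
        assert len(tiles) == expected_tiles
        assert grid.padded_dims == padded

    @given(h=st.integers(5, 90), w=st.integers(5, 90))
    @settings(max_examples=30, deadline=None)
    def test_roundtrip_identity(self, h, w):
        rng = np.random.default_rng(h * 100 + w)
        img = rng.random((h, w))
        tiles, grid = pm.grid_patches(img, size=16)
        np.testing.assert_array_equal(pm.stitch(tiles, grid), img)

    def test_stitch_matches_direct_indexing(self, rng):
        img = rng.random((40, 56))
        tiles, grid = pm.grid_patches(img, size=16)
        out = pm.stitch([t * 0.5 for t in tiles], grid)
        np.testing.assert_allclose(out, img * 0.5)

    def test_mismatched_patch_count_rejected(self):
        tiles, grid = pm.grid_patches(np.zeros((32, 32)), size=16)
        with pytest.raises(pm.DimensionError):
            pm.stitch(tiles[:-1], grid)
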