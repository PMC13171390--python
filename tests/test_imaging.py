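"""I/O, preprocessing, boundary derivation and the patch representation."""

import imageio.v3 as iio
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from sgbnet import imaging
from sgbnet.imaging import (
    FundusSample,
    PreprocessConfig,
    ValidationError,
    derive_boundary,
    grid_patches,
    load_sample,
    preprocess,
    sample_train_patches,
    stitch,
)


def make_sample(h=64, w=64, seed=0):
    rng = np.random.default_rng(seed)
    vessel = (rng.random((h, w)) < 0.1).astype(np.uint8)
    return FundusSample(
        image=rng.random((h, w)).astype(np.float32),
        vessel_mask=vessel,
        fov_mask=np.ones((h, w), np.uint8),
        boundary_mask=derive_boundary(vessel),
    )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoadSample:
    def test_uint8_scaling_and_mask_binarisation(self, tmp_path):
        img = np.zeros((20, 30), np.uint8)
        img[0, 0] = 255
        img[5, 5] = 128
        mask = np.zeros((20, 30), np.uint8)
        mask[2:7, 3:9] = 255
        iio.imwrite(tmp_path / "img.png", img)
        iio.imwrite(tmp_path / "mask.png", mask)
        s = load_sample(tmp_path / "img.png", tmp_path / "mask.png")
        assert s.image[0, 0] == pytest.approx(1.0)
        assert s.image[5, 5] == pytest.approx(128 / 255)
        assert set(np.unique(s.vessel_mask)) == {0, 1}
        assert s.vessel_mask.sum() == 30
        # absent FOV defaults to all ones; shapes agree across planes
        assert s.fov_mask.all() and s.fov_mask.shape == (20, 30)
        assert s.boundary_mask.shape == (20, 30)

    def test_shape_mismatch_rejected(self, tmp_path):
        iio.imwrite(tmp_path / "img.png", np.zeros((20, 30), np.uint8))
        iio.imwrite(tmp_path / "mask.png", np.zeros((20, 31), np.uint8))
        with pytest.raises(ValidationError):
            load_sample(tmp_path / "img.png", tmp_path / "mask.png")

    def test_unreadable_file_names_path(self, tmp_path):
        with pytest.raises(IOError, match="nope.png"):
            load_sample(tmp_path / "nope.png", tmp_path / "nope.png")

    def test_manifest_roundtrip(self, tmp_path):
        from sgbnet import synthetic
        samples = [synthetic.generate(
            synthetic.SynthParams(seed=s, size=(64, 64), n_trees=2,
                                  branch_depth=3, n_lesions=0))
            for s in (1, 2)]
        manifest = synthetic.write_samples(samples, tmp_path)
        loaded = imaging.read_manifest(manifest, source="synthetic")
        assert len(loaded) == 2
        np.testing.assert_array_equal(loaded[0].vessel_mask,
                                      samples[0].vessel_mask)
        np.testing.assert_array_equal(loaded[1].fov_mask, samples[1].fov_mask)


# ---------------------------------------------------------------------------
# boundary derivation
# ---------------------------------------------------------------------------

class TestDeriveBoundary:
    def test_empty_and_full_masks(self):
        assert derive_boundary(np.zeros((8, 8), np.uint8)).sum() == 0
        full = derive_boundary(np.ones((8, 8), np.uint8))
        # all-ones mask: boundary is the 1-px outer frame (erosion treats
        # off-grid pixels as background)
        assert full[1:-1, 1:-1].sum() == 0
        assert full.sum() == 28

    def test_centred_square(self):
        mask = np.zeros((5, 5), np.uint8)
        mask[1:4, 1:4] = 1
        ring = derive_boundary(mask, thickness=1)
        # brute-force oracle: dilation fills the whole 5x5 grid, erosion
        # keeps only the centre pixel
        assert ring.sum() == 24
        assert ring[2, 2] == 0

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            derive_boundary(np.full((4, 4), 2))

    def test_matches_brute_force_oracle(self, rng):
        se = np.ones((3, 3), bool)
        for _ in range(25):
            mask = (rng.random((16, 16)) < 0.3).astype(np.uint8)
            expected = np.zeros_like(mask)
            padded = np.pad(mask, 1)
            for i in range(16):
                for j in range(16):
                    neigh = padded[i:i + 3, j:j + 3]
                    dil = (neigh & se).any()
                    ero = bool((neigh | ~se).all())
                    expected[i, j] = 1 if (dil and not ero) else 0
            np.testing.assert_array_equal(derive_boundary(mask), expected)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_identity_chain(self):
        s = make_sample()
        out = preprocess(s, PreprocessConfig(hist_eq="none", gamma=1.0))
        np.testing.assert_allclose(out.image, s.image, atol=1e-6)

    def test_gamma_closed_form(self):
        s = make_sample()
        s.image[:] = 0.25
        out = preprocess(s, PreprocessConfig(hist_eq="none", gamma=0.5))
        np.testing.assert_allclose(out.image, 0.5, atol=1e-6)

    def test_constant_image_stays_constant_under_global_eq(self):
        s = make_sample()
        s.image[:] = 0.3
        out = preprocess(s, PreprocessConfig(hist_eq="global", gamma=1.0))
        assert np.ptp(out.image) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("hist_eq", ["none", "global", "clahe"])
    def test_range_and_masks_preserved(self, hist_eq):
        s = make_sample(96, 96, seed=3)
        out = preprocess(s, PreprocessConfig(hist_eq=hist_eq))
        assert out.image.min() >= 0.0 and out.image.max() <= 1.0
        assert out.image.ndim == 2
        np.testing.assert_array_equal(out.vessel_mask, s.vessel_mask)
        np.testing.assert_array_equal(out.fov_mask, s.fov_mask)

    def test_rgb_collapses_to_single_channel(self):
        rng = np.random.default_rng(0)
        s = make_sample()
        rgb = FundusSample(image=rng.random((64, 64, 3)).astype(np.float32),
                           vessel_mask=s.vessel_mask, fov_mask=s.fov_mask,
                           boundary_mask=s.boundary_mask)
        assert preprocess(rgb).image.ndim == 2

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValidationError):
            PreprocessConfig(gamma=0.0)


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

class TestTrainPatches:
    def test_count_size_and_determinism(self):
        s = make_sample(96, 96)
        a = sample_train_patches(s, n=17, size=32, rng_seed=5)
        b = sample_train_patches(s, n=17, size=32, rng_seed=5)
        assert len(a.image) == 17
        assert a.image.patches.shape == (17, 32, 32)
        np.testing.assert_array_equal(a.image.patches, b.image.patches)
        np.testing.assert_array_equal(a.vessel.coords, b.vessel.coords)

    def test_different_seeds_differ(self):
        s = make_sample(96, 96)
        a = sample_train_patches(s, n=20, size=32, rng_seed=1)
        b = sample_train_patches(s, n=20, size=32, rng_seed=2)
        assert not np.array_equal(a.image.patches, b.image.patches)

    def test_single_window_when_patch_equals_image(self):
        s = make_sample(64, 64)
        tp = sample_train_patches(s, n=8, size=64, rng_seed=0)
        for k in range(8):
            np.testing.assert_array_equal(tp.image.patches[k], s.image)
            np.testing.assert_array_equal(tp.vessel.patches[k], s.vessel_mask)

    def test_labels_follow_image_coords(self):
        s = make_sample(96, 96, seed=9)
        tp = sample_train_patches(s, n=5, size=32, rng_seed=3)
        for k, (r, c) in enumerate(tp.image.coords):
            np.testing.assert_array_equal(
                tp.vessel.patches[k], s.vessel_mask[r:r + 32, c:c + 32])

    def test_invalid_args_rejected(self):
        s = make_sample()
        with pytest.raises(ValidationError):
            sample_train_patches(s, n=0, size=32, rng_seed=0)
        with pytest.raises(ValidationError):
            sample_train_patches(s, n=4, size=-1, rng_seed=0)


class TestGridPatches:
    @pytest.mark.parametrize("hw,expected_n,expected_pad", [
        ((128, 128), 4, (128, 128)),
        ((96, 96), 1, (96, 96)),
        ((100, 100), 4, (128, 128)),
    ])
    def test_patch_counts_and_padding(self, hw, expected_n, expected_pad):
        img = np.random.default_rng(0).random(hw).astype(np.float32)
        ps = grid_patches(img, size=96, stride=32)
        assert len(ps) == expected_n
        assert ps.padded_shape == expected_pad

    def test_single_patch_is_the_image(self):
        img = np.random.default_rng(1).random((96, 96)).astype(np.float32)
        ps = grid_patches(img, size=96, stride=32)
        np.testing.assert_array_equal(ps.patches[0], img)

    def test_invalid_stride_rejected(self):
        img = np.zeros((96, 96))
        with pytest.raises(ValidationError):
            grid_patches(img, size=96, stride=0)


class TestStitch:
    def test_constant_patches_average_to_constant(self):
        img = np.zeros((100, 130), np.float32)
        ps = grid_patches(img, 96, 32)
        ps.patches = np.full_like(ps.patches, 0.7)
        np.testing.assert_allclose(stitch(ps), 0.7, atol=1e-6)

    def test_roundtrip_identity_fixed_sizes(self):
        rng = np.random.default_rng(3)
        for hw in [(96, 96), (128, 97), (211, 144)]:
            img = rng.random(hw).astype(np.float32)
            np.testing.assert_allclose(stitch(grid_patches(img)), img,
                                       atol=1e-6)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(h=st.integers(96, 300), w=st.integers(96, 300),
           seed=st.integers(0, 10_000))
    def test_roundtrip_identity_property(self, h, w, seed):
        img = np.random.default_rng(seed).random((h, w)).astype(np.float32)
        np.testing.assert_allclose(stitch(grid_patches(img)), img, atol=1e-6)


class TestOverlay:
    def test_blend_and_shape_checks(self):
        s = make_sample(32, 32, seed=1)
        out = imaging.overlay(s.image, s.vessel_mask, alpha=1.0)
        assert out.shape == (32, 32, 3)
        sel = s.vessel_mask.astype(bool)
        np.testing.assert_allclose(out[sel, 0], 1.0, atol=1e-6)
        with pytest.raises(ValidationError):
            imaging.overlay(s.image, s.vessel_mask[:16])
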