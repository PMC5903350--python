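"""Grayscale reconstruction, h-dome enhancement and Otsu segmentation,
each cross-checked against an independent brute-force oracle."""

import numpy as np
import pytest

from angiomvd import EnhanceParams, VolumeImage, enhance_microvessels, grayscale_reconstruct, otsu_threshold
from angiomvd.errors import DegenerateInputError

from .oracles import exhaustive_otsu, iterative_reconstruction


def vol(data):
    return VolumeImage(np.asarray(data, dtype=float))


class TestGrayscaleReconstruction:
    def test_fixed_point_marker_equals_mask(self, rng):
        data = rng.random((6, 6, 6)) * 50
        out = grayscale_reconstruct(vol(data), vol(data))
        np.testing.assert_array_equal(out.data, data)

    def test_marker_above_mask_rejected(self):
        with pytest.raises(ValueError):
            grayscale_reconstruct(vol(np.ones((3, 3, 3))), vol(np.zeros((3, 3, 3))))

    def test_matches_iterative_geodesic_dilation_oracle(self, rng):
        """On random 8^3 marker/mask pairs the result equals the fixed point
        of iterated geodesic dilation."""
        for _ in range(25):
            mask = rng.random((8, 8, 8)) * 100
            marker = mask - rng.random((8, 8, 8)) * 30
            out = grayscale_reconstruct(vol(marker), vol(mask))
            expected = iterative_reconstruction(marker, mask)
            np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_constant_image_minus_h(self):
        """A flat mask has no regional maxima: reconstruction of mask - h
        returns mask - h everywhere... except nothing to flood, so output
        stays at the marker level."""
        mask = np.full((5, 5, 5), 40.0)
        out = grayscale_reconstruct(vol(mask - 7), vol(mask))
        np.testing.assert_allclose(out.data, mask - 7)

    def test_two_plateaus_with_clipped_marker(self):
        """Plateaus of 10 and 20 over a moat of 0, marker clipped at 12:
        the 20-plateau floods back only to 12; verified against the oracle."""
        mask = np.zeros((3, 9, 9))
        mask[1, 2:4, 2:4] = 10.0
        mask[1, 6:8, 6:8] = 20.0
        marker = np.minimum(mask, 12.0)
        out = grayscale_reconstruct(vol(marker), vol(mask))
        expected = iterative_reconstruction(marker, mask)
        np.testing.assert_allclose(out.data, expected)
        assert out.data[1, 6:8, 6:8].max() == 12.0
        assert out.data[1, 2:4, 2:4].max() == 10.0

    def test_sandwich_and_idempotence(self, rng):
        mask = rng.random((8, 8, 8)) * 60
        marker = mask - rng.random((8, 8, 8)) * 20
        out = grayscale_reconstruct(vol(marker), vol(mask)).data
        assert np.all(out >= marker - 1e-12) and np.all(out <= mask + 1e-12)
        again = grayscale_reconstruct(vol(out), vol(mask)).data
        np.testing.assert_allclose(again, out)

    def test_monotone_in_both_arguments(self, rng):
        mask = rng.random((8, 8, 8)) * 50
        marker = mask - rng.random((8, 8, 8)) * 20
        out1 = grayscale_reconstruct(vol(marker), vol(mask)).data
        out2 = grayscale_reconstruct(vol(marker - 5), vol(mask)).data
        assert np.all(out2 <= out1 + 1e-12)


class TestEnhancement:
    def test_zero_weight_is_identity(self, rng):
        data = rng.random((6, 6, 6)) * 100
        out = enhance_microvessels(vol(data), EnhanceParams(combine_weight=0.0))
        np.testing.assert_array_equal(out.data, data)

    def test_hdome_single_bright_voxel(self):
        """An isolated spike of 100 over background 0 with h=10, w=1: its
        h-dome is exactly h (the marker reconstructs the spike to 100-h), so
        the enhanced value is 100 + 10 = 110 — checked against the iterative
        oracle."""
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 100.0
        params = EnhanceParams(mode="hdome", marker_offset=10.0, combine_weight=1.0)
        out = enhance_microvessels(vol(data), params)
        recon_oracle = iterative_reconstruction(data - 10.0, data)
        expected = data + (data - recon_oracle)
        np.testing.assert_allclose(out.data, expected)
        assert out.data[3, 3, 3] == pytest.approx(110.0)
        assert np.allclose(np.delete(out.data.ravel(), 3 * 49 + 3 * 7 + 3), 0.0)

    def test_tophat_mode_leaves_large_slab_unchanged(self):
        """Opening-by-reconstruction keeps structures wider than the ball, so
        a thick bright slab is untouched while a thin spike is boosted."""
        data = np.zeros((9, 11, 11))
        data[2:7, 2:9, 2:9] = 100.0  # slab much wider than radius-1 ball
        data[8, 5, 5] = 60.0  # isolated spike
        params = EnhanceParams(mode="tophat_by_reconstruction", structuring_radius=1, combine_weight=1.0)
        out = enhance_microvessels(vol(data), params)
        np.testing.assert_allclose(out.data[4, 5, 5], 100.0)
        assert out.data[8, 5, 5] == pytest.approx(120.0)

    def test_shape_preserved(self, small_phantom):
        out = enhance_microvessels(small_phantom.volume)
        assert out.shape == small_phantom.volume.shape

    def test_enhancement_enables_single_threshold_segmentation(self):
        """A dim radius-1 microvessel next to a bright radius-6 vessel in
        soft tissue: global Otsu alone keeps only the bright vessel, but
        after reconstruction-based enhancement one threshold captures both
        tubes — the reason an enhancement stage precedes thresholding."""
        from scipy import ndimage

        rng = np.random.default_rng(7)
        shape = (40, 60, 60)
        data = 40.0 + 5.0 * rng.normal(size=shape)  # soft tissue
        thin = np.zeros(shape, bool)
        thin[5:35, 15, 15] = True
        thin = ndimage.distance_transform_edt(~thin) <= 1
        thick = np.zeros(shape, bool)
        thick[5:35, 40, 40] = True
        thick = ndimage.distance_transform_edt(~thick) <= 6
        data[thin] = 62.0
        data[thick] = 100.0
        v = vol(data)
        _, mask_raw = otsu_threshold(v)
        assert mask_raw.mask[thick].mean() > 0.99
        assert mask_raw.mask[thin].mean() < 0.01  # dim tube lost
        params = EnhanceParams(
            mode="tophat_by_reconstruction", structuring_radius=2, combine_weight=1.0
        )
        enhanced = enhance_microvessels(v, params)
        _, mask_enh = otsu_threshold(enhanced)
        assert mask_enh.mask[thick].mean() > 0.99
        assert mask_enh.mask[thin].mean() > 0.99  # dim tube recovered
        assert mask_enh.mask[~(thin | thick)].mean() < 0.01


class TestOtsu:
    def test_bimodal_two_valued(self, rng):
        data = np.zeros((10, 10, 10))
        idx = rng.choice(1000, 100, replace=False)
        data.ravel()[idx] = 100.0
        thr, mask = otsu_threshold(vol(data))
        assert 0 < thr < 100
        assert mask.mask.mean() == pytest.approx(0.1)

    def test_matches_exhaustive_search_oracle(self, rng):
        for _ in range(50):
            data = rng.integers(0, 256, size=(6, 6, 6)).astype(float)
            thr, _ = otsu_threshold(vol(data))
            assert thr == pytest.approx(exhaustive_otsu(data), abs=1e-9)

    def test_shift_equivariance(self, rng):
        data = rng.integers(0, 200, size=(8, 8, 8)).astype(float)
        thr0, mask0 = otsu_threshold(vol(data))
        thr1, mask1 = otsu_threshold(vol(data + 37.0))
        assert thr1 == pytest.approx(thr0 + 37.0)
        np.testing.assert_array_equal(mask0.mask, mask1.mask)

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(vol(np.full((4, 4, 4), 3.0)))

    def test_agrees_with_skimage(self, rng):
        from skimage.filters import threshold_otsu

        data = rng.integers(0, 256, size=(12, 12, 12)).astype(float)
        thr, _ = otsu_threshold(vol(data))
        ref = threshold_otsu(data, nbins=256)
        # conventions differ by at most one bin width
        bin_w = (data.max() - data.min()) / 256
        assert abs(thr - ref) <= bin_w + 1e-9
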