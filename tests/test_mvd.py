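"""The centerline density statistic and its rival metrics."""

import numpy as np
import pytest
from scipy import ndimage

from angiomvd import (
    VOI,
    BinaryVolume,
    Skeleton,
    mvd_centerline_3d,
    mvd_slice_count_2d,
    mvd_vessel_count_3d,
    mvd_voxel_fraction_3d,
    prune_skeleton,
    skeletonize_3d,
)
from angiomvd.errors import BoundsError, FrameError


def skel_from(coords, shape):
    m = np.zeros(shape, bool)
    for c in coords:
        m[c] = True
    return Skeleton(mask=m)


VOI100 = VOI((0, 0, 0), (100, 100, 100))


class TestCenterline3D:
    def test_empty_skeleton(self):
        res = mvd_centerline_3d(skel_from([], (100, 100, 100)), VOI100)
        assert res.value == 0.0

    def test_single_spanning_line(self):
        """A straight 100-voxel centerline through a 100^3 VOI gives exactly
        1.0e-4 — one centerline voxel per 10^4 VOI voxels."""
        sk = skel_from([(i, 50, 50) for i in range(100)], (100, 100, 100))
        res = mvd_centerline_3d(sk, VOI100)
        assert res.numerator == 100
        assert res.denominator == 10**6
        assert res.value == pytest.approx(1.0e-4)
        assert res.value_e4 == pytest.approx(1.0)

    def test_matches_membership_oracle(self, small_phantom):
        """Counting truth-centerline voxels inside the VOI by explicit
        per-voxel membership equals the vectorized numerator."""
        sk = Skeleton(mask=small_phantom.centerline_mask)
        voi = VOI((10, 20, 5), (60, 60, 60))
        res = mvd_centerline_3d(sk, voi)
        brute = sum(
            1
            for (z, y, x) in small_phantom.centerline_truth
            if 10 <= z < 70 and 20 <= y < 80 and 5 <= x < 65
        )
        assert res.numerator == brute
        assert res.value == brute / 60**3

    def test_additive_over_partition(self, small_phantom):
        """Centerline counts over VOIs partitioning a region sum to the
        count over the whole region."""
        sk = Skeleton(mask=small_phantom.centerline_mask)
        whole = mvd_centerline_3d(sk, VOI((0, 0, 0), (100, 100, 100)))
        parts = 0
        for oz in (0, 50):
            for oy in (0, 50):
                for ox in (0, 50):
                    parts += mvd_centerline_3d(sk, VOI((oz, oy, ox), (50, 50, 50))).numerator
        assert parts == whole.numerator

    def test_frame_mismatch(self):
        sk = skel_from([(1, 1, 1)], (50, 50, 50))
        with pytest.raises(FrameError):
            mvd_centerline_3d(sk, VOI100)


class TestSliceCount2D:
    def test_three_disks(self):
        mask = np.zeros((20, 100, 100), bool)
        for cy, cx in [(20, 20), (50, 70), (80, 30)]:
            yy, xx = np.mgrid[:100, :100]
            mask[9] |= ((yy - cy) ** 2 + (xx - cx) ** 2) <= 25
        res = mvd_slice_count_2d(BinaryVolume(mask), VOI((0, 0, 0), (20, 100, 100)), 10)
        assert res.numerator == 3
        assert res.denominator == 10**4

    def test_background_slice_is_zero(self):
        mask = np.zeros((20, 50, 50), bool)
        mask[0] = True
        res = mvd_slice_count_2d(BinaryVolume(mask), VOI((0, 0, 0), (20, 50, 50)), 20)
        assert res.numerator == 0

    def test_slice_index_is_one_based(self):
        mask = np.zeros((10, 30, 30), bool)
        mask[4, 10:13, 10:13] = True  # array index 4 == slice number 5
        voi = VOI((0, 0, 0), (10, 30, 30))
        assert mvd_slice_count_2d(BinaryVolume(mask), voi, 5).numerator == 1
        assert mvd_slice_count_2d(BinaryVolume(mask), voi, 4).numerator == 0
        with pytest.raises(BoundsError):
            mvd_slice_count_2d(BinaryVolume(mask), voi, 11)
        with pytest.raises(BoundsError):
            mvd_slice_count_2d(BinaryVolume(mask), voi, 0)

    def test_slice_sensitivity_on_depth_varying_phantom(self):
        """Two slices of a depth-varying network give different counts —
        the documented weakness of the single-slice protocol."""
        from angiomvd.synthvessel import generate_tree, spec_from_preset

        ph = generate_tree(spec_from_preset("tumor_heterogeneous", seed=4))
        voi = VOI((30, 30, 30), (100, 100, 100))
        m = BinaryVolume(ph.mask_truth.mask)
        c10 = mvd_slice_count_2d(m, voi, 10).numerator
        c50 = mvd_slice_count_2d(m, voi, 50).numerator
        assert c10 != c50


class TestVesselCount3D:
    def test_connected_tree_counts_one_regardless_of_shape(self, small_phantom):
        """Any single connected tree scores 1: the vessel-count metric cannot
        separate trees differing in curvature or caliber."""
        mask = small_phantom.mask_truth
        sub = mask.mask[:100, :100, :100]
        n_true = ndimage.label(sub, structure=ndimage.generate_binary_structure(3, 3))[1]
        res = mvd_vessel_count_3d(mask, VOI100)
        assert res.numerator == n_true

    def test_gaps_increase_count(self):
        from angiomvd.synthvessel import VesselTreeSpec, generate_tree

        spec = VesselTreeSpec(
            domain_shape=(100, 60, 60),
            n_roots=1,
            branching_prob=0.0,
            segment_length_voxels=(80.0, 80.0),
            radius_root_voxels=2.0,
            tortuosity=0.0,
            gap_count=3,
            gap_length_voxels=(6.0, 6.0),
            noise_sd=0.0,
            seed=9,
            max_generations=0,
        )
        ph = generate_tree(spec)
        res = mvd_vessel_count_3d(ph.mask_truth, VOI((0, 0, 0), (100, 60, 60)))
        assert res.numerator == 4

    def test_empty(self):
        res = mvd_vessel_count_3d(BinaryVolume(np.zeros((100,) * 3, bool)), VOI100)
        assert res.numerator == 0


class TestVoxelFraction3D:
    def test_diameter_sensitivity(self):
        """Doubling tube radius roughly quadruples the voxel fraction —
        caliber dominates this metric."""
        from .conftest import straight_tube_mask

        f = []
        for r in (3, 6):
            mask, _ = straight_tube_mask(shape=(60, 40, 40), axis_len=50, radius=r)
            res = mvd_voxel_fraction_3d(BinaryVolume(mask), VOI((0, 0, 0), (60, 40, 40)))
            f.append(res.value)
        assert f[1] / f[0] == pytest.approx(4.0, rel=0.25)

    def test_bounds(self):
        full = BinaryVolume(np.ones((10, 10, 10), bool))
        voi = VOI((0, 0, 0), (10, 10, 10))
        assert mvd_voxel_fraction_3d(full, voi).value == 1.0
        empty = BinaryVolume(np.zeros((10, 10, 10), bool))
        assert mvd_voxel_fraction_3d(empty, voi).value == 0.0


def test_three_way_radius_contrast(small_phantom):
    """Scaling tube radius x1/x2/x3 on a fixed tree: centerline MVD moves
    < 10%, voxel-fraction MVD moves > 200%, vessel-count MVD not at all."""
    from angiomvd.synthvessel import VesselTreeSpec, generate_tree

    cl, vf, vc = [], [], []
    voi = VOI((0, 0, 0), (150, 150, 150))
    for r in (1.5, 3.0, 4.5):
        spec = VesselTreeSpec(
            domain_shape=(150, 150, 150),
            n_roots=1,
            branching_prob=1.0,
            segment_length_voxels=(45.0, 55.0),
            radius_root_voxels=r,
            radius_decay=1.0,
            tortuosity=0.0,
            noise_sd=0.0,
            seed=3,
            max_generations=2,
            boundary_margin=10,
        )
        ph = generate_tree(spec)
        sk = prune_skeleton(skeletonize_3d(ph.mask_truth), min_branch_len=5)
        cl.append(mvd_centerline_3d(sk, voi).value)
        vf.append(mvd_voxel_fraction_3d(ph.mask_truth, voi).value)
        vc.append(mvd_vessel_count_3d(ph.mask_truth, voi).numerator)
    assert max(cl) / min(cl) < 1.10
    assert max(vf) / min(vf) > 3.0
    assert vc[0] == vc[1] == vc[2] == 1
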