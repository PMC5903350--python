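"""Parallel thinning, skeleton graph decomposition and pruning."""

import numpy as np
import pytest

from angiomvd import BinaryVolume, Skeleton, prune_skeleton, skeleton_to_graph, skeletonize_3d
from angiomvd.errors import ParameterError

from .conftest import straight_tube_mask
from .oracles import count_components, is_simple_point, random_blob_mask


def skeleton_from_coords(coords, shape):
    m = np.zeros(shape, bool)
    for c in coords:
        m[c] = True
    return Skeleton(mask=m)


def y_skeleton(arm_a=20, arm_b=20, arm_c=3):
    """Three arms meeting at one junction; arm lengths exclude the junction
    voxel. Arm directions are chosen so the first voxels of different arms
    are not mutually 26-adjacent (otherwise the junction smears over several
    voxels, which is a property of 26-connectivity, not of the graph code)."""
    shape = (60, 60, 60)
    j = (30, 30, 30)
    coords = [j]
    coords += [(30, 30 - i, 30) for i in range(1, arm_a + 1)]
    coords += [(30, 30 + i, 30 - i) for i in range(1, arm_b + 1)]
    coords += [(30, 30 + i, 30 + i) for i in range(1, arm_c + 1)]
    return skeleton_from_coords(coords, shape)


class TestThinning:
    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        sk = skeletonize_3d(BinaryVolume(m))
        assert sk.n_voxels == 1 and sk.mask[2, 2, 2]

    def test_empty_mask_flagged_not_error(self):
        sk = skeletonize_3d(BinaryVolume(np.zeros((4, 4, 4), bool)))
        assert sk.n_voxels == 0
        assert sk.meta["empty_input"]

    def test_straight_tube_recovers_axis(self):
        """Skeleton of a straight radius-3 tube of length 50: voxel count
        within +-10% of 50 and every voxel within 1 voxel of the true axis."""
        mask, axis = straight_tube_mask(axis_len=50, radius=3)
        sk = skeletonize_3d(BinaryVolume(mask))
        assert 45 <= sk.n_voxels <= 55
        vox = sk.voxels
        assert np.all(np.abs(vox[:, 1] - 20) <= 1)
        assert np.all(np.abs(vox[:, 2] - 20) <= 1)

    def test_skeleton_subset_of_mask(self, two_tube_mask):
        sk = skeletonize_3d(two_tube_mask)
        assert np.all(two_tube_mask.mask[sk.mask])

    def test_two_disjoint_tubes_stay_disjoint(self, two_tube_mask):
        sk = skeletonize_3d(two_tube_mask)
        assert count_components(sk.mask, 3) == 2

    def test_topology_preserved_on_random_masks(self, rng):
        """26-connected foreground component count is invariant under
        thinning (no object is broken apart or lost)."""
        for _ in range(30):
            m = random_blob_mask(rng)
            if not m.any():
                continue
            sk = skeletonize_3d(BinaryVolume(m))
            assert count_components(sk.mask, 3) == count_components(m, 3)

    def test_thinness_no_removable_voxels(self, small_phantom):
        """Every skeleton voxel is either a curve endpoint or topologically
        non-simple — the definition of a thinning fixed point."""
        sk = skeletonize_3d(small_phantom.mask_truth)
        m = np.pad(sk.mask, 1)
        full = np.ones((3, 3, 3), bool)
        for z, y, x in np.argwhere(m):
            local = m[z - 1 : z + 2, y - 1 : y + 2, x - 1 : x + 2]
            n_neighbors = int((local & full).sum()) - 1
            if n_neighbors <= 1:
                continue  # endpoints are kept by design
            assert not is_simple_point(local), f"removable voxel at {(z, y, x)}"

    def test_diameter_invariance(self):
        """The pruned skeleton voxel count of straight tubes of radii
        2, 4, 6, 8 and fixed length agree within +-10% of each other —
        the property that makes centerline MVD caliber-insensitive."""
        counts = []
        for r in (2, 4, 6, 8):
            mask, _ = straight_tube_mask(shape=(70, 40, 40), axis_len=50, radius=r)
            sk = prune_skeleton(skeletonize_3d(BinaryVolume(mask)), min_branch_len=5)
            counts.append(sk.n_voxels)
        assert max(counts) <= 1.1 * min(counts) + 1


class TestGraph:
    def test_straight_line(self):
        sk = skeleton_from_coords([(5, 5, 5 + i) for i in range(30)], (10, 10, 40))
        g = skeleton_to_graph(sk)
        assert len(g.endpoints) == 2
        assert len(g.junctions) == 0
        assert len(g.branches) == 1
        assert g.branches[0].length == 28
        assert sum(g.branch_lengths) + len(g.endpoints) + len(g.junctions) == g.n_voxels

    def test_y_shape(self):
        g = skeleton_to_graph(y_skeleton())
        assert len(g.endpoints) == 3
        assert len(g.junctions) == 1
        assert len(g.branches) == 3
        # interiors exclude the endpoint and junction nodes
        assert sorted(g.branch_lengths) == [2, 19, 19]
        assert sum(g.branch_lengths) + 4 == g.n_voxels

    def test_empty(self):
        g = skeleton_to_graph(Skeleton(mask=np.zeros((3, 3, 3), bool)))
        assert g.summary() == {
            "endpoint_count": 0,
            "junction_count": 0,
            "branch_count": 0,
            "branch_lengths": [],
            "voxel_count": 0,
        }

    def test_partition_property_on_phantom(self, small_phantom):
        """Branches and nodes partition the skeleton voxel set exactly."""
        sk = skeletonize_3d(small_phantom.mask_truth)
        g = skeleton_to_graph(sk)
        assert sum(g.branch_lengths) + len(g.endpoints) + len(g.junctions) == sk.n_voxels


class TestPruning:
    def test_min_len_one_is_identity(self):
        sk = y_skeleton()
        out = prune_skeleton(sk, min_branch_len=1)
        np.testing.assert_array_equal(out.mask, sk.mask)

    def test_short_arm_removed(self):
        """Y with arms 20, 20, 3 at threshold 5: the short arm disappears,
        the junction dissolves into a through-path with 2 endpoints."""
        out = prune_skeleton(y_skeleton(20, 20, 3), min_branch_len=5)
        g = skeleton_to_graph(out)
        assert out.n_voxels == 41
        assert len(g.endpoints) == 2
        assert len(g.junctions) == 0

    def test_lone_path_never_eroded(self):
        line = skeleton_from_coords([(5, 5, 5 + i) for i in range(30)], (10, 10, 40))
        for mbl in (5, 20, 30):
            out = prune_skeleton(line, min_branch_len=mbl)
            assert out.n_voxels == 30

    def test_short_component_removed_entirely(self):
        line = skeleton_from_coords([(5, 5, 5 + i) for i in range(3)], (10, 10, 10))
        out = prune_skeleton(line, min_branch_len=5)
        assert out.n_voxels == 0

    def test_idempotent(self, small_phantom):
        sk = skeletonize_3d(small_phantom.mask_truth)
        once = prune_skeleton(sk, min_branch_len=5)
        twice = prune_skeleton(once, min_branch_len=5)
        np.testing.assert_array_equal(once.mask, twice.mask)

    def test_bad_threshold(self):
        with pytest.raises(ParameterError):
            prune_skeleton(y_skeleton(), min_branch_len=0)
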