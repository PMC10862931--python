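"""Centroid, principal axes, and the slab/shell partitions."""

import numpy as np
import pytest

from fatomics import MaskVolume, centroid, partition_axial_slabs, partition_shells, principal_axes
from fatomics.geometry import slab_slice_counts


def _ellipsoid_mask(shape, spacing, semi_axes, rotation=None):
    idx = np.stack(np.meshgrid(*(np.arange(n) for n in shape), indexing="ij"), axis=-1)
    coords = idx * np.array(spacing)
    center = (np.array(shape) - 1) / 2 * np.array(spacing)
    rel = coords - center
    if rotation is not None:
        rel = rel @ rotation.T
    q = sum((rel[..., i] / semi_axes[i]) ** 2 for i in range(3))
    return MaskVolume((q <= 1).astype(np.uint8), spacing)


class TestCentroid:
    def test_centered_sphere(self):
        mask = _ellipsoid_mask((40, 40, 20), (1, 1, 2), (15, 15, 15))
        expected = (np.array(mask.shape) - 1) / 2 * np.array(mask.spacing)
        assert np.all(np.abs(centroid(mask) - expected) < 0.5 * np.array(mask.spacing))

    def test_single_voxel(self):
        data = np.zeros((5, 5, 5), dtype=np.uint8)
        data[1, 2, 3] = 1
        np.testing.assert_allclose(centroid(MaskVolume(data, (0.5, 0.5, 2.5))),
                                   [0.5, 1.0, 7.5])

    def test_two_blob_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        data = np.zeros((12, 12, 12), dtype=np.uint8)
        pts = rng.integers(0, 12, size=(30, 3))
        data[pts[:, 0], pts[:, 1], pts[:, 2]] = 1
        mask = MaskVolume(data, (0.7, 1.1, 2.0))
        explicit = np.array([
            [i * 0.7, j * 1.1, k * 2.0]
            for i in range(12) for j in range(12) for k in range(12) if data[i, j, k]
        ])
        np.testing.assert_allclose(centroid(mask), explicit.mean(axis=0))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            centroid(MaskVolume(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1)))


class TestPrincipalAxes:
    def test_ellipsoid_extents(self):
        spacing = (1.0, 1.0, 2.0)
        mask = _ellipsoid_mask((136, 104, 36), spacing, (60, 45, 30))
        axes = principal_axes(mask)
        tol = 2 * max(spacing)
        assert axes.major == pytest.approx(120, abs=tol)
        assert axes.intermediate == pytest.approx(90, abs=tol)
        assert axes.minor == pytest.approx(60, abs=tol)
        assert axes.aspect_major_minor >= axes.aspect_major_intermediate >= 1

    def test_sphere_is_isotropic(self):
        mask = _ellipsoid_mask((64, 64, 32), (1, 1, 2), (25, 25, 25))
        axes = principal_axes(mask)
        assert max(axes.lengths) - min(axes.lengths) < 2 * 2.0
        assert axes.aspect_major_minor == pytest.approx(1.0, abs=0.1)

    def test_rotation_invariance_about_z(self):
        spacing = (1.0, 1.0, 1.0)
        a = np.deg2rad(30)
        rot = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        plain = principal_axes(_ellipsoid_mask((110, 110, 70), spacing, (50, 35, 25)))
        rotated = principal_axes(_ellipsoid_mask((110, 110, 70), spacing, (50, 35, 25), rot))
        np.testing.assert_allclose(plain.lengths, rotated.lengths, atol=2.0)

    def test_collinear_mask_rejected(self):
        data = np.zeros((10, 3, 3), dtype=np.uint8)
        data[:, 1, 1] = 1
        with pytest.raises(ValueError, match="collinear"):
            principal_axes(MaskVolume(data, (1, 1, 1)))


class TestAxialSlabs:
    def test_remainder_rule(self):
        assert slab_slice_counts(40) == [10, 10, 10, 10]
        assert slab_slice_counts(10) == [3, 3, 2, 2]
        assert slab_slice_counts(7) == [2, 2, 2, 1]

    def test_divisible_case_equal_slabs(self):
        data = np.zeros((8, 8, 44), dtype=np.uint8)
        data[2:6, 2:6, 2:42] = 1  # 40 foreground slices
        labels = partition_axial_slabs(MaskVolume(data, (1, 1, 1)))
        for k in range(1, 5):
            slices = np.unique(np.nonzero(labels.data == k)[2])
            assert len(slices) == 10

    def test_partition_is_exact(self, small_shell):
        _, _, sac, _ = small_shell
        labels = partition_axial_slabs(sac)
        assert (labels.data > 0).sum() == (sac.data > 0).sum()
        assert np.array_equal(labels.data > 0, sac.data > 0)
        assert set(np.unique(labels.data)) == {0, 1, 2, 3, 4}

    def test_z_flip_swaps_pq1_pq4(self, small_shell):
        _, _, sac, _ = small_shell
        labels = partition_axial_slabs(sac)
        flipped = partition_axial_slabs(MaskVolume(sac.data[:, :, ::-1], sac.spacing))
        # PQ1 of the flipped volume occupies PQ4 of the original
        np.testing.assert_array_equal(
            flipped.data[:, :, ::-1] == 1, labels.data == 4
        )

    def test_too_few_slices_rejected(self):
        data = np.zeros((6, 6, 6), dtype=np.uint8)
        data[2, 2, 2:4] = 1
        with pytest.raises(ValueError, match="slabs"):
            partition_axial_slabs(MaskVolume(data, (1, 1, 1)))


class TestShells:
    def test_spherical_bands_match_analytic_volumes(self):
        # solid sphere r=40 mm on a fine isotropic grid; depth bands at
        # d = 10, 20, 30 mm correspond to radius bands [30,40], [20,30], ...
        spacing = (1.0, 1.0, 1.0)
        mask = _ellipsoid_mask((90, 90, 90), spacing, (40, 40, 40))
        labels = partition_shells(mask)
        voxel_vol = np.prod(spacing)
        diag = np.linalg.norm(spacing)
        for k, (r_in, r_out) in enumerate([(30, 40), (20, 30), (10, 20), (0, 10)], start=1):
            analytic = 4 / 3 * np.pi * (r_out**3 - r_in**3)
            measured = (labels.data == k).sum() * voxel_vol
            # tolerance: voxels within one voxel diagonal of either band surface
            boundary_area = 4 * np.pi * (r_out**2 + r_in**2)
            assert abs(measured - analytic) < boundary_area * diag, f"shell {k}"

    def test_partition_is_exact(self, small_shell):
        _, _, sac, _ = small_shell
        labels = partition_shells(sac)
        assert np.array_equal(labels.data > 0, sac.data > 0)
        assert set(np.unique(labels.data)) == {0, 1, 2, 3, 4}

    def test_band_volumes_converge_under_refinement(self):
        # banding error is surface-dominated and shrinks ~linearly with
        # spacing: halving the grid must bring every band closer to its
        # analytic volume
        coarse = _ellipsoid_mask((46, 46, 46), (2, 2, 2), (40, 40, 40))
        fine = _ellipsoid_mask((90, 90, 90), (1, 1, 1), (40, 40, 40))
        vc = [(partition_shells(coarse).data == k).sum() * 8.0 for k in range(1, 5)]
        vf = [(partition_shells(fine).data == k).sum() * 1.0 for k in range(1, 5)]
        analytic = [4 / 3 * np.pi * (o**3 - i**3)
                    for i, o in [(30, 40), (20, 30), (10, 20), (0, 10)]]
        for a, b, ref in zip(vc, vf, analytic):
            assert abs(b - ref) < abs(a - ref), "refinement must reduce banding error"

    def test_empty_sac_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            partition_shells(MaskVolume(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1)))
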