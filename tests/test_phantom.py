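"""Phantom generator: determinism, geometry, imaging model, ground truth."""

import math

import numpy as np
import pytest

from mesoreg import phantom as ph
from mesoreg.affine_intensity import warp
from mesoreg.core import Grid3D, Segment, VesselTree, Volume
from mesoreg.deformable import bending_energy
from mesoreg.evaluation import dice


class TestVesselTree:
    def test_seeded_determinism(self, desk_grid):
        t1 = ph.generate_vessel_tree(desk_grid, seed=42)
        t2 = ph.generate_vessel_tree(desk_grid, seed=42)
        assert t1.segments == t2.segments

    def test_depth_one_is_single_unbranched_root(self, desk_grid):
        t = ph.generate_vessel_tree(desk_grid, ph.BranchingParams(depth=1), seed=0)
        assert len(t.segments) == 1
        assert t.segments[0].parent == -1
        assert len(t.branch_points()) == 0

    def test_depth_two_has_branch_point(self, desk_grid):
        t = ph.generate_vessel_tree(desk_grid, ph.BranchingParams(depth=2), seed=0)
        assert len(t.branch_points()) >= 1

    def test_tree_fits_in_domain(self, desk_grid):
        t = ph.generate_vessel_tree(desk_grid, ph.BranchingParams(depth=4), seed=7)
        lo, hi = desk_grid.bounds()
        pts = t.points()
        assert np.all(pts >= lo - 1e-9) and np.all(pts <= hi + 1e-9)
        bps = t.branch_points()
        assert np.all(bps >= lo - 1e-9) and np.all(bps <= hi + 1e-9)

    def test_radius_range_validation(self, desk_grid):
        with pytest.raises(ValueError):
            ph.BranchingParams(radius_range=(30.0, 8.0))
        with pytest.raises(ValueError):
            ph.generate_vessel_tree(
                desk_grid, ph.BranchingParams(radius_range=(8.0, 500.0)), seed=0
            )


class TestRasterize:
    def test_single_segment_matches_bruteforce(self):
        grid = Grid3D((40, 12, 12), (20.0, 20.0, 20.0))
        seg = Segment((100.0, 110.0, 110.0), (600.0, 110.0, 110.0), 30.0, -1)
        tree = VesselTree([seg])
        _, mask = ph.rasterize_tree(tree, grid)
        # brute-force point-to-segment distance over every voxel
        a, b = np.asarray(seg.start), np.asarray(seg.end)
        v = b - a
        for idx in np.ndindex(grid.shape):
            p = grid.voxel_to_physical(np.asarray(idx))
            t = np.clip((p - a) @ v / (v @ v), 0, 1)
            d = np.linalg.norm(p - (a + t * v))
            assert bool(mask.values[idx]) == (d <= seg.radius)

    def test_far_region_empty(self, desk_grid, desk_tree):
        _, mask = ph.rasterize_tree(desk_tree, desk_grid)
        # corner voxels lie beyond the clamping margin of any vessel
        assert mask.values[0, 0, 0] == 0 and mask.values[-1, -1, -1] == 0

    def test_segment_order_invariance(self, desk_grid, desk_tree):
        _, m1 = ph.rasterize_tree(desk_tree, desk_grid)
        # reversing only changes iteration order; parents keep original indices
        rev = VesselTree(list(desk_tree.segments))
        rev.segments = list(reversed(desk_tree.segments))
        _, m2 = ph.rasterize_tree(rev, desk_grid)
        assert np.array_equal(m1.values, m2.values)


class TestImagingModel:
    def test_identity_parameters(self, desk_grid, desk_tree):
        vol, _ = ph.rasterize_tree(desk_tree, desk_grid)
        out = ph.apply_imaging_model(
            vol,
            ph.ImagingParams(depth_decay_per_mm=0.0, gain=1.0,
                             gaussian_noise_sd=0.0, background_level=0.0),
            seed=0,
        )
        assert np.array_equal(out.values, vol.values)

    def test_exponential_depth_decay(self):
        # 1 mm of depth at decay ln2/mm halves the expected intensity
        grid = Grid3D((4, 4, 501), (20.0, 20.0, 2.0))  # z: 0..1000 µm
        clean = Volume(grid, np.ones(grid.shape, dtype=np.float32))
        out = ph.apply_imaging_model(
            clean,
            ph.ImagingParams(depth_decay_per_mm=math.log(2), gain=1.0,
                             gaussian_noise_sd=0.0, background_level=0.0),
        )
        assert out.values[0, 0, 500] == pytest.approx(0.5 * out.values[0, 0, 0], rel=1e-6)

    def test_noise_mean_consistency_across_seeds(self, desk_grid, desk_tree):
        vol, _ = ph.rasterize_tree(desk_tree, desk_grid)
        params = ph.ImagingParams(gaussian_noise_sd=0.1)
        a = ph.apply_imaging_model(vol, params, seed=1).values[:10, :10, :10]
        b = ph.apply_imaging_model(vol, params, seed=2).values[:10, :10, :10]
        se = 0.1 / math.sqrt(a.size)
        assert abs(float(a.mean()) - float(b.mean())) < 3 * math.sqrt(2) * se

    def test_negative_decay_rejected(self):
        with pytest.raises(ValueError):
            ph.ImagingParams(depth_decay_per_mm=-1.0)


class TestSampleAffine:
    def test_zero_bounds_identity(self):
        t = ph.sample_affine(0.0, 0.0, seed=5)
        assert np.allclose(t.matrix, np.eye(4))

    def test_rigidity(self):
        t = ph.sample_affine(200.0, math.pi / 15, seed=9)
        R = t.linear
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_rotation_angle_bounded(self):
        t = ph.sample_affine(200.0, math.pi / 15, seed=3)
        angle = math.acos(np.clip((np.trace(t.linear) - 1) / 2, -1, 1))
        assert angle <= math.pi / 15 + 1e-12


class TestSmoothDeformation:
    def test_zero_amplitude_zero_field(self, small_iso_grid):
        d = ph.sample_smooth_deformation(small_iso_grid, 0.0, 200.0, seed=1)
        assert not d.vectors.any()

    def test_max_displacement_clamped(self, small_iso_grid):
        d = ph.sample_smooth_deformation(small_iso_grid, 40.0, 200.0, seed=2)
        mags = np.linalg.norm(d.physical_vectors(), axis=-1)
        assert mags.max() <= 40.0 + 1e-3

    def test_bending_energy_decreases_with_smoothness(self, small_iso_grid):
        be1 = bending_energy(ph.sample_smooth_deformation(small_iso_grid, 40.0, 100.0, seed=3))
        be2 = bending_energy(ph.sample_smooth_deformation(small_iso_grid, 40.0, 200.0, seed=3))
        assert be2 < be1


class TestMakePair:
    def test_identity_no_variability_dice_one(self, desk_grid, desk_tree):
        pair = ph.make_pair(
            desk_tree, desk_grid, {"kind": "identity"},
            ph.Variability(0.0, 0, 0.0),
            ph.ImagingParams(gaussian_noise_sd=0.0),
            seed=1,
        )
        assert dice(pair.moving_mask, pair.fixed_mask) == 1.0

    def test_gt_maps_landmarks_exactly(self, rigid_pair):
        labels = rigid_pair.landmarks_fixed.labels
        pf = rigid_pair.landmarks_fixed.as_array(labels)
        pg = rigid_pair.landmarks_moving.as_array(labels)
        err = np.abs(rigid_pair.gt_transform.apply(pf) - pg).max()
        assert err < 1e-6

    def test_dropout_terminal_count(self, desk_grid, desk_tree):
        n_term = len(desk_tree.terminal_indices())
        pair = ph.make_pair(
            desk_tree, desk_grid, {"kind": "identity"},
            ph.Variability(dropout_fraction=0.3, extra_vessel_count=2),
            seed=4,
        )
        moving_terms = pair.log["moving_terminal_count"]
        assert moving_terms == round(0.7 * n_term) + 2

    def test_seeded_determinism(self, desk_grid, desk_tree):
        p1 = ph.make_pair(desk_tree, desk_grid, {"kind": "rigid"}, seed=11)
        p2 = ph.make_pair(desk_tree, desk_grid, {"kind": "rigid"}, seed=11)
        assert np.array_equal(p1.fixed_volume.values, p2.fixed_volume.values)
        assert np.array_equal(p1.moving_volume.values, p2.moving_volume.values)
        assert np.allclose(p1.gt_transform.matrix, p2.gt_transform.matrix)

    def test_gt_resampling_recovers_fixed_mask(self):
        """Pulling the moving mask back through gt recovers the fixed mask.

        Nearest-neighbour resampling loses a surface shell about half a
        voxel thick, so the Dice bound is probed with vessels several voxels
        across; the residual deficit is pure resampling discretisation.
        """
        grid = Grid3D((128, 128, 64), (8.0, 8.0, 8.0))
        tree = ph.generate_vessel_tree(
            grid, ph.BranchingParams(radius_range=(50.0, 60.0)), seed=7
        )
        pair = ph.make_pair(
            tree, grid, {"kind": "rigid", "max_translation_um": (100, 100, 20)},
            ph.Variability(0.0, 0, 0.0),
            ph.ImagingParams(gaussian_noise_sd=0.0),
            seed=2,
        )
        recovered = warp(pair.moving_mask, pair.gt_transform, out_grid=grid)
        assert dice(recovered, pair.fixed_mask) >= 0.95

    def test_at_least_three_landmarks(self, rigid_pair):
        assert len(rigid_pair.landmarks_fixed) >= 3
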