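"""Deformable registration: losses vs oracles, network mechanics, DDF warping."""

import numpy as np
import pytest

from mesoreg import phantom as ph
from mesoreg.core import BinaryMask, DenseDisplacementField, Grid3D, Volume
from mesoreg.deformable import (
    LocalNet,
    TrainConfig,
    bending_energy,
    build_network,
    gdl_loss,
    total_loss,
    train,
    warp_with_ddf,
)
from mesoreg.deformable.losses import (
    bending_energy_value_grad,
    gdl_value_grad,
    ncc_value_grad,
)

from conftest import random_mask, random_volume


def _ddf(vectors, spacing=(20.0, 20.0, 20.0)):
    vectors = np.asarray(vectors, dtype=np.float32)
    return DenseDisplacementField(Grid3D(vectors.shape[:3], spacing), vectors)


def _gdl_bruteforce(f, g):
    """Direct evaluation of the weighted two-label overlap formula."""
    num = den = 0.0
    for fl, gl in ((f, g), (1 - f, 1 - g)):
        w = 1.0 / max(fl.sum(), 1e-12) ** 2
        num += w * (fl * gl).sum()
        den += w * (fl + gl).sum()
    return 1.0 - 2.0 * num / den


class TestGDL:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng, shape=(8, 8, 8))
        assert gdl_loss(m, m) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_single_voxels_match_bruteforce(self):
        f = np.zeros((2, 2, 2)); f[0, 0, 0] = 1
        g = np.zeros((2, 2, 2)); g[1, 1, 1] = 1
        grid = Grid3D((2, 2, 2), (20, 20, 20))
        got = gdl_loss(BinaryMask(grid, f.astype(np.uint8)), g)
        assert got == pytest.approx(_gdl_bruteforce(f, g), abs=1e-12)

    def test_range_and_bruteforce_on_random_pairs(self, rng):
        for _ in range(100):
            f = (rng.uniform(size=(6, 6, 6)) < 0.3).astype(float)
            g = (rng.uniform(size=(6, 6, 6)) < 0.3).astype(float)
            grid = Grid3D((6, 6, 6), (20, 20, 20))
            got = gdl_loss(BinaryMask(grid, f.astype(np.uint8)), g)
            assert 0.0 - 1e-12 <= got <= 1.0 + 1e-12
            assert got == pytest.approx(_gdl_bruteforce(f, g), abs=1e-10)


def _be_bruteforce(u):
    """Loop-based central second differences over every interior position."""
    total = 0.0
    X, Y, Z, _ = u.shape
    for c in range(3):
        f = u[..., c]
        for x in range(X):
            for y in range(Y):
                for z in range(Z):
                    h = np.zeros((3, 3))
                    if 1 <= x < X - 1:
                        h[0, 0] = f[x + 1, y, z] - 2 * f[x, y, z] + f[x - 1, y, z]
                    if 1 <= y < Y - 1:
                        h[1, 1] = f[x, y + 1, z] - 2 * f[x, y, z] + f[x, y - 1, z]
                    if 1 <= z < Z - 1:
                        h[2, 2] = f[x, y, z + 1] - 2 * f[x, y, z] + f[x, y, z - 1]
                    if 1 <= x < X - 1 and 1 <= y < Y - 1:
                        h[0, 1] = h[1, 0] = (
                            f[x + 1, y + 1, z] - f[x + 1, y - 1, z]
                            - f[x - 1, y + 1, z] + f[x - 1, y - 1, z]
                        ) / 4
                    if 1 <= x < X - 1 and 1 <= z < Z - 1:
                        h[0, 2] = h[2, 0] = (
                            f[x + 1, y, z + 1] - f[x + 1, y, z - 1]
                            - f[x - 1, y, z + 1] + f[x - 1, y, z - 1]
                        ) / 4
                    if 1 <= y < Y - 1 and 1 <= z < Z - 1:
                        h[1, 2] = h[2, 1] = (
                            f[x, y + 1, z + 1] - f[x, y + 1, z - 1]
                            - f[x, y - 1, z + 1] + f[x, y - 1, z - 1]
                        ) / 4
                    total += (h**2).sum()
    return total / (X * Y * Z)


class TestBendingEnergy:
    def test_constant_field_zero(self):
        assert bending_energy(_ddf(np.ones((5, 5, 5, 3)))) == 0.0

    def test_affine_field_zero(self):
        idx = np.moveaxis(np.indices((6, 6, 6)).astype(float), 0, -1)
        A = np.array([[0.1, 0.2, 0.0], [0.0, -0.3, 0.1], [0.2, 0.0, 0.5]])
        u = idx @ A.T + np.array([1.0, -2.0, 0.5])
        assert bending_energy(_ddf(u)) == pytest.approx(0.0, abs=1e-10)

    def test_quadratic_closed_form(self):
        # u_x = x^2: second difference is exactly 2 at interior x
        X, Y, Z = 7, 5, 5
        u = np.zeros((X, Y, Z, 3))
        u[..., 0] = (np.arange(X)[:, None, None] ** 2) * np.ones((1, Y, Z))
        expected = 4.0 * (X - 2) * Y * Z / (X * Y * Z)
        assert bending_energy(_ddf(u)) == pytest.approx(expected, rel=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        u = rng.normal(size=(5, 6, 4, 3))
        val, _ = bending_energy_value_grad(u)
        assert val == pytest.approx(_be_bruteforce(u), rel=1e-10)


class TestTotalLoss:
    def test_aligned_identical_pair_is_minus_one(self, rng):
        v = random_volume(rng, shape=(8, 8, 8))
        m = random_mask(rng, shape=(8, 8, 8))
        zero = _ddf(np.zeros((8, 8, 8, 3)))
        assert total_loss(v, v, m, m, zero) == pytest.approx(-1.0, abs=1e-9)

    def test_decomposition_exact(self, rng):
        f = random_volume(rng, shape=(8, 8, 8))
        g = random_volume(rng, shape=(8, 8, 8))
        mf = random_mask(rng, shape=(8, 8, 8))
        mg = random_mask(rng, shape=(8, 8, 8))
        ddf = _ddf(rng.normal(size=(8, 8, 8, 3)))
        ncc_val, _ = ncc_value_grad(f.values, g.values)
        expected = -ncc_val + gdl_loss(mf, mg.values.astype(float)) + bending_energy(ddf)
        got = total_loss(f, g, mf, mg, ddf)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_misalignment_increases_loss(self, rng):
        v = random_volume(rng, shape=(10, 10, 10))
        mvals = np.zeros((10, 10, 10), np.uint8)
        mvals[2:7, 2:7, 2:7] = 1
        m = BinaryMask(v.grid, mvals)
        zero = _ddf(np.zeros((10, 10, 10, 3)))
        aligned = total_loss(v, v, m, m, zero)
        g = Volume(v.grid, np.roll(v.values, 3, axis=0))
        mg = BinaryMask(v.grid, np.roll(mvals, 3, axis=0))
        assert total_loss(v, g, m, mg, zero) > aligned


class TestNetwork:
    def test_forward_shape_contract(self):
        model = build_network(TrainConfig(base_channels=4, seed=0))
        x = np.random.default_rng(0).normal(size=(4, 64, 64, 32)).astype(np.float32)
        u = model.forward(x, keep_cache=False)
        assert u.shape == (3, 64, 64, 32)

    def test_seeded_build_is_deterministic(self):
        a = build_network(TrainConfig(seed=5))
        b = build_network(TrainConfig(seed=5))
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_initial_ddf_near_zero(self):
        model = build_network(TrainConfig(base_channels=4, seed=2))
        x = np.random.default_rng(1).normal(size=(4, 32, 32, 32)).astype(np.float32)
        u = model.forward(x, keep_cache=False)
        assert np.abs(u).mean() < 0.5

    def test_invalid_dims_rejected(self):
        model = build_network(TrainConfig(base_channels=4))
        with pytest.raises(ValueError):
            model.forward(np.zeros((4, 48, 48, 24), np.float32))

    def test_parameter_gradients_match_finite_differences(self):
        """End-to-end backprop check on a scalar projection of the DDF."""
        rng = np.random.default_rng(3)
        model = build_network(TrainConfig(base_channels=4, seed=3))
        x = rng.normal(size=(4, 32, 32, 32)).astype(np.float32)
        proj = rng.normal(size=(3, 32, 32, 32)).astype(np.float32)
        y = model.forward(x, keep_cache=True)
        grads = model.backward(proj)
        for pname in ("out.W", "dec1.W", "enc0.W", "enc2.b"):
            p = model.params[pname]
            idx = tuple(0 for _ in p.shape)
            eps = 1e-2
            old = p[idx]
            p[idx] = old + eps
            J2 = float((proj * model.forward(x, keep_cache=False)).sum())
            p[idx] = old - eps
            J1 = float((proj * model.forward(x, keep_cache=False)).sum())
            p[idx] = old
            numeric = (J2 - J1) / (2 * eps)
            # float32 forward + ReLU kinks limit finite-difference agreement
            assert grads[pname][idx] == pytest.approx(numeric, rel=0.1, abs=1e-3)


class TestWarpWithDDF:
    def test_zero_field_identity(self, rng):
        v = random_volume(rng, shape=(8, 8, 8))
        out = warp_with_ddf(v, _ddf(np.zeros((8, 8, 8, 3))))
        assert np.allclose(out.values, v.values)

    def test_constant_one_voxel_shift(self, rng):
        v = random_volume(rng, shape=(8, 8, 8))
        u = np.zeros((8, 8, 8, 3)); u[..., 0] = 1.0
        out = warp_with_ddf(v, _ddf(u))
        assert np.allclose(out.values[:-1], v.values[1:], atol=1e-6)
        assert np.allclose(out.values[-1], 0.0)

    def test_gt_field_consistent_with_landmarks(self):
        """Warping landmarks through the phantom's gt field is exact."""
        gi = ph.iso_grid(48)
        tree = ph.generate_vessel_tree(gi, seed=21)
        pair = ph.make_pair(tree, gi, {"kind": "smooth"}, seed=22)
        labels = pair.landmarks_fixed.labels
        pf = pair.landmarks_fixed.as_array(labels)
        pg = pair.landmarks_moving.as_array(labels)
        moved = pf + pair.gt_transform.displacement_at(pf)
        # under half a voxel (construction uses the same interpolation)
        assert np.linalg.norm(moved - pg, axis=1).max() < 10.0


class TestTraining:
    def _tiny_pairs(self, n=2):
        gi = ph.iso_grid(32)
        out = []
        for i in range(n):
            tree = ph.generate_vessel_tree(
                gi, ph.BranchingParams(depth=4, radius_range=(8.0, 30.0)), seed=50 + i
            )
            out.append(
                ph.make_pair(
                    tree, gi,
                    {"kind": "smooth", "amplitude_um": 30.0},
                    ph.Variability(0.0, 0, 0.0),
                    seed=60 + i,
                )
            )
        return out

    def test_zero_epochs_returns_initial_model(self):
        pairs = self._tiny_pairs(1)
        cfg = TrainConfig(epochs=0, seed=4, base_channels=4)
        reference = LocalNet(cfg)
        model, trace = train(pairs, cfg)
        for k in model.params:
            assert np.array_equal(model.params[k], reference.params[k])
        assert trace["train"] == []

    def test_loss_decreases_on_tiny_problem(self):
        pairs = self._tiny_pairs(2)
        model, trace = train(pairs, TrainConfig(epochs=8, seed=1, base_channels=4))
        assert trace["train"][-1] < trace["train"][0]
        assert len(trace["train"]) == len(trace["val"]) == 8
        assert np.all(np.isfinite(trace["train"]))

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig(epochs=1))

    def test_save_load_round_trip(self, tmp_path):
        model = build_network(TrainConfig(base_channels=4, seed=9))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = LocalNet.load(path)
        for k in model.params:
            assert np.array_equal(model.params[k], loaded.params[k])
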