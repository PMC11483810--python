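"""Weakly supervised training loop and DDF-based warping.

Training minimises ``L_total = -NCC + GDL + BE`` per pair (batch size 1)
with Adam; the gradient flows from the composite loss through a
differentiable trilinear warping layer into the network. No ground-truth
transform is used anywhere in the loss — supervision is "weak" in that it
comes only from the paired segmentations.
"""

from __future__ import annotations

import copy

import numpy as np
from scipy.ndimage import map_coordinates, rotate as _nd_rotate

from ..core import (
    BinaryMask,
    DenseDisplacementField,
    PhantomPair,
    RegistrationResult,
    Volume,
)
from .losses import bending_energy_value_grad, gdl_value_grad, ncc_value_grad
from .network import LocalNet, TrainConfig

__all__ = ["train", "split_pairs", "register_deformable", "warp_with_ddf", "pair_to_channels"]


# ---------------------------------------------------------------------------
# differentiable trilinear warp (voxel-unit pull-back)
# ---------------------------------------------------------------------------


class _TrilinearWarp:
    """Samples channels of a static image at ``index + u``; d/du available."""

    def __init__(self, image: np.ndarray):
        # image: (C, X, Y, Z), constant w.r.t. the optimisation
        self.image = image.astype(np.float32)
        self.shape = image.shape[1:]
        self._base = np.stack(
            np.meshgrid(*[np.arange(s, dtype=np.float32) for s in self.shape], indexing="ij"),
            axis=0,
        )

    def forward(self, u: np.ndarray) -> np.ndarray:
        p = self._base + u.astype(np.float32)
        S = np.asarray(self.shape)
        valid = np.ones(self.shape, dtype=bool)
        for c in range(3):
            valid &= (p[c] >= 0) & (p[c] <= S[c] - 1)
        pc = np.stack([np.clip(p[c], 0, S[c] - 1 - 1e-4) for c in range(3)])
        f = np.floor(pc).astype(np.int64)
        w = pc - f
        corners = {}
        out = np.zeros((self.image.shape[0],) + tuple(self.shape), dtype=np.float32)
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wt = (
                        (w[0] if dx else 1 - w[0])
                        * (w[1] if dy else 1 - w[1])
                        * (w[2] if dz else 1 - w[2])
                    )
                    corners[(dx, dy, dz)] = self.image[:, f[0] + dx, f[1] + dy, f[2] + dz]
                    out += wt * corners[(dx, dy, dz)]
        out *= valid
        self._cache = (w, valid, corners)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Gradient of sum(dout * output) with respect to u, shape (3, X, Y, Z)."""
        w, valid, corners = self._cache
        du = np.zeros((3,) + tuple(self.shape), dtype=np.float32)
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    proj = (dout * corners[(dx, dy, dz)]).sum(axis=0)
                    wx = w[0] if dx else 1 - w[0]
                    wy = w[1] if dy else 1 - w[1]
                    wz = w[2] if dz else 1 - w[2]
                    sx = 1.0 if dx else -1.0
                    sy = 1.0 if dy else -1.0
                    sz = 1.0 if dz else -1.0
                    du[0] += proj * sx * wy * wz
                    du[1] += proj * wx * sy * wz
                    du[2] += proj * wx * wy * sz
        du *= valid
        return du


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------


def _normalise(v: np.ndarray) -> np.ndarray:
    v = v.astype(np.float32)
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v * 0.0


def pair_to_channels(pair: PhantomPair) -> tuple[np.ndarray, np.ndarray]:
    """Split a pair into fixed (2, X, Y, Z) and moving (2, X, Y, Z) stacks.

    Channel order: intensity (z-scored) then segmentation. The network input
    is their concatenation: fixed-int, fixed-seg, moving-int, moving-seg.
    """
    fixed = np.stack(
        [_normalise(pair.fixed_volume.values), pair.fixed_mask.values.astype(np.float32)]
    )
    moving = np.stack(
        [_normalise(pair.moving_volume.values), pair.moving_mask.values.astype(np.float32)]
    )
    return fixed, moving


def split_pairs(
    pairs: list[PhantomPair], fraction: float = 0.5, seed: int = 0
) -> tuple[list[PhantomPair], list[PhantomPair]]:
    """Seeded train/validation split (default 50/50)."""
    order = np.random.default_rng(seed).permutation(len(pairs))
    n_train = int(round(fraction * len(pairs)))
    return [pairs[i] for i in order[:n_train]], [pairs[i] for i in order[n_train:]]


def _rotate_stack(stack: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate all channels about the z axis (in-plane), preserving shape."""
    deg = float(np.degrees(angle_rad))
    out = np.stack(
        [_nd_rotate(ch, deg, axes=(0, 1), reshape=False, order=1, mode="constant")
         for ch in stack]
    )
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# loss evaluation for one pair
# ---------------------------------------------------------------------------


def _pair_loss(
    model: LocalNet,
    fixed: np.ndarray,
    moving: np.ndarray,
    with_grad: bool,
) -> tuple[float, dict[str, np.ndarray] | None, np.ndarray]:
    """Total loss (and parameter gradients) for one channel-stacked pair."""
    x = np.concatenate([fixed, moving])
    u = model.forward(x, keep_cache=with_grad)  # (3, X, Y, Z)
    warp = _TrilinearWarp(moving)
    warped = warp.forward(u)
    f_int, f_seg = fixed[0], fixed[1]
    ncc_val, d_ncc = ncc_value_grad(f_int, warped[0])
    gdl_val, d_gdl = gdl_value_grad(f_seg, np.clip(warped[1], 0.0, 1.0))
    u_last = np.moveaxis(u, 0, -1)
    be_val, d_be = bending_energy_value_grad(u_last)
    loss = -ncc_val + gdl_val + be_val
    if not with_grad:
        return loss, None, u
    dout = np.stack([-d_ncc, d_gdl]).astype(np.float32)
    du = warp.backward(dout) + np.moveaxis(d_be, -1, 0)
    grads = model.backward(du.astype(np.float32))
    return loss, grads, u


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            step = self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            params[k] = (params[k] - step).astype(np.float32)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(
    pairs: list[PhantomPair],
    cfg: TrainConfig = TrainConfig(),
    val_pairs: list[PhantomPair] | None = None,
    model: LocalNet | None = None,
) -> tuple[LocalNet, dict[str, list[float]]]:
    """Train on phantom pairs; returns the best-validation-loss model state.

    Per-epoch mean total loss is recorded for the training pairs and for the
    validation pairs; without a validation set the epoch-mean training loss
    doubles as the selection criterion (no extra forward passes).
    Deterministic for a fixed config seed.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    model = model if model is not None else LocalNet(cfg)
    data = [pair_to_channels(p) for p in pairs]
    val_data = [pair_to_channels(p) for p in val_pairs] if val_pairs else None
    opt = _Adam(model.params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    trace: dict[str, list[float]] = {"train": [], "val": []}
    best_state = model.state_dict()
    best_val = np.inf

    for _epoch in range(cfg.epochs):
        epoch_losses = []
        for fixed, moving in data:
            if cfg.augment_rotation > 0:
                ang = rng.uniform(-cfg.augment_rotation, cfg.augment_rotation)
                fixed = _rotate_stack(fixed, ang)
                moving = _rotate_stack(moving, ang)
            loss, grads, _ = _pair_loss(model, fixed, moving, with_grad=True)
            opt.step(model.params, grads)
            epoch_losses.append(loss)
        trace["train"].append(float(np.mean(epoch_losses)))
        if val_data is None:
            val_loss = trace["train"][-1]
        else:
            val_loss = float(
                np.mean([_pair_loss(model, f, m, with_grad=False)[0] for f, m in val_data])
            )
        trace["val"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()

    if cfg.epochs > 0:
        model.load_state_dict(best_state)
    return model, trace


# ---------------------------------------------------------------------------
# inference and warping
# ---------------------------------------------------------------------------


def warp_with_ddf(x: Volume | BinaryMask, ddf: DenseDisplacementField):
    """Pull-back resampling through a dense field: out(v) = x(v + ddf(v)).

    Linear interpolation for volumes; masks are linearly interpolated and
    thresholded at 0.5. Out-of-bounds samples fill with 0.
    """
    if x.grid.shape != ddf.grid.shape:
        raise ValueError("image and DDF grids must match")
    base = np.stack(
        np.meshgrid(*[np.arange(s, dtype=np.float64) for s in x.grid.shape], indexing="ij")
    )
    coords = base + np.moveaxis(ddf.vectors.astype(np.float64), -1, 0)
    vals = map_coordinates(
        x.values.astype(np.float32), coords.reshape(3, -1), order=1, cval=0.0,
        mode="constant",
    ).reshape(x.grid.shape)
    if isinstance(x, BinaryMask):
        return BinaryMask(x.grid, (vals >= 0.5).astype(np.uint8))
    return Volume(x.grid, vals)


def register_deformable(pair: PhantomPair, model: LocalNet) -> RegistrationResult:
    """Predict a DDF for one pair and warp the moving volume and mask."""
    fixed, moving = pair_to_channels(pair)
    loss, _, u = _pair_loss(model, fixed, moving, with_grad=False)
    ddf = DenseDisplacementField(pair.fixed_volume.grid, np.moveaxis(u, 0, -1))
    return RegistrationResult(
        transform=ddf,
        metric_trace=np.asarray([loss]),
        iterations=1,
        converged=True,
        warped_volume=warp_with_ddf(pair.moving_volume, ddf),
        warped_mask=warp_with_ddf(pair.moving_mask, ddf),
        info={"metric": "total_loss", "maximise": False},
    )
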