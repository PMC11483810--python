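"""A compact 3D encoder-decoder predicting dense displacement fields.

Implemented directly on numpy with hand-written backpropagation so the
whole benchmark runs on a plain CPU stack. The design follows the
weakly supervised local-deformation networks used for medical image
registration: a 4-level U-Net-style encoder-decoder over the four stacked
input channels (fixed intensity, fixed segmentation, moving intensity,
moving segmentation), emitting a 3-channel displacement field in voxel
units of the input grid. For economy the field is predicted at half
resolution and trilinearly upsampled; the last layer is He-initialised and
scaled small so the initial field is near zero.

Array layout is channels-first: ``(C, X, Y, Z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TrainConfig", "LocalNet", "build_network"]


@dataclass(frozen=True)
class TrainConfig:
    """Architecture and training controls.

    Defaults are desk-scale; the full-scale settings from mesoscopy practice
    (crop 512 x 512 x 128, 1000 epochs, z-rotation augmentation up to
    pi/15 rad) remain reachable through these fields.
    """

    depth: int = 4                       # encoder levels below the half-res stem
    base_channels: int = 8
    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 50
    augment_rotation: float = 0.0        # rad about z; pi/15 at full scale
    crop: tuple[int, int, int] | None = None
    seed: int = 0
    val_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.depth != 4:
            raise ValueError("only the 4-level architecture is supported")
        if self.augment_rotation < 0 or self.augment_rotation > pi:
            raise ValueError("augment_rotation must be in [0, pi]")
        if self.crop is not None and any(c % 32 for c in self.crop):
            raise ValueError("crop dims must be divisible by 32")


# ---------------------------------------------------------------------------
# primitive layers (forward + backward)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, X, Y, Z) -> (X*Y*Z, C*27) patch matrix with zero padding."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (C, X, Y, Z, 3,3,3)
    win = np.moveaxis(win, 0, 3)  # (X, Y, Z, C, 3,3,3)
    n = x.shape[1] * x.shape[2] * x.shape[3]
    return win.reshape(n, -1)


def conv3_forward(
    x: np.ndarray, W: np.ndarray, b: np.ndarray, col_cache: dict | None = None
) -> np.ndarray:
    """Same-padded 3x3x3 convolution. W: (Cout, Cin, 3, 3, 3)."""
    cout = W.shape[0]
    cols = _im2col(x)
    if col_cache is not None:
        col_cache["cols"] = cols
    out = cols @ W.reshape(cout, -1).T + b
    return np.ascontiguousarray(
        out.reshape(x.shape[1], x.shape[2], x.shape[3], cout).transpose(3, 0, 1, 2)
    )


def conv3_backward(
    x: np.ndarray, W: np.ndarray, dy: np.ndarray, cols: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) of conv3_forward."""
    cout, cin = W.shape[:2]
    n = x.shape[1] * x.shape[2] * x.shape[3]
    dy_mat = dy.reshape(cout, n).T  # (N, Cout)
    if cols is None:
        cols = _im2col(x)
    dW = (dy_mat.T @ cols).reshape(W.shape)
    db = dy_mat.sum(axis=0)
    # dx = conv(dy, W transposed and spatially flipped)
    W_flip = np.ascontiguousarray(W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    dx_cols = _im2col(dy)  # (N, Cout*27)
    dx = dx_cols @ W_flip.reshape(cin, -1).T
    dx = dx.reshape(x.shape[1], x.shape[2], x.shape[3], cin).transpose(3, 0, 1, 2)
    return np.ascontiguousarray(dx), dW, db


def relu_forward(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(x: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return dy * (x > 0)


def pool2_forward(x: np.ndarray) -> np.ndarray:
    c, a, b, d = x.shape
    return x.reshape(c, a // 2, 2, b // 2, 2, d // 2, 2).mean(axis=(2, 4, 6))


def pool2_backward(dy: np.ndarray) -> np.ndarray:
    up = np.repeat(np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2), 2, axis=3)
    return up / 8.0


def up2_nearest_forward(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)


def up2_nearest_backward(dy: np.ndarray) -> np.ndarray:
    c, a, b, d = dy.shape
    return dy.reshape(c, a // 2, 2, b // 2, 2, d // 2, 2).sum(axis=(2, 4, 6))


def _up2_linear_axis(x: np.ndarray, axis: int) -> np.ndarray:
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    out = np.empty(x.shape[:-1] + (2 * n,), dtype=x.dtype)
    left = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)   # x[k-1], clamped
    right = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)  # x[k+1], clamped
    out[..., 0::2] = 0.75 * x + 0.25 * left
    out[..., 1::2] = 0.75 * x + 0.25 * right
    return np.moveaxis(out, -1, axis)


def _up2_linear_axis_backward(dy: np.ndarray, axis: int) -> np.ndarray:
    dy = np.moveaxis(dy, axis, -1)
    de = dy[..., 0::2]
    do = dy[..., 1::2]
    dx = 0.75 * (de + do)
    # left-neighbour term of even outputs
    dx[..., :-1] += 0.25 * de[..., 1:]
    dx[..., 0] += 0.25 * de[..., 0]
    # right-neighbour term of odd outputs
    dx[..., 1:] += 0.25 * do[..., :-1]
    dx[..., -1] += 0.25 * do[..., -1]
    return np.moveaxis(dx, -1, axis)


def up2_linear_forward(x: np.ndarray) -> np.ndarray:
    for ax in (1, 2, 3):
        x = _up2_linear_axis(x, ax)
    return x


def up2_linear_backward(dy: np.ndarray) -> np.ndarray:
    for ax in (3, 2, 1):
        dy = _up2_linear_axis_backward(dy, ax)
    return dy


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class LocalNet:
    """4-level encoder-decoder with skip connections (see module docstring).

    ``forward`` maps a (4, X, Y, Z) stack to a (3, X, Y, Z) displacement
    field; ``backward`` returns parameter gradients given dL/dDDF. All grid
    dimensions must be divisible by 32 (half-resolution stem over 4
    pooling levels).
    """

    IN_CHANNELS = 4

    def __init__(self, cfg: TrainConfig = TrainConfig()):
        self.cfg = cfg
        c = cfg.base_channels
        rng = np.random.default_rng(cfg.seed)
        self.channels = {
            "enc0": (self.IN_CHANNELS, c),
            "enc1": (c, 2 * c),
            "enc2": (2 * c, 4 * c),
            "enc3": (4 * c, 8 * c),
            "bottom": (8 * c, 8 * c),
            "dec3": (16 * c, 4 * c),
            "dec2": (8 * c, 2 * c),
            "dec1": (4 * c, c),
            "dec0": (2 * c, c),
            "out": (c, 3),
        }
        self.params: dict[str, np.ndarray] = {}
        for name, (cin, cout) in self.channels.items():
            std = np.sqrt(2.0 / (cin * 27))
            W = rng.normal(0.0, std, size=(cout, cin, 3, 3, 3))
            if name == "out":  # He init then scaled small: near-zero initial DDF
                W *= 1e-2
            self.params[f"{name}.W"] = W.astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)
        self._cache: dict[str, np.ndarray] = {}

    # -- forward -----------------------------------------------------
    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[0] != self.IN_CHANNELS:
            raise ValueError(f"input must be ({self.IN_CHANNELS}, X, Y, Z)")
        if any(s % 32 for s in x.shape[1:]):
            raise ValueError("spatial dims must be divisible by 32")
        p = self.params
        cache: dict[str, np.ndarray] = {}

        def block(name: str, inp: np.ndarray, activate: bool = True) -> np.ndarray:
            col_cache: dict | None = {} if keep_cache else None
            z = conv3_forward(inp, p[f"{name}.W"], p[f"{name}.b"], col_cache)
            cache[f"{name}.x"] = inp
            if keep_cache:
                cache[f"{name}.cols"] = col_cache["cols"]
            if activate:
                cache[f"{name}.z"] = z
                return relu_forward(z)
            return z

        h = pool2_forward(x.astype(np.float32))  # half-resolution stem
        e0 = block("enc0", h)
        e1 = block("enc1", pool2_forward(e0))
        e2 = block("enc2", pool2_forward(e1))
        e3 = block("enc3", pool2_forward(e2))
        bt = block("bottom", pool2_forward(e3))
        d3 = block("dec3", np.concatenate([up2_nearest_forward(bt), e3]))
        d2 = block("dec2", np.concatenate([up2_nearest_forward(d3), e2]))
        d1 = block("dec1", np.concatenate([up2_nearest_forward(d2), e1]))
        d0 = block("dec0", np.concatenate([up2_nearest_forward(d1), e0]))
        ddf_half = block("out", d0, activate=False)
        ddf = up2_linear_forward(ddf_half)
        if keep_cache:
            self._cache = cache
        return ddf.astype(np.float32)

    # -- backward ----------------------------------------------------
    def backward(self, dddf: np.ndarray) -> dict[str, np.ndarray]:
        cache = self._cache
        if not cache:
            raise RuntimeError("forward(keep_cache=True) must run before backward")
        grads: dict[str, np.ndarray] = {}

        def block_back(name: str, dy: np.ndarray, activate: bool = True) -> np.ndarray:
            if activate:
                dy = relu_backward(cache[f"{name}.z"], dy)
            dx, dW, db = conv3_backward(
                cache[f"{name}.x"], self.params[f"{name}.W"], dy,
                cols=cache.get(f"{name}.cols"),
            )
            grads[f"{name}.W"] = dW
            grads[f"{name}.b"] = db
            return dx

        c = self.cfg.base_channels
        d_half = up2_linear_backward(dddf.astype(np.float32))
        d_d0 = block_back("out", d_half, activate=False)
        dcat0 = block_back("dec0", d_d0)
        d_d1, d_e0_skip = dcat0[:c], dcat0[c:]
        dcat1 = block_back("dec1", up2_nearest_backward(d_d1))
        d_d2, d_e1_skip = dcat1[: 2 * c], dcat1[2 * c :]
        dcat2 = block_back("dec2", up2_nearest_backward(d_d2))
        d_d3, d_e2_skip = dcat2[: 4 * c], dcat2[4 * c :]
        dcat3 = block_back("dec3", up2_nearest_backward(d_d3))
        d_bt, d_e3_skip = dcat3[: 8 * c], dcat3[8 * c :]
        d_p3 = block_back("bottom", up2_nearest_backward(d_bt))
        d_e3 = pool2_backward(d_p3) + d_e3_skip
        d_p2 = block_back("enc3", d_e3)
        d_e2 = pool2_backward(d_p2) + d_e2_skip
        d_p1 = block_back("enc2", d_e2)
        d_e1 = pool2_backward(d_p1) + d_e1_skip
        d_p0 = block_back("enc1", d_e1)
        d_e0 = pool2_backward(d_p0) + d_e0_skip
        block_back("enc0", d_e0)
        return grads

    # -- persistence -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32).copy()

    def save(self, path) -> None:
        np.savez(path, **self.params)

    @classmethod
    def load(cls, path, cfg: TrainConfig | None = None) -> "LocalNet":
        data = np.load(path)
        if cfg is None:
            c = data["enc0.W"].shape[0]
            cfg = TrainConfig(base_channels=int(c))
        model = cls(cfg)
        model.load_state_dict({k: data[k] for k in data.files})
        return model


def build_network(cfg: TrainConfig = TrainConfig()) -> LocalNet:
    """Construct a seeded, deterministically initialised network."""
    return LocalNet(cfg)
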