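"""Training losses and their analytic gradients.

Array-level internals (`*_grad`) operate on raw numpy arrays and return
``(value, gradient)``; the public operations wrap them for the package's
container types. Displacement fields and their derivatives are expressed
in voxel units.
"""

from __future__ import annotations

import numpy as np

from ..core import BinaryMask, DenseDisplacementField, Volume

__all__ = ["gdl_loss", "bending_energy", "total_loss"]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# negative NCC (image loss)
# ---------------------------------------------------------------------------


def ncc_value_grad(f: np.ndarray, g: np.ndarray) -> tuple[float, np.ndarray]:
    """NCC and its gradient with respect to ``g`` (both flattened internally)."""
    a = f.astype(np.float64).ravel()
    b = g.astype(np.float64).ravel()
    a0 = a - a.mean()
    b0 = b - b.mean()
    na = np.sqrt(a0 @ a0)
    nb = np.sqrt(b0 @ b0)
    denom = na * nb
    if denom < _EPS:
        return 0.0, np.zeros_like(g, dtype=np.float64)
    val = float(a0 @ b0) / denom
    # d ncc / d b0 = a0/(na*nb) - val * b0/nb^2 ; centring projects out the mean
    grad = a0 / denom - val * b0 / (nb * nb)
    grad -= grad.mean()
    return val, grad.reshape(g.shape)


# ---------------------------------------------------------------------------
# generalised Dice loss (segmentation loss)
# ---------------------------------------------------------------------------


def gdl_value_grad(mf: np.ndarray, gs: np.ndarray) -> tuple[float, np.ndarray]:
    """Generalised Dice loss between a binary fixed mask and a soft mask.

    Two labels (foreground/background) with inverse-squared-volume weights
    computed from the fixed mask; returns the loss and its gradient with
    respect to the soft moving mask.
    """
    f1 = mf.astype(np.float64)
    g1 = np.clip(gs.astype(np.float64), 0.0, 1.0)
    f0, g0 = 1.0 - f1, 1.0 - g1
    w1 = 1.0 / max(f1.sum(), _EPS) ** 2
    w0 = 1.0 / max(f0.sum(), _EPS) ** 2
    num = w1 * (f1 * g1).sum() + w0 * (f0 * g0).sum()
    den = w1 * (f1 + g1).sum() + w0 * (f0 + g0).sum()
    den = max(den, _EPS)
    val = 1.0 - 2.0 * num / den
    dnum = w1 * f1 - w0 * f0  # d/dg1 (g0 = 1 - g1)
    dden = w1 - w0
    grad = -2.0 * (dnum * den - num * dden) / den**2
    return float(val), grad


def gdl_loss(mf: BinaryMask, mg_warped: BinaryMask | Volume | np.ndarray) -> float:
    """Generalised Dice loss in [0, 1]; 0 for identical masks."""
    g = mg_warped.values if hasattr(mg_warped, "values") else np.asarray(mg_warped)
    if g.shape != mf.grid.shape:
        raise ValueError("masks must share a grid")
    if np.any(g < -1e-6) or np.any(g > 1 + 1e-6):
        raise ValueError("warped mask values must lie in [0, 1]")
    val, _ = gdl_value_grad(mf.values, g)
    return val


# ---------------------------------------------------------------------------
# bending energy (regularisation loss)
# ---------------------------------------------------------------------------

_SECOND = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _shift_slices(ax: int, offset: int, ndim: int = 3):
    sl = [slice(None)] * ndim
    if offset == 1:
        sl[ax] = slice(2, None)
    elif offset == -1:
        sl[ax] = slice(None, -2)
    else:
        sl[ax] = slice(1, -1)
    return tuple(sl)


def bending_energy_value_grad(u: np.ndarray) -> tuple[float, np.ndarray]:
    """Bending energy of a displacement field ``u`` of shape (X, Y, Z, 3).

    Mean over voxels of the squared Frobenius norm of the per-component
    Hessian, second derivatives by central finite differences on interior
    voxels (voxel units). Returns the energy and d/du.
    """
    if min(u.shape[:3]) < 3:
        raise ValueError("grid must have at least 3 voxels per axis")
    V = float(np.prod(u.shape[:3]))
    total = 0.0
    grad = np.zeros_like(u, dtype=np.float64)
    for c in range(3):
        comp = u[..., c].astype(np.float64)
        for a, b in _SECOND:
            if a == b:
                d = comp[_shift_slices(a, 1)] - 2 * comp[_shift_slices(a, 0)] + comp[
                    _shift_slices(a, -1)
                ]
                total += float((d**2).sum())
                gc = grad[..., c]
                gc[_shift_slices(a, 1)] += (2.0 / V) * d
                gc[_shift_slices(a, 0)] += (-4.0 / V) * d
                gc[_shift_slices(a, -1)] += (2.0 / V) * d
            else:
                pp = [slice(None)] * 3
                pm = [slice(None)] * 3
                mp = [slice(None)] * 3
                mm = [slice(None)] * 3
                for ax, s_pp, s_pm, s_mp, s_mm in ((a, 1, 1, -1, -1), (b, 1, -1, 1, -1)):
                    for sl, off in ((pp, s_pp), (pm, s_pm), (mp, s_mp), (mm, s_mm)):
                        sl[ax] = slice(2, None) if off == 1 else slice(None, -2)
                for sl in (pp, pm, mp, mm):
                    for ax in range(3):
                        if ax not in (a, b):
                            sl[ax] = slice(None)
                d = (comp[tuple(pp)] - comp[tuple(pm)] - comp[tuple(mp)] + comp[tuple(mm)]) / 4.0
                total += 2.0 * float((d**2).sum())  # off-diagonal Hessian terms count twice
                gc = grad[..., c]
                gc[tuple(pp)] += (1.0 / V) * d
                gc[tuple(pm)] -= (1.0 / V) * d
                gc[tuple(mp)] -= (1.0 / V) * d
                gc[tuple(mm)] += (1.0 / V) * d
    return total / V, grad


def bending_energy(ddf: DenseDisplacementField) -> float:
    """Mean squared second derivatives of the DDF; zero for affine fields."""
    val, _ = bending_energy_value_grad(ddf.vectors.astype(np.float64))
    return val


# ---------------------------------------------------------------------------
# total loss
# ---------------------------------------------------------------------------


def total_loss(
    f: Volume,
    g_warped: Volume,
    mf: BinaryMask,
    mg_warped: BinaryMask | Volume | np.ndarray,
    ddf: DenseDisplacementField,
) -> float:
    """Unweighted composite loss: -NCC(f, g_warped) + GDL(mf, mg_warped) + BE(ddf)."""
    if f.grid != g_warped.grid or f.grid != mf.grid:
        raise ValueError("all inputs must share a grid")
    ncc_val, _ = ncc_value_grad(f.values, g_warped.values)
    return -ncc_val + gdl_loss(mf, mg_warped) + bending_energy(ddf)
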