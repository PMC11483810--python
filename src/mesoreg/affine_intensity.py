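"""Affine co-registration by gradient ascent on MI or NCC.

The optimiser maximises a similarity metric Psi(f, g o T) over the
parameters of a rigid (default) or full affine transform acting on physical
coordinates, using central finite-difference gradients and plain gradient
ascent with step-halving (the step never grows). Stopping follows the
printed rules: a 100-iteration cap or an iteration-to-iteration metric
change below 1e-8. The best transform visited is always returned.

For CPU tractability the metric is evaluated on a fixed, seeded subsample
of voxels (optionally restricted to a signal region, mirroring the masking
of background used for sparse vascular scans); the final warp and any
reported quality metrics always use the full grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core import (
    AffineTransform3D,
    BinaryMask,
    LandmarkSet,
    RegistrationResult,
    Volume,
)

__all__ = [
    "SimilarityMetric",
    "OptimizerSettings",
    "mutual_information",
    "ncc",
    "com_initialize",
    "landmark_initialize",
    "register_affine",
    "warp",
]


@dataclass(frozen=True)
class SimilarityMetric:
    """Choice of similarity metric: ``"MI"`` (nats) or ``"NCC"``."""

    kind: str = "NCC"
    histogram_bins: int = 50

    def __post_init__(self) -> None:
        if self.kind.upper() not in ("MI", "NCC"):
            raise ValueError("metric kind must be 'MI' or 'NCC'")
        if self.histogram_bins < 2:
            raise ValueError("need at least 2 histogram bins")
        object.__setattr__(self, "kind", self.kind.upper())


@dataclass(frozen=True)
class OptimizerSettings:
    """Gradient-ascent controls.

    ``learning_rate`` scales the normalised-gradient step of physical length
    ``initial_step_um`` (µm-equivalent parameter units); step-halving guards
    divergence and never increases the step. Finite-difference steps are
    1 µm for translations and 0.001 rad for rotations.
    """

    learning_rate: float = 1.0
    max_iterations: int = 100
    convergence_min: float = 1e-8
    initial_step_um: float = 40.0
    max_halvings: int = 10
    max_samples: int = 40000
    sample_seed: int = 0
    dof: str = "rigid"  # "rigid" (6) or "affine" (12)
    fd_step_translation_um: float = 1.0
    fd_step_rotation_rad: float = 1e-3
    smoothing_sigma_vox: float = 2.0  # metric-side Gaussian smoothing

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.dof not in ("rigid", "affine"):
            raise ValueError("dof must be 'rigid' or 'affine'")


# ---------------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------------


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _mi_arrays(f: np.ndarray, g: np.ndarray, bins: int) -> float:
    joint, _, _ = np.histogram2d(f.ravel(), g.ravel(), bins=bins)
    joint /= joint.sum()
    h_f = _entropy(joint.sum(axis=1))
    h_g = _entropy(joint.sum(axis=0))
    return h_f + h_g - _entropy(joint.ravel())


def mutual_information(f: Volume, g: Volume, bins: int = 50) -> float:
    """Mutual information MI = H(F) + H(G) - H(F,G) in nats.

    Marginal and joint entropies come from the joint 2D histogram of
    co-located voxel intensities with ``bins`` equal-width bins per image;
    empty bins contribute nothing.
    """
    if f.grid != g.grid:
        raise ValueError("volumes must share a grid")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    return _mi_arrays(f.values, g.values, bins)


def _soft_bin(vals: np.ndarray, lo: float, hi: float, bins: int):
    """Linear (partial-volume) bin assignment: indices and right-bin weights."""
    t = np.clip((vals - lo) / max(hi - lo, 1e-12), 0.0, 1.0) * (bins - 1)
    i0 = np.minimum(t.astype(np.int64), bins - 2)
    return i0, t - i0


def _mi_soft(fi, fw, g: np.ndarray, g_lo: float, g_hi: float, bins: int) -> float:
    """MI with linear-interpolated (Parzen-style) histograms.

    Used inside the optimiser so MI varies smoothly under sub-bin intensity
    changes and 1 µm finite-difference steps produce usable gradients; the
    public :func:`mutual_information` keeps the plain binned definition.
    """
    gi, gw = _soft_bin(g, g_lo, g_hi, bins)
    joint = np.zeros(bins * bins)
    for df, wf in ((0, 1.0 - fw), (1, fw)):
        for dg, wg in ((0, 1.0 - gw), (1, gw)):
            np.add.at(joint, (fi + df) * bins + gi + dg, wf * wg)
    joint /= joint.sum()
    joint = joint.reshape(bins, bins)
    return _entropy(joint.sum(axis=1)) + _entropy(joint.sum(axis=0)) - _entropy(joint.ravel())


def _ncc_arrays(f: np.ndarray, g: np.ndarray) -> float:
    a = f.ravel().astype(np.float64)
    b = g.ravel().astype(np.float64)
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        raise ValueError("NCC undefined for constant input")
    return float(a @ b) / denom


def ncc(f: Volume, g: Volume) -> float:
    """Normalised cross-correlation in [-1, 1] over co-located voxels."""
    if f.grid != g.grid:
        raise ValueError("volumes must share a grid")
    return _ncc_arrays(f.values, g.values)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def _centroid(v: Volume) -> np.ndarray:
    w = np.maximum(v.values.astype(np.float64), 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("volume has no positive mass")
    idx = np.indices(v.grid.shape, dtype=np.float64)
    com_idx = np.array([(idx[a] * w).sum() / total for a in range(3)])
    return v.grid.voxel_to_physical(com_idx)


def com_initialize(f: Volume, g: Volume) -> AffineTransform3D:
    """Pure translation mapping the fixed intensity centroid onto the moving one."""
    return AffineTransform3D.translation(_centroid(g) - _centroid(f))


def landmark_initialize(lf: LandmarkSet, lg: LandmarkSet) -> AffineTransform3D:
    """Least-squares rigid alignment of paired landmarks (fixed -> moving).

    Solves ``argmin_{R,t} sum ||R p_f + t - p_g||^2`` with ``det R = +1``
    (Kabsch); requires >= 3 shared, non-collinear points.
    """
    labels = lf.shared_labels(lg)
    if len(labels) < 3:
        raise ValueError("need at least 3 shared landmark labels")
    P = lf.as_array(labels)
    Q = lg.as_array(labels)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    if np.linalg.matrix_rank(P0, tol=1e-9 * max(1.0, np.abs(P0).max())) < 2:
        raise ValueError("landmarks are collinear; rigid alignment is underdetermined")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return AffineTransform3D.from_rotation_translation(R, t)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------


def warp(x: Volume | BinaryMask, t: AffineTransform3D, out_grid=None):
    """Resample ``x`` on ``out_grid`` by pulling values through ``t``.

    ``t`` maps fixed-space physical coordinates into the space of ``x``
    (pull-back convention). Linear interpolation for volumes, nearest
    neighbour for masks; out-of-bounds voxels fill with 0.
    """
    grid = x.grid if out_grid is None else out_grid
    axes = grid.coordinate_arrays()
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    moved = t.apply(pts)
    idx = x.grid.physical_to_voxel(moved).T
    if isinstance(x, BinaryMask):
        vals = map_coordinates(x.values, idx, order=0, cval=0, mode="constant")
        return BinaryMask(grid, vals.reshape(grid.shape))
    vals = map_coordinates(
        x.values.astype(np.float32), idx.astype(np.float32), order=1, cval=0.0,
        mode="constant",
    )
    return Volume(grid, vals.reshape(grid.shape))


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def _rotation_xyz(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _params_to_transform(
    alpha: np.ndarray, centre: np.ndarray, init: AffineTransform3D, dof: str
) -> AffineTransform3D:
    t = alpha[:3]
    R = _rotation_xyz(*alpha[3:6])
    if dof == "affine":
        scales = np.exp(alpha[6:9])
        shears = alpha[9:12]
        S = np.diag(scales)
        Sh = np.eye(3)
        Sh[0, 1], Sh[0, 2], Sh[1, 2] = shears
        R = R @ S @ Sh
    inner = AffineTransform3D.rigid_about_centre(R, t, centre) if dof == "rigid" else \
        AffineTransform3D.from_rotation_translation(R, centre + t - R @ centre)
    return init.compose(inner)


def _sample_points(
    f: Volume, sample_mask: BinaryMask | None, opts: OptimizerSettings
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded voxel subsample (physical coords + fixed values) for the metric.

    With no explicit mask, a threshold-segmented signal region of the fixed
    image is used so sparse vascular signal is not drowned by background.
    """
    if sample_mask is None:
        from .preprocess import threshold_segment

        sample_mask = threshold_segment(f)
    if sample_mask.grid != f.grid:
        raise ValueError("sample mask must live on the fixed grid")
    candidates = np.flatnonzero(sample_mask.values)
    if candidates.size < 100:
        candidates = np.arange(f.grid.n_voxels)
    rng = np.random.default_rng(opts.sample_seed)
    if candidates.size > opts.max_samples:
        candidates = rng.choice(candidates, size=opts.max_samples, replace=False)
        candidates.sort()
    ijk = np.stack(np.unravel_index(candidates, f.grid.shape), axis=-1)
    pts = f.grid.voxel_to_physical(ijk)
    fvals = f.values.reshape(-1)[candidates].astype(np.float64)
    return pts, fvals


def register_affine(
    f: Volume,
    g: Volume,
    metric: SimilarityMetric = SimilarityMetric(),
    init: AffineTransform3D | None = None,
    opts: OptimizerSettings = OptimizerSettings(),
    sample_mask: BinaryMask | None = None,
) -> RegistrationResult:
    """Gradient-ascent affine registration of ``g`` (moving) onto ``f`` (fixed).

    Returns the best-metric transform visited, the per-iteration metric
    trace, and the moving volume warped through that transform.
    """
    if init is None:
        init = com_initialize(f, g)
    np.linalg.inv(init.matrix)  # raises if degenerate

    if opts.smoothing_sigma_vox > 0:
        from scipy.ndimage import gaussian_filter

        f = Volume(f.grid, gaussian_filter(f.values, opts.smoothing_sigma_vox))
        g_metric = Volume(g.grid, gaussian_filter(g.values, opts.smoothing_sigma_vox))
    else:
        g_metric = g
    pts, fvals = _sample_points(f, sample_mask, opts)
    gvals_arr = g_metric.values.astype(np.float32)
    centre = f.grid.centre
    nparams = 6 if opts.dof == "rigid" else 12
    if metric.kind == "MI":
        f_lo, f_hi = float(fvals.min()), float(fvals.max())
        g_lo, g_hi = float(gvals_arr.min()), float(gvals_arr.max())
        fi_soft, fw_soft = _soft_bin(fvals, f_lo, f_hi, metric.histogram_bins)

    # µm-equivalent parameter scaling: one unit of any scaled parameter moves
    # points by about one µm at the in-plane half-extent arm.
    arm = float(np.linalg.norm(f.grid.extent[:2])) / 2.0
    scale = np.ones(nparams)
    scale[3:] = 1.0 / max(arm, 1.0)

    fd_steps = np.empty(nparams)
    fd_steps[:3] = opts.fd_step_translation_um
    fd_steps[3:] = opts.fd_step_rotation_rad

    def metric_of_batch(alphas: list[np.ndarray]) -> list[float]:
        """Evaluate Psi for several parameter vectors with one interpolation call."""
        all_idx = []
        for a in alphas:
            T = _params_to_transform(a, centre, init, opts.dof)
            all_idx.append(g.grid.physical_to_voxel(T.apply(pts)))
        coords = np.concatenate(all_idx, axis=0).T
        sampled = map_coordinates(gvals_arr, coords, order=1, cval=0.0, mode="constant")
        out = []
        n = pts.shape[0]
        for k in range(len(alphas)):
            gs = sampled[k * n : (k + 1) * n].astype(np.float64)
            if metric.kind == "MI":
                out.append(_mi_soft(fi_soft, fw_soft, gs, g_lo, g_hi, metric.histogram_bins))
            else:
                gs0 = gs - gs.mean()
                f0 = fvals - fvals.mean()
                denom = math.sqrt(float(f0 @ f0) * float(gs0 @ gs0))
                out.append(float(f0 @ gs0) / denom if denom > 0 else -1.0)
        return out

    alpha = np.zeros(nparams)
    psi = metric_of_batch([alpha])[0]
    best_alpha, best_psi = alpha.copy(), psi
    gamma = opts.learning_rate
    trace: list[float] = []
    converged = False

    for _ in range(opts.max_iterations):
        # central finite-difference gradient, all perturbations in one call
        perturbed = []
        for k in range(nparams):
            for sgn in (+1.0, -1.0):
                a = alpha.copy()
                a[k] += sgn * fd_steps[k]
                perturbed.append(a)
        vals = metric_of_batch(perturbed)
        grad = np.array(
            [(vals[2 * k] - vals[2 * k + 1]) / (2 * fd_steps[k]) for k in range(nparams)]
        )
        # steepest-ascent direction in µm-equivalent parameter space
        # (beta = alpha / scale, so dPsi/dbeta = dPsi/dalpha * scale)
        grad_beta = grad * scale
        norm = np.linalg.norm(grad_beta)
        if norm == 0.0:
            trace.append(psi)
            converged = True
            break
        direction = grad_beta / norm

        # line search restarts from gamma each iteration; halvings within an
        # iteration only guard divergence and gamma itself never increases
        accepted = False
        g_try = gamma
        for _h in range(opts.max_halvings + 1):
            candidate = alpha + g_try * opts.initial_step_um * direction * scale
            psi_new = metric_of_batch([candidate])[0]
            if psi_new > psi:
                alpha, delta, psi = candidate, psi_new - psi, psi_new
                accepted = True
                break
            g_try /= 2.0
        trace.append(psi)
        if psi > best_psi:
            best_psi, best_alpha = psi, alpha.copy()
        if not accepted or (accepted and delta < opts.convergence_min):
            converged = True
            break

    T_best = _params_to_transform(best_alpha, centre, init, opts.dof)
    warped = warp(g, T_best, out_grid=f.grid)
    return RegistrationResult(
        transform=T_best,
        metric_trace=np.asarray(trace),
        iterations=len(trace),
        converged=converged,
        warped_volume=warped,
        info={
            "metric": metric.kind,
            "initial_psi": float(metric_of_batch([np.zeros(nparams)])[0]),
            "best_psi": float(best_psi),
            "n_samples": int(pts.shape[0]),
        },
    )
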