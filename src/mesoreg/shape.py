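"""Shape-based affine co-registration from binary segmentations.

Two strategies operating on segmentation masks resampled to isotropic
resolution: point-to-plane ICP on marching-cubes surfaces, and NCC-driven
affine registration of Euclidean distance maps (which weight the vessel
centre line, where the distance from background peaks).

All resulting transforms follow the package convention: they map fixed-space
physical coordinates into moving-space coordinates (pull-back warping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, distance_transform_edt, map_coordinates
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .affine_intensity import OptimizerSettings, SimilarityMetric, register_affine, warp
from .core import (
    AffineTransform3D,
    BinaryMask,
    Grid3D,
    RegistrationResult,
    Volume,
)

__all__ = [
    "SurfacePointCloud",
    "DistanceMap",
    "ICPSettings",
    "resample_isotropic",
    "extract_surface",
    "icp_point_to_plane",
    "distance_transform",
    "register_distance",
]


@dataclass
class SurfacePointCloud:
    """Surface vertices (µm) with outward unit normals."""

    points: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if self.points.shape != self.normals.shape:
            raise ValueError("points and normals must have equal counts")
        norms = np.linalg.norm(self.normals, axis=1)
        if self.points.shape[0] and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("normals must be unit length")

    def __len__(self) -> int:
        return self.points.shape[0]

    def transform(self, t: AffineTransform3D) -> "SurfacePointCloud":
        R = t.linear
        n = self.normals @ np.linalg.inv(R).T  # normals transform with inv-transpose
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        return SurfacePointCloud(t.apply(self.points), n)


@dataclass
class DistanceMap:
    """Per-voxel distance (voxel units) to the nearest background voxel."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float32)
        if arr.shape != self.grid.shape:
            raise ValueError("distance map shape must equal grid shape")
        if np.any(arr < 0):
            raise ValueError("distances must be >= 0")
        self.values = arr


@dataclass(frozen=True)
class ICPSettings:
    max_iterations: int = 1000
    max_corr_dist_um: float = 200.0  # 10 voxels at 20 µm isotropic
    convergence_min: float = 1e-8


def resample_isotropic(
    x: Volume | BinaryMask, spacing_um: float | None = None
) -> Volume | BinaryMask:
    """Resample to an isotropic grid (default: the in-plane spacing).

    Linear interpolation for volumes, nearest neighbour for masks; physical
    coordinates are preserved through the grid origin.
    """
    grid = x.grid
    s = float(spacing_um) if spacing_um is not None else float(min(grid.spacing[:2]))
    if np.allclose(grid.spacing, (s, s, s)):
        return x
    new_shape = tuple(
        max(1, int(round(grid.extent[a] / s)) + 1) for a in range(3)
    )
    new_grid = Grid3D(new_shape, (s, s, s), grid.origin)
    axes = new_grid.coordinate_arrays()
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    idx = grid.physical_to_voxel(np.stack([X, Y, Z], axis=-1)).reshape(-1, 3).T
    if isinstance(x, BinaryMask):
        vals = map_coordinates(x.values, idx, order=0, mode="nearest")
        return BinaryMask(new_grid, vals.reshape(new_shape))
    vals = map_coordinates(x.values.astype(np.float32), idx.astype(np.float32),
                           order=1, mode="nearest")
    return Volume(new_grid, vals.reshape(new_shape))


def extract_surface(m: BinaryMask) -> SurfacePointCloud:
    """Marching-cubes surface of a {0,1} mask at iso-level 0.5.

    The mask must live on an isotropic grid (resample first). Vertices are
    returned in physical µm; normals are unit vectors oriented outward
    (away from the foreground).
    """
    if m.foreground_count == 0:
        raise ValueError("cannot extract a surface from an empty mask")
    sp = m.grid.spacing
    if not np.allclose(sp, sp[0]):
        raise ValueError("extract_surface requires an isotropic grid; resample first")
    padded = np.pad(m.values.astype(np.float32), 1)
    verts, _faces, normals, _vals = marching_cubes(
        padded, level=0.5, spacing=(sp[0], sp[1], sp[2]), step_size=1
    )
    # skimage normals follow the descending gradient: from foreground (1)
    # towards background (0), i.e. outward already.
    verts = verts - np.asarray(sp) + np.asarray(m.grid.origin)
    norms = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return SurfacePointCloud(verts, norms)


def _rodrigues(omega: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(omega)
    if theta < 1e-12:
        return np.eye(3)
    k = omega / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def icp_point_to_plane(
    fixed: SurfacePointCloud,
    moving: SurfacePointCloud,
    opts: ICPSettings = ICPSettings(),
) -> RegistrationResult:
    """Point-to-plane ICP aligning the moving cloud onto the fixed cloud.

    Each iteration matches every moving point to its nearest fixed point
    within ``max_corr_dist_um``, minimises the sum of squared distances to
    the tangent planes at the matched points (projections on the fixed
    normals) through a linearised small-angle least squares, and composes
    the rigid increment. The RMS residual trace is non-increasing; the
    returned transform maps fixed space to moving space.
    """
    if len(fixed) < 4 or len(moving) < 4:
        raise ValueError("ICP needs at least 4 points per cloud")
    tree = cKDTree(fixed.points)
    T = np.eye(4)  # moving -> fixed
    q = moving.points.copy()

    def residual_stats(qp: np.ndarray):
        dist, idx = tree.query(qp, distance_upper_bound=opts.max_corr_dist_um)
        sel = np.isfinite(dist)
        if not np.any(sel):
            return None
        fpts = fixed.points[idx[sel]]
        fnrm = fixed.normals[idx[sel]]
        r = np.einsum("ij,ij->i", qp[sel] - fpts, fnrm)
        return qp[sel], fpts, fnrm, r

    stats = residual_stats(q)
    if stats is None:
        raise ValueError("no correspondences within max_corr_dist at start")
    trace: list[float] = []
    converged = False
    for _ in range(opts.max_iterations):
        qs, fpts, fnrm, r = stats
        rms = float(np.sqrt(np.mean(r**2)))
        # solve for increment (omega, t): minimise sum((q + omega x q + t - f).n)^2
        A = np.hstack([np.cross(qs, fnrm), fnrm])
        b = -r
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        R = _rodrigues(x[:3])
        U, _s, Vt = np.linalg.svd(R)
        R = U @ Vt  # re-orthonormalise
        dT = np.eye(4)
        dT[:3, :3] = R
        dT[:3, 3] = x[3:]
        q_new = q @ R.T + x[3:]
        stats_new = residual_stats(q_new)
        if stats_new is None:
            trace.append(rms)
            converged = True
            break
        rms_new = float(np.sqrt(np.mean(stats_new[3] ** 2)))
        if rms_new > rms:  # keep the trace monotone; stop at the best state
            trace.append(rms)
            converged = True
            break
        trace.append(rms_new)
        T = dT @ T
        q = q_new
        stats = stats_new
        if abs(rms - rms_new) < opts.convergence_min:
            converged = True
            break

    moving_to_fixed = AffineTransform3D(T)
    return RegistrationResult(
        transform=moving_to_fixed.inverse(),  # fixed -> moving (pull-back)
        metric_trace=np.asarray(trace),
        iterations=len(trace),
        converged=converged,
        info={"metric": "point_to_plane_rms", "maximise": False},
    )


def distance_transform(m: BinaryMask) -> DistanceMap:
    """Exact Euclidean distance (voxels) to the nearest background voxel.

    Zero on background; an all-foreground mask has no background reference
    and is rejected. Vessel centre lines attain the slice-wise maxima,
    which is what makes distance maps useful as a registration surrogate.
    """
    if m.values.all():
        raise ValueError("distance transform undefined for an all-foreground mask")
    d = distance_transform_edt(m.values.astype(bool), sampling=1.0)
    return DistanceMap(m.grid, d.astype(np.float32))


def register_distance(
    mf: BinaryMask,
    mg: BinaryMask,
    opts: OptimizerSettings = OptimizerSettings(),
    spacing_um: float | None = None,
    init: AffineTransform3D | None = None,
) -> RegistrationResult:
    """NCC affine registration of Euclidean distance maps.

    Both masks are resampled to isotropic resolution, distance transformed,
    and passed through the intensity-based NCC registration. Initialisation
    defaults to centre of mass of the distance maps; a rigid ``init`` (e.g.
    from landmarks) can be supplied instead. The warped moving mask (on the
    original fixed grid) is attached to the result.
    """
    if mf.foreground_count == 0 or mg.foreground_count == 0:
        raise ValueError("both masks must be non-empty")
    mf_iso = resample_isotropic(mf, spacing_um)
    mg_iso = resample_isotropic(mg, spacing_um)
    df = distance_transform(mf_iso)
    dg = distance_transform(mg_iso)
    vf = Volume(mf_iso.grid, df.values)
    vg = Volume(mg_iso.grid, dg.values)
    roi = binary_dilation(mf_iso.values.astype(bool), iterations=3)
    result = register_affine(
        vf,
        vg,
        metric=SimilarityMetric(kind="NCC"),
        init=init,
        opts=opts,
        sample_mask=BinaryMask(mf_iso.grid, roi.astype(np.uint8)),
    )
    result.warped_mask = warp(mg, result.transform, out_grid=mf.grid)
    result.info["method"] = "distance"
    return result
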