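"""Core containers shared by every stage of the co-registration benchmark.

Conventions used throughout the package:

* voxel indices are 0-based and map to physical coordinates through the
  voxel-centre convention ``x = origin + index * spacing``;
* physical coordinates are in micrometres (µm), matching the native
  20 x 20 x 4 µm voxel size of raster-scan photoacoustic mesoscopy;
* affine transforms act on physical coordinates and map *fixed*-space
  points into *moving*-space points (pull-back convention for warping);
* dense displacement fields are stored in voxel units of the fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Grid3D",
    "Volume",
    "BinaryMask",
    "AffineTransform3D",
    "DenseDisplacementField",
    "LandmarkSet",
    "Segment",
    "VesselTree",
    "PhantomPair",
    "RegistrationResult",
]


@dataclass(frozen=True)
class Grid3D:
    """Anisotropic 3D sampling grid.

    Parameters
    ----------
    shape
        Voxel counts ``(nx, ny, nz)``; every entry must be >= 1.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in µm; every entry must be > 0.
    origin
        Physical position (µm) of the centre of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (20.0, 20.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three counts >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be three positive values, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> np.ndarray:
        """Physical size (µm) spanned by voxel centres along each axis."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    @property
    def centre(self) -> np.ndarray:
        """Physical centre of the grid (µm)."""
        return np.asarray(self.origin) + self.extent / 2.0

    def voxel_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices ``(..., 3)`` to physical µm."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map physical µm coordinates ``(..., 3)`` to fractional voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centres."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box (lo, hi) of the voxel-centre lattice."""
        lo = np.asarray(self.origin, dtype=float)
        return lo, lo + self.extent


def _check_values(grid: Grid3D, values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.shape != grid.shape:
        raise ValueError(f"{name} values shape {arr.shape} != grid shape {grid.shape}")
    return arr


@dataclass
class Volume:
    """Scalar intensity volume on a :class:`Grid3D` (arbitrary units)."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, "Volume").astype(np.float32, copy=False)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume values must be finite")

    def with_values(self, values: np.ndarray) -> "Volume":
        return Volume(self.grid, values)


@dataclass
class BinaryMask:
    """{0, 1} segmentation mask aligned to a :class:`Grid3D`."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _check_values(self.grid, self.values, "BinaryMask")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("BinaryMask values must be 0 or 1")
        self.values = arr.astype(np.uint8, copy=False)

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return BinaryMask(self.grid, values)


class AffineTransform3D:
    """4x4 homogeneous transform on physical coordinates (fixed -> moving)."""

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(m[3], (0.0, 0.0, 0.0, 1.0)):
            raise ValueError("last row of a homogeneous transform must be (0,0,0,1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("linear block is singular")
        self.matrix = m

    # -- constructors ------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform3D":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation: Sequence[float]
    ) -> "AffineTransform3D":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def translation(cls, t: Sequence[float]) -> "AffineTransform3D":
        return cls.from_rotation_translation(np.eye(3), t)

    @classmethod
    def rigid_about_centre(
        cls, rotation: np.ndarray, translation: Sequence[float], centre: Sequence[float]
    ) -> "AffineTransform3D":
        """Rotation about ``centre`` followed by a translation: x -> R(x-c)+c+t."""
        R = np.asarray(rotation, dtype=float)
        c = np.asarray(centre, dtype=float)
        t = np.asarray(translation, dtype=float)
        return cls.from_rotation_translation(R, c + t - R @ c)

    # -- algebra -----------------------------------------------------
    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to points of shape ``(..., 3)`` (µm)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.offset

    def compose(self, other: "AffineTransform3D") -> "AffineTransform3D":
        """Return ``self o other`` (first apply ``other``, then ``self``)."""
        return AffineTransform3D(self.matrix @ other.matrix)

    def inverse(self) -> "AffineTransform3D":
        return AffineTransform3D(np.linalg.inv(self.matrix))

    def is_rigid(self, tol: float = 1e-8) -> bool:
        R = self.linear
        return bool(
            np.allclose(R.T @ R, np.eye(3), atol=tol) and np.linalg.det(R) > 0
        )

    def rotation_angle(self) -> float:
        """Rotation angle (rad) of the linear block, assuming rigidity."""
        tr = np.clip((np.trace(self.linear) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.arccos(tr))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"AffineTransform3D(\n{np.array_str(self.matrix, precision=4)})"


@dataclass
class DenseDisplacementField:
    """Per-voxel displacement vectors in voxel units of ``grid``.

    ``vectors[..., c]`` is the displacement along axis ``c``; warping with the
    field samples the moving image at ``index + vectors[index]`` (pull-back).
    """

    grid: Grid3D
    vectors: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.vectors, dtype=np.float32)
        if arr.shape != self.grid.shape + (3,):
            raise ValueError(
                f"DDF shape {arr.shape} != grid shape {self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("DDF vectors must be finite")
        self.vectors = arr

    def physical_vectors(self) -> np.ndarray:
        """Displacements converted to µm."""
        return self.vectors * np.asarray(self.grid.spacing, dtype=np.float32)

    def displacement_at(self, points_um: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated physical displacement (µm) at physical points."""
        from scipy.ndimage import map_coordinates

        idx = self.grid.physical_to_voxel(np.atleast_2d(points_um))
        out = np.empty_like(idx)
        for c in range(3):
            out[:, c] = map_coordinates(
                self.vectors[..., c].astype(float), idx.T, order=1, mode="nearest"
            )
        return out * np.asarray(self.grid.spacing)


class LandmarkSet(Mapping[str, np.ndarray]):
    """Labelled 3D physical points (µm). Labels must be unique."""

    def __init__(self, points: Mapping[str, Sequence[float]] | Iterable[tuple[str, Sequence[float]]]):
        items = dict(points)
        if not items:
            raise ValueError("LandmarkSet needs at least one point")
        self._points = {str(k): np.asarray(v, dtype=float).reshape(3) for k, v in items.items()}

    def __getitem__(self, label: str) -> np.ndarray:
        return self._points[label]

    def __iter__(self):
        return iter(self._points)

    def __len__(self) -> int:
        return len(self._points)

    @property
    def labels(self) -> list[str]:
        return sorted(self._points)

    def shared_labels(self, other: "LandmarkSet") -> list[str]:
        return sorted(set(self._points) & set(other._points))

    def as_array(self, labels: Sequence[str] | None = None) -> np.ndarray:
        labels = self.labels if labels is None else list(labels)
        return np.stack([self._points[l] for l in labels])

    def transform(self, t: AffineTransform3D) -> "LandmarkSet":
        return LandmarkSet({k: t.apply(v) for k, v in self._points.items()})


@dataclass(frozen=True)
class Segment:
    """One straight vessel segment in physical space (µm)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float
    parent: int  # index of parent segment, -1 for a root

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("segment radius must be positive")


@dataclass
class VesselTree:
    """Random branching vessel network used as the imaged anatomy stand-in."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("VesselTree must contain at least one segment")
        roots = [i for i, s in enumerate(self.segments) if s.parent < 0]
        if not roots:
            raise ValueError("VesselTree must contain at least one root")
        for i, s in enumerate(self.segments):
            if s.parent >= 0:
                p = self.segments[s.parent]
                if not np.allclose(s.start, p.end):
                    raise ValueError(f"segment {i} does not start at its parent's end")

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in range(len(self.segments))}
        for i, s in enumerate(self.segments):
            if s.parent >= 0:
                ch[s.parent].append(i)
        return ch

    def terminal_indices(self) -> list[int]:
        ch = self.children()
        return [i for i in range(len(self.segments)) if not ch[i]]

    def branch_points(self) -> np.ndarray:
        """End points of segments with >= 2 children, shape (n, 3) µm."""
        ch = self.children()
        pts = [self.segments[i].end for i in range(len(self.segments)) if len(ch[i]) >= 2]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def points(self) -> np.ndarray:
        """All segment endpoints, shape (2n, 3)."""
        return np.asarray(
            [p for s in self.segments for p in (s.start, s.end)], dtype=float
        )


@dataclass
class PhantomPair:
    """Synthetic fixed/moving scan pair with known ground truth."""

    fixed_volume: Volume
    fixed_mask: BinaryMask
    moving_volume: Volume
    moving_mask: BinaryMask
    gt_transform: AffineTransform3D | DenseDisplacementField
    landmarks_fixed: LandmarkSet
    landmarks_moving: LandmarkSet
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        gf, gm = self.fixed_volume.grid, self.moving_volume.grid
        if gf.shape[:2] != gm.shape[:2] or gf.spacing != gm.spacing:
            raise ValueError("fixed and moving grids may differ only in z extent")
        shared = self.landmarks_fixed.shared_labels(self.landmarks_moving)
        if len(shared) != len(self.landmarks_fixed):
            raise ValueError("landmark labels must be paired")


@dataclass
class RegistrationResult:
    """Outcome of one registration run."""

    transform: AffineTransform3D | DenseDisplacementField
    metric_trace: np.ndarray
    iterations: int
    converged: bool
    warped_volume: Volume | None = None
    warped_mask: BinaryMask | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metric_trace = np.asarray(self.metric_trace, dtype=float)
        if self.metric_trace.size != self.iterations:
            raise ValueError("metric trace length must equal iteration count")
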