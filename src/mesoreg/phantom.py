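"""Synthetic vascular mesoscopy phantoms with known ground truth.

The generator emulates the features of raster-scan photoacoustic mesoscopy
that make co-registration hard: sparse tubular networks on an anisotropic
grid, depth-dependent fluence decay, scan-to-scan gain and noise
variability, partial network overlap (terminal vessels appearing or
disappearing between scans) and a known rigid or smooth deformable
ground-truth transform with branch-point landmarks.

Every operation is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    AffineTransform3D,
    BinaryMask,
    DenseDisplacementField,
    Grid3D,
    LandmarkSet,
    PhantomPair,
    Segment,
    VesselTree,
    Volume,
)

__all__ = [
    "BranchingParams",
    "ImagingParams",
    "Variability",
    "desk_grid",
    "iso_grid",
    "generate_vessel_tree",
    "rasterize_tree",
    "apply_imaging_model",
    "sample_affine",
    "sample_smooth_deformation",
    "make_pair",
]


@dataclass(frozen=True)
class BranchingParams:
    """Random binary branching controls.

    ``depth`` counts segment generations along each root-to-tip path;
    ``radius_range`` is (min, max) vessel radius in µm with per-generation
    tapering; ``tortuosity`` scales direction jitter per segment.
    """

    depth: int = 5
    branch_prob: float = 0.65
    radius_range: tuple[float, float] = (8.0, 30.0)
    tortuosity: float = 0.3

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in [0, 1]")


@dataclass(frozen=True)
class ImagingParams:
    """Simple photoacoustic image-formation model.

    Expected voxel value = ``background + gain * clean * exp(-decay * z_mm)``
    plus i.i.d. Gaussian noise; z is depth below the grid origin.
    """

    depth_decay_per_mm: float = 0.5
    gain: float = 1.0
    gaussian_noise_sd: float = 0.1
    background_level: float = 0.05

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.gaussian_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.depth_decay_per_mm < 0:
            raise ValueError("negative depth decay is not physical")


@dataclass(frozen=True)
class Variability:
    """Scan-to-scan biological/technical variability of the moving scan."""

    dropout_fraction: float = 0.1
    extra_vessel_count: int = 2
    gain_sigma: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.extra_vessel_count < 0:
            raise ValueError("extra_vessel_count must be >= 0")


def desk_grid() -> Grid3D:
    """Default desk-scale grid: 128 x 128 x 64 voxels at 20 x 20 x 4 µm."""
    return Grid3D((128, 128, 64), (20.0, 20.0, 4.0))


def iso_grid(n: int = 64, spacing_um: float = 20.0) -> Grid3D:
    """Isotropic cube grid used for desk-scale deformable experiments."""
    return Grid3D((n, n, n), (spacing_um,) * 3)


# ---------------------------------------------------------------------------
# vessel tree generation
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def generate_vessel_tree(
    domain: Grid3D,
    params: BranchingParams = BranchingParams(),
    seed: int = 0,
) -> VesselTree:
    """Grow a random binary branching vessel network inside ``domain``.

    The tree is grown breadth-first from a single root near the domain
    centre; each tip extends by one segment per generation, branching into
    two with probability ``branch_prob`` (the root always branches when
    ``depth >= 2`` so at least one branch-point landmark exists). Directions
    receive tortuosity jitter; the out-of-plane component is compressed to
    the slab aspect ratio so the network stays inside thin volumes.
    """
    lo, hi = domain.bounds()
    extent = hi - lo
    if min(extent[:2]) <= 0:
        raise ValueError("domain has no in-plane extent")
    r_lo, r_hi = params.radius_range
    if r_hi > min(e for e in extent if e > 0) / 4 + 1e-9:
        raise ValueError("radius_range exceeds a quarter of the smallest domain extent")

    rng = np.random.default_rng(seed)
    margin = r_hi
    seg_len = 0.6 * min(extent[0], extent[1]) / params.depth
    z_aspect = extent[2] / max(extent[0], extent[1]) if extent[2] > 0 else 0.0

    def clamp(p: np.ndarray) -> np.ndarray:
        return np.clip(p, lo + margin, np.maximum(hi - margin, lo + margin))

    def jitter(d: np.ndarray, scale: float) -> np.ndarray:
        v = d + scale * rng.normal(size=3)
        v[2] *= max(z_aspect, 0.05)
        return _unit(v)

    start = lo + extent * np.array(
        [rng.uniform(0.25, 0.75), rng.uniform(0.25, 0.75), rng.uniform(0.4, 0.6)]
    )
    direction = jitter(
        np.array([math.cos(a := rng.uniform(0, 2 * math.pi)), math.sin(a), 0.0]), 0.2
    )

    segments: list[Segment] = []
    # queue entries: (parent index, start point, direction, radius, generation)
    queue = [(-1, start, direction, r_hi, 1)]
    while queue:
        parent, p0, d, r, gen = queue.pop(0)
        length = seg_len * rng.uniform(0.8, 1.2)
        p1 = clamp(p0 + length * jitter(d, params.tortuosity))
        idx = len(segments)
        segments.append(Segment(tuple(p0), tuple(p1), float(r), parent))
        if gen >= params.depth:
            continue
        force_branch = gen == 1 and params.depth >= 2
        n_children = 2 if (force_branch or rng.uniform() < params.branch_prob) else 1
        new_dir = _unit(p1 - p0)
        for c in range(n_children):
            if n_children == 2:
                ang = rng.uniform(0.35, 0.9) * (1 if c == 0 else -1)
                ca, sa = math.cos(ang), math.sin(ang)
                rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
                child_dir = jitter(rot @ new_dir, 0.1)
            else:
                child_dir = jitter(new_dir, params.tortuosity)
            child_r = max(r_lo, r * rng.uniform(0.65, 0.85))
            queue.append((idx, p1, child_dir, child_r, gen + 1))
    return VesselTree(segments)


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------


def rasterize_tree(tree: VesselTree, grid: Grid3D) -> tuple[Volume, BinaryMask]:
    """Rasterise a vessel tree onto a grid.

    A voxel belongs to the mask iff its centre lies within the segment radius
    of some segment axis (exact physical point-to-segment distance); the
    intensity image carries value 1 inside the vessel with a linear edge
    decaying to 0 over one voxel (the largest spacing) beyond the surface.
    """
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    edge = float(spacing.max())
    vol = np.zeros(grid.shape, dtype=np.float32)
    mask = np.zeros(grid.shape, dtype=np.uint8)

    for seg in tree.segments:
        a = np.asarray(seg.start)
        b = np.asarray(seg.end)
        r = seg.radius
        pad = r + edge
        lo_idx = np.floor((np.minimum(a, b) - pad - origin) / spacing).astype(int)
        hi_idx = np.ceil((np.maximum(a, b) + pad - origin) / spacing).astype(int)
        lo_idx = np.clip(lo_idx, 0, np.asarray(grid.shape) - 1)
        hi_idx = np.clip(hi_idx, 0, np.asarray(grid.shape) - 1)
        if np.any(lo_idx > hi_idx):
            continue
        sl = tuple(slice(l, h + 1) for l, h in zip(lo_idx, hi_idx))
        axes = [
            origin[d] + np.arange(lo_idx[d], hi_idx[d] + 1) * spacing[d] for d in range(3)
        ]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        P = np.stack([X, Y, Z], axis=-1)
        v = b - a
        vv = float(v @ v)
        if vv == 0.0:
            d = np.linalg.norm(P - a, axis=-1)
        else:
            t = np.clip(((P - a) @ v) / vv, 0.0, 1.0)
            d = np.linalg.norm(P - (a + t[..., None] * v), axis=-1)
        mask[sl] |= (d <= r).astype(np.uint8)
        contrib = np.clip((r + edge - d) / edge, 0.0, 1.0)
        np.maximum(vol[sl], contrib.astype(np.float32), out=vol[sl])

    return Volume(grid, vol), BinaryMask(grid, mask)


# ---------------------------------------------------------------------------
# imaging model and ground-truth transforms
# ---------------------------------------------------------------------------


def apply_imaging_model(
    clean: Volume, params: ImagingParams = ImagingParams(), seed: int = 0
) -> Volume:
    """Apply gain, depth-dependent fluence decay, background and noise."""
    z_mm = (clean.grid.coordinate_arrays()[2] - clean.grid.origin[2]) / 1000.0
    decay = np.exp(-params.depth_decay_per_mm * z_mm).astype(np.float32)
    out = params.background_level + params.gain * clean.values * decay[None, None, :]
    if params.gaussian_noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, params.gaussian_noise_sd, size=out.shape)
    return Volume(clean.grid, out.astype(np.float32))


def sample_affine(
    max_translation_um: float | tuple[float, float, float],
    max_rotation_rad: float,
    seed: int = 0,
    centre: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> AffineTransform3D:
    """Draw a random rigid transform (rotation about the depth axis).

    Rotation emulates in-plane repositioning of the scan head: an angle drawn
    uniformly in ``[-max_rotation_rad, max_rotation_rad]`` about the z axis
    through ``centre``, composed with a uniform 3D translation bounded
    per-component by ``max_translation_um``.
    """
    bounds = np.broadcast_to(np.asarray(max_translation_um, dtype=float), (3,))
    if np.any(bounds < 0) or max_rotation_rad < 0:
        raise ValueError("bounds must be >= 0")
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-max_rotation_rad, max_rotation_rad)
    t = rng.uniform(-bounds, bounds)
    ca, sa = math.cos(angle), math.sin(angle)
    R = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    return AffineTransform3D.rigid_about_centre(R, t, centre)


def sample_smooth_deformation(
    grid: Grid3D,
    amplitude_um: float,
    smoothness_scale_um: float,
    seed: int = 0,
) -> DenseDisplacementField:
    """Draw a smooth random displacement field (longitudinal-growth stand-in).

    Gaussian white noise per component is low-pass filtered at
    ``smoothness_scale_um`` and rescaled so the maximum displacement
    magnitude equals ``amplitude_um``; stored in voxel units of ``grid``.
    """
    if amplitude_um < 0:
        raise ValueError("amplitude must be >= 0")
    vectors = np.zeros(grid.shape + (3,), dtype=np.float32)
    if amplitude_um > 0:
        rng = np.random.default_rng(seed)
        spacing = np.asarray(grid.spacing)
        sigmas = smoothness_scale_um / spacing
        u_phys = np.empty(grid.shape + (3,), dtype=float)
        for c in range(3):
            u_phys[..., c] = gaussian_filter(
                rng.normal(size=grid.shape), sigma=sigmas, mode="nearest"
            )
        mags = np.linalg.norm(u_phys, axis=-1)
        # scale so the median magnitude is half the amplitude (the typical
        # displacement), then clamp larger vectors so max |u| <= amplitude
        med = float(np.median(mags))
        if med > 0:
            u_phys *= 0.5 * amplitude_um / med
        mags = np.linalg.norm(u_phys, axis=-1)
        over = mags > amplitude_um
        if np.any(over):
            u_phys[over] *= (amplitude_um / mags[over])[:, None]
        vectors = (u_phys / spacing).astype(np.float32)
    return DenseDisplacementField(grid, vectors)


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------


def _transform_point(
    gt: AffineTransform3D | DenseDisplacementField, p: np.ndarray
) -> np.ndarray:
    if isinstance(gt, AffineTransform3D):
        return gt.apply(p)
    return p + gt.displacement_at(p.reshape(1, 3))[0]


def _transform_tree(
    gt: AffineTransform3D | DenseDisplacementField, tree: VesselTree
) -> VesselTree:
    segs = []
    for s in tree.segments:
        segs.append(
            Segment(
                tuple(_transform_point(gt, np.asarray(s.start))),
                tuple(_transform_point(gt, np.asarray(s.end))),
                s.radius,
                s.parent,
            )
        )
    return VesselTree(segs)


def _dropout_and_sprout(
    tree: VesselTree,
    dropout_fraction: float,
    extra_vessel_count: int,
    rng: np.random.Generator,
    domain: Grid3D,
) -> tuple[VesselTree, list[int]]:
    """Remove terminal segments and sprout new ones.

    Only terminals whose parent keeps at least one other child are eligible
    (at most one drop per parent), so branch points deeper in the tree
    survive and the terminal count changes by exactly the dropped number.
    Returns the edited tree and, for each new segment, the original index it
    maps to (-1 for sprouts).
    """
    n = len(tree.segments)
    children = tree.children()
    terminals = tree.terminal_indices()
    n_drop = len(terminals) - round((1.0 - dropout_fraction) * len(terminals))
    dropped: set[int] = set()
    if n_drop > 0:
        order = rng.permutation(len(terminals))
        used_parents: set[int] = set()
        for k in order:
            t = terminals[k]
            p = tree.segments[t].parent
            if p >= 0 and len(children[p]) >= 2 and p not in used_parents:
                dropped.add(t)
                used_parents.add(p)
                if len(dropped) == n_drop:
                    break

    keep = [i for i in range(n) if i not in dropped]
    remap = {old: new for new, old in enumerate(keep)}
    segs = [
        replace(tree.segments[i], parent=remap.get(tree.segments[i].parent, -1)
                if tree.segments[i].parent >= 0 else -1)
        for i in keep
    ]
    origin_of = list(keep)

    # sprout new terminal vessels from internal nodes so each adds one terminal
    internal = [remap[i] for i in keep if any(c in remap for c in children[i])]
    lo, hi = domain.bounds()
    for _ in range(extra_vessel_count):
        host_idx = int(internal[int(rng.integers(len(internal)))]) if internal else 0
        host = segs[host_idx]
        d = _unit(rng.normal(size=3) * np.array([1.0, 1.0, 0.2]))
        length = 0.35 * min(hi[0] - lo[0], hi[1] - lo[1]) / 5
        end = np.clip(np.asarray(host.end) + length * d, lo, hi)
        segs.append(
            Segment(host.end, tuple(end), max(host.radius * 0.7, 4.0), host_idx)
        )
        origin_of.append(-1)
    return VesselTree(segs), origin_of


def make_pair(
    tree: VesselTree,
    grid: Grid3D,
    transform_spec: AffineTransform3D | DenseDisplacementField | dict,
    variability: Variability = Variability(),
    imaging: ImagingParams = ImagingParams(),
    seed: int = 0,
) -> PhantomPair:
    """Build a fixed/moving phantom scan pair with exact ground truth.

    The fixed scan images ``tree``; the moving scan images the same network
    after terminal dropout/sprouting (biological variability), geometric
    transformation by the ground truth (rigid or smooth deformable, mapping
    fixed-space to moving-space coordinates) and an independent imaging-noise
    realisation with jittered gain. Landmarks are the branch points present
    in both networks (>= 3 required; regenerated up to 10 times).
    """
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        sub = rng.integers(0, 2**31 - 1, size=6)
        if isinstance(transform_spec, dict):
            spec = dict(transform_spec)
            kind = spec.pop("kind")
            if kind == "identity":
                gt: AffineTransform3D | DenseDisplacementField = AffineTransform3D.identity()
            elif kind == "rigid":
                gt = sample_affine(
                    spec.get("max_translation_um", (200.0, 200.0, 20.0)),
                    spec.get("max_rotation_rad", math.radians(10.0)),
                    seed=int(sub[0]),
                    centre=tuple(grid.centre),
                )
            elif kind == "smooth":
                gt = sample_smooth_deformation(
                    grid,
                    spec.get("amplitude_um", 40.0),
                    spec.get("smoothness_scale_um", 200.0),
                    seed=int(sub[0]),
                )
            else:
                raise ValueError(f"unknown transform kind {kind!r}")
        else:
            gt = transform_spec

        moving_tree, origin_of = _dropout_and_sprout(
            tree, variability.dropout_fraction, variability.extra_vessel_count, rng, grid
        )

        # branch points shared by both networks, in original segment indexing
        fixed_branches = {
            i for i, ch in tree.children().items() if len(ch) >= 2
        }
        moving_children = moving_tree.children()
        moving_branches_orig = {
            origin_of[i]
            for i, ch in moving_children.items()
            if len(ch) >= 2 and origin_of[i] >= 0
        }
        shared = sorted(fixed_branches & moving_branches_orig)
        if len(shared) < 3:
            continue

        fixed_clean, fixed_mask = rasterize_tree(tree, grid)
        moving_geo = _transform_tree(gt, moving_tree)
        moving_clean, moving_mask = rasterize_tree(moving_geo, grid)

        gain_factor = float(np.exp(rng.normal(0.0, variability.gain_sigma)))
        fixed_vol = apply_imaging_model(fixed_clean, imaging, seed=int(sub[1]))
        moving_imaging = replace(imaging, gain=imaging.gain * gain_factor)
        moving_vol = apply_imaging_model(moving_clean, moving_imaging, seed=int(sub[2]))

        lf = {}
        lm = {}
        for j, k in enumerate(shared):
            p = np.asarray(tree.segments[k].end)
            lf[f"L{j}"] = p
            lm[f"L{j}"] = _transform_point(gt, p)

        log = {
            "seed": int(seed),
            "attempt": attempt,
            "dropout_fraction": variability.dropout_fraction,
            "extra_vessel_count": variability.extra_vessel_count,
            "gain_factor": gain_factor,
            "noise_sd": imaging.gaussian_noise_sd,
            "imaging": asdict(imaging),
            "transform_kind": type(gt).__name__,
            "n_landmarks": len(shared),
            "fixed_terminal_count": len(tree.terminal_indices()),
            "moving_terminal_count": len(moving_tree.terminal_indices()),
        }
        return PhantomPair(
            fixed_volume=fixed_vol,
            fixed_mask=fixed_mask,
            moving_volume=moving_vol,
            moving_mask=moving_mask,
            gt_transform=gt,
            landmarks_fixed=LandmarkSet(lf),
            landmarks_moving=LandmarkSet(lm),
            log=log,
        )
    raise RuntimeError("could not generate a pair with >= 3 shared branch points in 10 attempts")
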