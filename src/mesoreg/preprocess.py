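"""Intensity pre-processing chain applied before registration.

The chain mirrors standard conditioning of photoacoustic mesoscopy stacks:
a high-pass filter along depth to remove slowly varying echo noise, a
slice-wise adaptive (Wiener) filter against stochastic noise, slice-wise
rolling-ball background removal, percentile clipping and slice-wise z-score
normalisation (so vessels at depth, where fluence has decayed, carry the
same weight as superficial ones). Mask conditioning (slice-wise dilation)
and depth-ROI selection are included here as well.

The canonical order is ``highpass -> wiener -> rolling_ball ->
clip_and_zscore``; each stage can be disabled via :class:`PreprocessConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation as _nd_binary_dilation
from scipy.signal import wiener as _wiener2
from skimage.morphology import disk, opening

from .core import BinaryMask, Grid3D, Volume

__all__ = [
    "PreprocessConfig",
    "highpass_filter",
    "wiener_filter",
    "rolling_ball",
    "clip_and_zscore",
    "dilate_mask_slicewise",
    "select_z_roi",
    "run_chain",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PreprocessConfig:
    """Stage parameters; ``None``/``False`` toggles disable a stage."""

    highpass_cutoff: float | None = 0.01  # fraction of Nyquist along z
    wiener_window: int = 3                # per-slice neighbourhood (voxels)
    rolling_ball_radius: int = 5          # per-slice structuring radius (pixels)
    clip_percentiles: tuple[float, float] = (0.05, 99.95)
    dilation_radius: int = 1              # per-slice mask dilation (pixels)
    enable_highpass: bool = True
    enable_wiener: bool = True
    enable_rolling_ball: bool = True
    enable_normalise: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.clip_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError("clip percentiles must satisfy 0 <= low < high <= 100")
        if self.rolling_ball_radius < 1 or self.dilation_radius < 1:
            raise ValueError("radii must be >= 1")
        if self.wiener_window < 3:
            raise ValueError("wiener window must be >= 3")


def highpass_filter(v: Volume, cutoff: float = 0.01) -> Volume:
    """Brick-wall FFT high-pass along the depth (z) axis.

    Frequencies strictly below ``cutoff`` (as a fraction of the Nyquist
    frequency) are removed, including the zero-frequency (mean) component;
    components above the cutoff pass with unit gain.
    """
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must be in (0, 1)")
    vals = v.values.astype(np.float64)
    nz = vals.shape[2]
    spec = np.fft.rfft(vals, axis=2)
    freqs = np.fft.rfftfreq(nz)          # cycles/sample; Nyquist = 0.5
    stop = freqs < cutoff * 0.5
    spec[:, :, stop] = 0.0
    out = np.fft.irfft(spec, n=nz, axis=2)
    return Volume(v.grid, out.astype(np.float32))


def wiener_filter(v: Volume, window: int = 3) -> Volume:
    """Slice-wise adaptive Wiener filter with an n-by-n neighbourhood.

    Per slice: ``out = mu + max(s2 - nu, 0) / max(s2, nu) * (in - mu)`` with
    local mean ``mu`` and variance ``s2`` over the window and noise power
    ``nu`` estimated as the slice-mean local variance (the classical
    adaptive choice).
    """
    if v.grid.shape[0] < window or v.grid.shape[1] < window:
        raise ValueError(f"each z-slice must be at least {window}x{window}")
    out = np.empty_like(v.values, dtype=np.float64)
    for k in range(v.grid.shape[2]):
        sl = v.values[:, :, k].astype(np.float64)
        if np.ptp(sl) == 0:  # constant slice: zero variance everywhere
            out[:, :, k] = sl
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                out[:, :, k] = _wiener2(sl, mysize=window)
    return Volume(v.grid, out.astype(np.float32))


def rolling_ball(v: Volume, radius: int = 5) -> Volume:
    """Slice-wise background removal by greyscale opening with a disk.

    The morphological opening (erosion then dilation with a flat disk of
    ``radius`` pixels) estimates the smooth background of each z-slice,
    which is then subtracted; features narrower than the disk survive.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    footprint = disk(radius)
    out = np.empty_like(v.values, dtype=np.float64)
    for k in range(v.grid.shape[2]):
        sl = v.values[:, :, k].astype(np.float64)
        out[:, :, k] = sl - opening(sl, footprint)
    return Volume(v.grid, out.astype(np.float32))


def clip_and_zscore(
    v: Volume, percentiles: tuple[float, float] = (0.05, 99.95)
) -> Volume:
    """Volume-wise percentile clipping followed by slice-wise z-scoring.

    Intensities are clipped to the given percentile range computed over the
    whole volume, then each z-slice is independently centred and scaled to
    unit standard deviation; constant slices map to zero.
    """
    lo, hi = np.percentile(v.values, percentiles)
    vals = np.clip(v.values.astype(np.float64), lo, hi)
    mu = vals.mean(axis=(0, 1), keepdims=True)
    sd = vals.std(axis=(0, 1), keepdims=True)
    out = (vals - mu) / np.maximum(sd, _EPS)
    out[:, :, (sd < _EPS).ravel()] = 0.0
    return Volume(v.grid, out.astype(np.float32))


def dilate_mask_slicewise(m: BinaryMask, radius: int = 1) -> BinaryMask:
    """Binary dilation of each z-slice with a flat disk footprint."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    footprint = disk(radius)
    out = np.empty_like(m.values)
    for k in range(m.grid.shape[2]):
        out[:, :, k] = _nd_binary_dilation(
            m.values[:, :, k].astype(bool), structure=footprint.astype(bool)
        )
    return BinaryMask(m.grid, out.astype(np.uint8))


def select_z_roi(v: Volume, m: BinaryMask) -> tuple[Volume, BinaryMask]:
    """Crop both arrays to the contiguous z-range containing mask signal.

    The grid origin is shifted so physical coordinates of retained voxels
    are unchanged.
    """
    if v.grid != m.grid:
        raise ValueError("volume and mask must share a grid")
    per_slice = m.values.any(axis=(0, 1))
    if not per_slice.any():
        raise ValueError("mask is empty; no z-ROI to select")
    z0 = int(np.argmax(per_slice))
    z1 = int(len(per_slice) - np.argmax(per_slice[::-1]))  # exclusive
    new_grid = Grid3D(
        (v.grid.shape[0], v.grid.shape[1], z1 - z0),
        v.grid.spacing,
        (v.grid.origin[0], v.grid.origin[1], v.grid.origin[2] + z0 * v.grid.spacing[2]),
    )
    return (
        Volume(new_grid, v.values[:, :, z0:z1]),
        BinaryMask(new_grid, m.values[:, :, z0:z1]),
    )


def threshold_segment(v: Volume, k_sd: float = 0.5, dilate: int = 3) -> BinaryMask:
    """Simple intensity-threshold segmentation (signal-ROI stand-in).

    Voxels brighter than ``mean + k_sd * sd`` of a lightly smoothed copy,
    dilated in 3D; used as a default signal region where no learned
    segmentation is available.
    """
    from scipy.ndimage import binary_dilation, gaussian_filter

    sm = gaussian_filter(v.values.astype(np.float32), 1.0)
    fg = sm > (sm.mean() + k_sd * sm.std())
    if dilate > 0:
        fg = binary_dilation(fg, iterations=dilate)
    return BinaryMask(v.grid, fg.astype(np.uint8))


def run_chain(v: Volume, cfg: PreprocessConfig = PreprocessConfig()) -> Volume:
    """Apply the enabled pre-processing stages in canonical order."""
    out = v
    if cfg.enable_highpass and cfg.highpass_cutoff is not None:
        out = highpass_filter(out, cfg.highpass_cutoff)
    if cfg.enable_wiener:
        out = wiener_filter(out, cfg.wiener_window)
    if cfg.enable_rolling_ball:
        out = rolling_ball(out, cfg.rolling_ball_radius)
    if cfg.enable_normalise:
        out = clip_and_zscore(out, cfg.clip_percentiles)
    return out
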