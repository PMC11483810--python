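"""Registration quality metrics and paired statistical comparison.

Segmentation metrics (Dice, symmetric average surface distance MD,
Hausdorff distance HD), intensity metrics (MI, SSIM), landmark TRE, the
pre/post percent-change convention, and the Wilcoxon + Holm-Bonferroni
machinery for comparing co-registration methods pairwise.

Surface distances use border voxels under 6-connectivity as the surface
definition and report physical µm. Percent change is relative:
``100 * (post - pre) / |pre|`` — positive means an increase (improvement
for Dice/MI/SSIM, worsening for MD/HD/TRE).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.ndimage import binary_erosion, uniform_filter
from scipy.spatial import cKDTree

from .core import BinaryMask, LandmarkSet, Volume

__all__ = [
    "dice",
    "surface_distances",
    "ssim",
    "tre",
    "percent_change",
    "wilcoxon_signed_rank",
    "holm_adjust",
    "compare_methods",
    "METRIC_DIRECTIONS",
]

#: +1 when an increase is an improvement, -1 when a decrease is
METRIC_DIRECTIONS = {"dice": +1, "md": -1, "hd": -1, "mi": +1, "ssim": +1, "tre": -1}


def dice(g: BinaryMask, f: BinaryMask) -> float:
    """Dice overlap 2|G n F| / (|G| + |F|)."""
    if g.grid.shape != f.grid.shape:
        raise ValueError("masks must share a grid shape")
    a = g.values.astype(bool)
    b = f.values.astype(bool)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / total


def _surface_points(m: BinaryMask) -> np.ndarray:
    """Physical coordinates (µm) of border voxels (6-connectivity)."""
    fg = m.values.astype(bool)
    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1, 1, :] = structure[1, :, 1] = structure[:, 1, 1] = True
    interior = binary_erosion(fg, structure=structure, border_value=0)
    border = fg & ~interior
    idx = np.argwhere(border)
    return m.grid.voxel_to_physical(idx)


def surface_distances(g: BinaryMask, f: BinaryMask) -> tuple[float, float]:
    """Symmetric average (MD) and Hausdorff (HD) surface distances in µm.

    MD pools both directed point-to-nearest-surface sums over the combined
    surface count; HD is the larger of the two directed maxima.
    """
    if g.foreground_count == 0 or f.foreground_count == 0:
        raise ValueError("both masks must be non-empty")
    gs = _surface_points(g)
    fs = _surface_points(f)
    d_g2f, _ = cKDTree(fs).query(gs)
    d_f2g, _ = cKDTree(gs).query(fs)
    md = (d_g2f.sum() + d_f2g.sum()) / (len(gs) + len(fs))
    hd = max(d_g2f.max(), d_f2g.max())
    return float(md), float(hd)


def ssim(f: Volume, g: Volume, window: int | None = 7) -> float:
    """Structural similarity with the two-term luminance/contrast-structure form.

    Local means, variances and cross-covariance over a cubic uniform window
    (whole-volume statistics when ``window`` is None); stabilising constants
    C1 = (0.01 L)^2, C2 = (0.03 L)^2 with L the dynamic range of the fixed
    image. Returns the mean of the local SSIM map.
    """
    if f.grid.shape != g.grid.shape:
        raise ValueError("volumes must share a grid shape")
    a = f.values.astype(np.float64)
    b = g.values.astype(np.float64)
    L = float(a.max() - a.min())
    if L == 0:
        L = 1.0
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    if window is None or window >= max(f.grid.shape):
        mu_a, mu_b = a.mean(), b.mean()
        va, vb = a.var(), b.var()
        cov = ((a - mu_a) * (b - mu_b)).mean()
    else:
        filt = lambda x: uniform_filter(x, size=window, mode="reflect")
        mu_a, mu_b = filt(a), filt(b)
        va = filt(a * a) - mu_a**2
        vb = filt(b * b) - mu_b**2
        cov = filt(a * b) - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
    return float(np.mean(num / den))


def tre(lf: LandmarkSet, lg_warped: LandmarkSet) -> float:
    """Mean Euclidean distance (µm) over shared landmark labels."""
    labels = lf.shared_labels(lg_warped)
    if not labels:
        raise ValueError("no shared landmark labels")
    d = np.linalg.norm(lf.as_array(labels) - lg_warped.as_array(labels), axis=1)
    return float(d.mean())


def percent_change(pre: float, post: float) -> float:
    """Relative change in percent: 100 * (post - pre) / |pre|."""
    if pre == 0:
        raise ValueError("percent change undefined for pre = 0")
    return 100.0 * (post - pre) / abs(pre)


def wilcoxon_signed_rank(x: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired deltas.

    Zero differences are dropped; the null distribution is enumerated
    exactly for n <= 15 (no ties), otherwise the normal approximation with
    tie correction is used. Needs >= 5 non-zero differences.
    """
    x = np.asarray(x, dtype=float)
    nz = x[x != 0]
    if nz.size == 0:
        raise ValueError("all differences are zero")
    if nz.size < 5:
        raise ValueError("need at least 5 non-zero differences")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 15 and not has_ties) else "approx"
    res = sstats.wilcoxon(nz, alternative="two-sided", method=method,
                          zero_method="wilcox")
    return float(res.pvalue)


def holm_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment with ``m`` total comparisons.

    ``adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j))`` over the
    ascending order statistics, returned in the original order. ``m``
    defaults to ``len(p)`` and may be larger (when only a subset of the
    family is supplied).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise ValueError("m must be >= the number of p-values")
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum((m - np.arange(len(p))) * p[order], 1.0)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


@dataclass(frozen=True)
class ComparisonRow:
    metric: str
    method_a: str
    method_b: str
    p_raw: float
    p_holm: float
    significant: bool


def compare_methods(
    reports: pd.DataFrame, alpha: float = 0.05, m: int = 10
) -> pd.DataFrame:
    """Pairwise Wilcoxon tests on percent-changes, Holm-adjusted.

    ``reports`` must carry columns ``pair``, ``method``, ``metric``,
    ``percent_change``. For every metric, each unordered pair of methods is
    tested on pair-matched percent-changes (C(5,2) = 10 comparisons for
    five methods); Holm adjustment uses ``m`` within each metric family and
    flags adjusted p-values below ``alpha``. Identical samples yield p = 1.
    """
    required = {"pair", "method", "metric", "percent_change"}
    if not required.issubset(reports.columns):
        raise ValueError(f"reports must have columns {sorted(required)}")
    rows: list[ComparisonRow] = []
    for metric, sub in reports.groupby("metric", sort=True):
        wide = sub.pivot_table(
            index="pair", columns="method", values="percent_change"
        )
        methods = sorted(wide.columns)
        combos = list(itertools.combinations(methods, 2))
        p_raw = []
        for a, b in combos:
            paired = wide[[a, b]].dropna()
            if len(paired) < 5:
                raise ValueError(
                    f"metric {metric!r}: fewer than 5 shared pairs for {a} vs {b}"
                )
            deltas = (paired[a] - paired[b]).to_numpy()
            try:
                p_raw.append(wilcoxon_signed_rank(deltas))
            except ValueError:  # identical samples
                p_raw.append(1.0)
        p_adj = holm_adjust(np.asarray(p_raw), m=max(m, len(p_raw)))
        for (a, b), pr, pa in zip(combos, p_raw, p_adj):
            rows.append(ComparisonRow(metric, a, b, float(pr), float(pa), bool(pa < alpha)))
    return pd.DataFrame([r.__dict__ for r in rows])
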