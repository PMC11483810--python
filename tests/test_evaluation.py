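"""Quality metrics and statistics against hand-worked and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mesoreg import evaluation as ev
from mesoreg.core import BinaryMask, Grid3D, LandmarkSet, Volume

from conftest import random_mask, random_volume


def _mask(vals, spacing=(20.0, 20.0, 20.0)):
    vals = np.asarray(vals, dtype=np.uint8)
    return BinaryMask(Grid3D(vals.shape, spacing), vals)


class TestDice:
    def test_identical_masks(self, rng):
        m = random_mask(rng)
        assert ev.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = 1
        b = np.zeros((4, 4, 4)); b[3, 3, 3] = 1
        assert ev.dice(_mask(a), _mask(b)) == 0.0

    def test_counting_example(self):
        # |G|=4, |F|=6, overlap 3 -> 2*3/10 = 0.6
        g = np.zeros((4, 4, 4)); g.ravel()[:4] = 1
        f = np.zeros((4, 4, 4)); f.ravel()[1:7] = 1
        assert ev.dice(_mask(g), _mask(f)) == pytest.approx(0.6)

    def test_symmetry(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert ev.dice(a, b) == ev.dice(b, a)


def _surface_points_bruteforce(m):
    """Independent border extraction: foreground with a 6-neighbour background."""
    fg = m.values.astype(bool)
    pts = []
    for idx in np.argwhere(fg):
        i, j, k = idx
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = idx + np.array(d)
            inside = (
                0 <= ni < fg.shape[0] and 0 <= nj < fg.shape[1] and 0 <= nk < fg.shape[2]
            )
            if not inside or not fg[ni, nj, nk]:
                pts.append(idx)
                break
    return m.grid.voxel_to_physical(np.asarray(pts))


def _surface_distances_bruteforce(g, f):
    gs = _surface_points_bruteforce(g)
    fs = _surface_points_bruteforce(f)
    d_g2f = np.array([np.linalg.norm(fs - p, axis=1).min() for p in gs])
    d_f2g = np.array([np.linalg.norm(gs - p, axis=1).min() for p in fs])
    md = (d_g2f.sum() + d_f2g.sum()) / (len(gs) + len(fs))
    return md, max(d_g2f.max(), d_f2g.max())


class TestSurfaceDistances:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng)
        md, hd = ev.surface_distances(m, m)
        assert md == 0.0 and hd == 0.0

    def test_two_single_voxels(self):
        a = np.zeros((8, 8, 3)); a[1, 1, 1] = 1
        b = np.zeros((8, 8, 3)); b[4, 1, 1] = 1  # 3 in-plane voxels = 60 µm
        md, hd = ev.surface_distances(_mask(a, (20, 20, 4)), _mask(b, (20, 20, 4)))
        assert md == pytest.approx(60.0)
        assert hd == pytest.approx(60.0)

    def test_matches_bruteforce_on_random_masks(self, rng):
        for _ in range(10):
            a = random_mask(rng, shape=(10, 10, 10), p=0.15)
            b = random_mask(rng, shape=(10, 10, 10), p=0.15)
            if a.foreground_count == 0 or b.foreground_count == 0:
                continue
            md, hd = ev.surface_distances(a, b)
            md_o, hd_o = _surface_distances_bruteforce(a, b)
            assert md == pytest.approx(md_o, abs=1e-9)
            assert hd == pytest.approx(hd_o, abs=1e-9)

    def test_md_not_exceeding_hd(self, rng):
        for _ in range(5):
            a = random_mask(rng, p=0.3)
            b = random_mask(rng, p=0.3)
            md, hd = ev.surface_distances(a, b)
            assert md <= hd + 1e-12


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        v = random_volume(rng, shape=(12, 12, 12))
        assert ev.ssim(v, v) == pytest.approx(1.0, abs=1e-9)

    def test_constant_offset_penalised(self, rng):
        v = random_volume(rng, shape=(12, 12, 12))
        L = float(v.values.max() - v.values.min())
        shifted = Volume(v.grid, v.values + L)
        assert ev.ssim(v, shifted) < 1.0

    def test_global_window_matches_closed_form(self, rng):
        f = random_volume(rng, shape=(5, 5, 5))
        g = random_volume(rng, shape=(5, 5, 5))
        a, b = f.values.astype(float), g.values.astype(float)
        L = a.max() - a.min()
        c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
        mu_a, mu_b = a.mean(), b.mean()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        expected = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
            (mu_a**2 + mu_b**2 + c1) * (a.var() + b.var() + c2)
        )
        assert ev.ssim(f, g, window=None) == pytest.approx(expected, rel=1e-12)


class TestTRE:
    def test_identical_sets_zero(self):
        l = LandmarkSet({"a": (1, 2, 3), "b": (4, 5, 6)})
        assert ev.tre(l, l) == 0.0

    def test_three_four_five_triangle(self):
        lf = LandmarkSet({"a": (0.0, 0.0, 0.0)})
        lg = LandmarkSet({"a": (60.0, 80.0, 0.0)})
        assert ev.tre(lf, lg) == pytest.approx(100.0)

    def test_transform_round_trip(self, rng):
        from mesoreg import phantom as ph

        t = ph.sample_affine(150.0, 0.2, seed=8)
        pts = {f"p{i}": rng.uniform(0, 1000, 3) for i in range(4)}
        l = LandmarkSet(pts)
        round_tripped = l.transform(t).transform(t.inverse())
        assert ev.tre(l, round_tripped) < 1e-9


class TestPercentChange:
    @pytest.mark.parametrize(
        "pre,post,expected", [(2.0, 3.0, 50.0), (3.0, 3.0, 0.0), (0.5, 0.1, -80.0)]
    )
    def test_examples(self, pre, post, expected):
        assert ev.percent_change(pre, post) == pytest.approx(expected)

    def test_zero_pre_rejected(self):
        with pytest.raises(ValueError):
            ev.percent_change(0.0, 1.0)


def _wilcoxon_enumeration(x):
    """Exact two-sided p by enumerating all sign assignments (no ties)."""
    x = np.asarray(x, float)
    x = x[x != 0]
    n = len(x)
    ranks = np.argsort(np.argsort(np.abs(x))) + 1.0
    w_obs = ranks[x > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, float)
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_six_positive_differences(self):
        p = ev.wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
        assert p == pytest.approx(2 / 64)

    def test_sign_symmetry(self, rng):
        x = rng.normal(size=9)
        assert ev.wilcoxon_signed_rank(x) == pytest.approx(ev.wilcoxon_signed_rank(-x))

    def test_matches_enumeration_at_n8(self, rng):
        for _ in range(5):
            x = rng.normal(size=8)
            assert ev.wilcoxon_signed_rank(x) == pytest.approx(_wilcoxon_enumeration(x))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ev.wilcoxon_signed_rank(np.zeros(6))


class TestHolm:
    def test_hand_worked_example(self):
        adj = ev.holm_adjust(np.array([0.01, 0.02, 0.04]), m=3)
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert ev.holm_adjust(np.array([0.2]), m=1)[0] == pytest.approx(0.2)

    def test_adjusted_bounds(self, rng):
        p = rng.uniform(size=10)
        adj = ev.holm_adjust(p, m=10)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_matches_statsmodels_when_m_equals_len(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=7)
        adj = ev.holm_adjust(p)
        _, adj_sm, _, _ = multipletests(p, method="holm")
        assert np.allclose(adj, adj_sm)


def _synthetic_reports(rng, n_pairs=12, methods=("a", "b", "c", "d", "e"), planted=None):
    rows = []
    for pid in range(n_pairs):
        for m in methods:
            delta = rng.normal()
            if planted and m == planted[0]:
                delta += planted[1]
            rows.append(
                {"pair": f"p{pid}", "method": m, "metric": "dice", "percent_change": delta}
            )
    return pd.DataFrame(rows)


class TestCompareMethods:
    def test_identical_methods_p_one(self, rng):
        df = _synthetic_reports(rng, methods=("a",))
        df2 = df.assign(method="b")
        table = ev.compare_methods(pd.concat([df, df2]))
        assert (table.p_raw == 1.0).all()
        assert not table.significant.any()

    def test_five_methods_ten_comparisons(self, rng):
        table = ev.compare_methods(_synthetic_reports(rng))
        assert len(table) == 10

    def test_planted_dominance_detected(self, rng):
        table = ev.compare_methods(_synthetic_reports(rng, planted=("a", 25.0)))
        a_rows = table[(table.method_a == "a") | (table.method_b == "a")]
        assert a_rows.significant.all()
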