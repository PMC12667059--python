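"""Pattern sums, D, block jackknife, f_dM windows, outlier calling."""

import math

import numpy as np
import pytest

from guenonflow.core import MISSING, PopulationMap
from guenonflow.introgression import (
    PatternSums,
    WindowStat,
    block_jackknife_d,
    d_statistic,
    fdm_windows,
    landscape_correlation,
    outlier_windows,
    site_patterns,
)

from conftest import make_gm


def quartet_gm(p_rows, **kw):
    """One diploid per role; build dosages 2*p for frequency vector columns."""
    G = (np.asarray(p_rows, dtype=float).T * 2).astype(np.int8)
    return make_gm(G, **kw)


class TestSitePatterns:
    def test_abba_site(self, quartet_pm):
        gm = quartet_gm([[0, 1, 1, 0]])
        ps = site_patterns(gm, quartet_pm)
        assert ps.ABBA == pytest.approx(1.0) and ps.BABA == pytest.approx(0.0)

    def test_baba_site(self, quartet_pm):
        gm = quartet_gm([[1, 0, 1, 0]])
        ps = site_patterns(gm, quartet_pm)
        assert ps.ABBA == pytest.approx(0.0) and ps.BABA == pytest.approx(1.0)

    def test_no_donor_derived_contributes_zero(self, quartet_pm):
        gm = quartet_gm([[0.5, 0.5, 0, 0]])
        ps = site_patterns(gm, quartet_pm)
        assert ps.ABBA == 0 and ps.BABA == 0 and ps.n_sites_used == 1

    def test_polymorphic_outgroup_skipped(self, quartet_pm):
        gm = quartet_gm([[0, 1, 1, 0.5]])
        ps = site_patterns(gm, quartet_pm)
        assert ps.n_sites_used == 0 and ps.n_sites_skipped == 1

    def test_outgroup_fixed_alt_polarity_flips(self, quartet_pm):
        # outgroup homozygous alt: ref is derived; P2,P3 hom-ref => ABBA
        gm = quartet_gm([[1, 0, 0, 1]])
        ps = site_patterns(gm, quartet_pm)
        assert ps.ABBA == pytest.approx(1.0) and ps.BABA == pytest.approx(0.0)

    def test_missing_role_site_unusable(self, quartet_pm):
        gm = make_gm([[0], [2], [2], [MISSING]])
        ps = site_patterns(gm, quartet_pm)
        assert ps.n_sites_used == 0

    def test_swapping_p1_p2_negates_d(self, quartet_pm):
        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, size=(4, 200)).astype(np.int8)
        gm = make_gm(G)
        swapped = PopulationMap(
            dict(quartet_pm.assignments),
            {"P1": "P2", "P2": "P1", "P3": "P3", "OUT": "OUT"},
        )
        d1 = d_statistic(site_patterns(gm, quartet_pm))
        d2 = d_statistic(site_patterns(gm, swapped))
        assert d1 == pytest.approx(-d2)


class TestDStatistic:
    def test_hand_arithmetic(self):
        assert d_statistic(PatternSums(6, 2, 8)) == pytest.approx(0.5)

    def test_symmetric_sums_give_zero(self):
        assert d_statistic(PatternSums(5, 5, 10)) == 0

    def test_degenerate_undefined(self):
        assert math.isnan(d_statistic(PatternSums(0, 0, 0)))

    def test_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.random(2) * 10
            assert abs(d_statistic(PatternSums(a, b, 1))) <= 1


class TestBlockJackknife:
    def test_identical_blocks_zero_se(self, quartet_pm):
        # same ABBA-heavy site repeated across 20 blocks
        n_blocks, per_block = 20, 5
        L = n_blocks * per_block
        pos = np.concatenate([
            np.arange(per_block) * 10 + b * 1000 + 1 for b in range(n_blocks)
        ])
        gm = quartet_gm([[0, 1, 1, 0]] * L, pos=pos)
        res = block_jackknife_d(gm, quartet_pm, block_size=1000)
        assert res.n_blocks == n_blocks
        assert res.SE == pytest.approx(0.0, abs=1e-12)
        assert res.D == pytest.approx(1.0)

    def test_too_few_blocks_raises(self, quartet_pm):
        gm = quartet_gm([[0, 1, 1, 0]] * 5, pos=np.arange(1, 6))
        with pytest.raises(ValueError, match="blocks"):
            block_jackknife_d(gm, quartet_pm, block_size=1_000_000)

    def test_block_size_invariance_on_homogeneous_data(self, quartet_pm):
        rng = np.random.default_rng(7)
        G = rng.integers(0, 3, size=(4, 400)).astype(np.int8)
        gm = make_gm(G, pos=np.arange(1, 401) * 25)
        d1 = block_jackknife_d(gm, quartet_pm, block_size=1000).D
        d2 = block_jackknife_d(gm, quartet_pm, block_size=500).D
        assert d1 == pytest.approx(d2)  # D is a ratio of totals


class TestFdmWindows:
    def test_hand_value_half(self, quartet_pm):
        # 100 identical sites p=(0, 0.5, 1, 0): numerator .5, denominator 1
        G = np.tile(np.array([[0], [1], [2], [0]], dtype=np.int8), (1, 100))
        gm = make_gm(G, pos=np.arange(1, 101) * 10)
        (w,) = fdm_windows(gm, quartet_pm, window=10_000, min_snps=100)
        assert w.f_dM == pytest.approx(0.5, abs=1e-12)
        assert w.n_snps == 100 and (w.start, w.end) == (0, 10_000)

    def test_99_snps_excluded_at_min_100(self, quartet_pm):
        G = np.tile(np.array([[0], [1], [2], [0]], dtype=np.int8), (1, 99))
        gm = make_gm(G, pos=np.arange(1, 100) * 10)
        assert fdm_windows(gm, quartet_pm, window=10_000, min_snps=100) == []
        assert len(fdm_windows(gm, quartet_pm, window=10_000, min_snps=99)) == 1

    def test_excess_sharing_with_p1_is_negative(self, quartet_pm):
        G = np.tile(np.array([[1], [0], [2], [0]], dtype=np.int8), (1, 50))
        gm = make_gm(G, pos=np.arange(1, 51) * 10)
        (w,) = fdm_windows(gm, quartet_pm, window=1000, min_snps=10)
        assert w.f_dM == pytest.approx(-0.5, abs=1e-12)

    def test_fdm_matches_d_sign_and_is_bounded(self, quartet_pm):
        rng = np.random.default_rng(11)
        for _ in range(30):
            G = rng.integers(0, 3, size=(4, 1)).astype(np.int8)
            G[3, 0] = rng.choice([0, 2])  # monomorphic outgroup
            gm = make_gm(G)
            ws = fdm_windows(gm, quartet_pm, window=100, min_snps=1)
            d = d_statistic(site_patterns(gm, quartet_pm))
            for w in ws:
                assert abs(w.f_dM) <= 1 + 1e-12
                if not math.isnan(d) and d != 0:
                    assert math.copysign(1, w.f_dM) == math.copysign(1, d)

    def test_windows_tile_and_do_not_overlap(self, quartet_pm):
        rng = np.random.default_rng(5)
        G = rng.integers(0, 3, size=(4, 500)).astype(np.int8)
        gm = make_gm(G, pos=np.sort(rng.choice(50_000, 500, replace=False)) + 1)
        ws = fdm_windows(gm, quartet_pm, window=5000, min_snps=5)
        assert all(w.end - w.start == 5000 for w in ws)
        spans = [(w.start, w.end) for w in ws]
        assert spans == sorted(spans)
        assert all(b >= a_end for (_, a_end), (b, _) in zip(spans, spans[1:]))


class TestLandscapeAndOutliers:
    def _windows(self, values):
        return [WindowStat("chr1", i * 10, (i + 1) * 10, 100, v)
                for i, v in enumerate(values)]

    def test_identity_gives_r_one(self):
        a = self._windows(np.random.default_rng(0).random(50))
        r, n = landscape_correlation(a, a)
        assert r == pytest.approx(1.0) and n == 50

    def test_negation_gives_r_minus_one(self):
        vals = np.random.default_rng(1).random(50)
        r, _ = landscape_correlation(self._windows(vals), self._windows(-vals))
        assert r == pytest.approx(-1.0)

    def test_only_shared_windows_used(self):
        vals = np.random.default_rng(2).random(30)
        a = self._windows(vals)
        r, n = landscape_correlation(a, a[:10])
        assert n == 10 and r == pytest.approx(1.0)

    def test_too_few_shared_raises(self):
        a = self._windows([0.1, 0.2])
        with pytest.raises(ValueError):
            landscape_correlation(a, a)

    def test_outlier_count_distinct_values(self):
        ws = self._windows(np.random.default_rng(3).permutation(1000))
        top = outlier_windows(ws, 99)
        assert len(top) == 10

    def test_all_ties_all_returned(self):
        ws = self._windows([0.5] * 20)
        assert len(outlier_windows(ws, 99)) == 20

    def test_threshold_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            vals = rng.normal(size=rng.integers(5, 400))
            ws = self._windows(vals)
            thr = float(np.percentile(vals, 99))
            expected = {i for i, v in enumerate(vals) if v >= thr}
            got = {w.start // 10 for w in outlier_windows(ws, 99)}
            assert got == expected
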