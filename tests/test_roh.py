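"""Scanning-window ROH caller: thresholds, normalization, summaries."""

import numpy as np
import pytest

from guenonflow.core import MISSING
from guenonflow.roh import (
    ROHParams,
    ROHSegment,
    ROHSummary,
    accessible_length,
    call_roh,
    roh_count_length_correlation,
    summarize_roh,
)
from guenonflow.simulate import simulate_roh_genome

from conftest import make_gm


def hom_gm(pos, het_at=(), missing_at=()):
    """Single-sample matrix: homozygous everywhere except listed indices."""
    dose = np.zeros(len(pos), dtype=np.int8)
    dose[list(het_at)] = 1
    dose[list(missing_at)] = MISSING
    return make_gm([dose], pos=np.asarray(pos))


class TestThresholds:
    def test_min_snps_rule(self):
        # 99 perfectly homozygous SNPs spanning 150 kb: fails min_snps=100
        pos = np.linspace(1, 150_001, 99).astype(int)
        assert call_roh(hom_gm(pos)) == []
        pos = np.linspace(1, 150_001, 100).astype(int)
        segs = call_roh(hom_gm(pos))
        assert len(segs) == 1 and segs[0].n_snps == 100

    def test_min_length_rule(self):
        # 100 SNPs spanning only 50 kb: dense enough but too short
        pos = np.linspace(1, 50_001, 120).astype(int)
        assert call_roh(hom_gm(pos)) == []

    def test_density_rule(self):
        # 100 SNPs over 6 Mb: 60 kb per SNP, sparser than 1 SNP / 50 kb
        pos = np.linspace(1, 6_000_001, 100).astype(int)
        assert call_roh(hom_gm(pos)) == []
        # same span with 150 SNPs (40 kb per SNP) passes
        pos = np.linspace(1, 6_000_001, 150).astype(int)
        assert len(call_roh(hom_gm(pos))) == 1

    def test_gap_rule_splits_runs(self):
        # two dense homozygous stretches separated by a 1.2 Mb gap
        left = np.arange(1, 300_002, 1000)
        right = left + 300_001 + 1_200_000
        segs = call_roh(hom_gm(np.concatenate([left, right])))
        assert len(segs) == 2
        assert segs[0].end <= left[-1] and segs[1].start >= right[0] - 1

    def test_gap_rule_boundary_kept(self):
        # a gap of exactly max_gap_bp does not split
        left = np.arange(1, 300_002, 1000)
        right = left + 300_001 + 1_000_000
        pos = np.concatenate([left, right])
        segs = call_roh(hom_gm(pos))
        # still one run, but density over the gap region decides emission
        assert sum(s.n_snps for s in segs) >= len(left)

    def test_missing_genotypes_do_not_break_runs(self):
        pos = np.arange(1, 300_002, 1000)
        segs_clean = call_roh(hom_gm(pos))
        segs_missing = call_roh(hom_gm(pos, missing_at=range(100, 120)))
        assert len(segs_clean) == len(segs_missing) == 1
        assert segs_missing[0].length >= 250_000

    def test_scattered_hets_break_calls(self):
        # every 10th SNP heterozygous: scanning windows never compatible
        pos = np.arange(1, 500_002, 1000)
        segs = call_roh(hom_gm(pos, het_at=range(0, len(pos), 10)))
        assert segs == []

    def test_single_het_tolerated_inside_long_run(self):
        pos = np.arange(1, 500_002, 1000)
        segs = call_roh(hom_gm(pos, het_at=[250]))
        assert len(segs) == 1 and segs[0].n_het == 1

    def test_raising_min_len_monotone(self):
        gm, _ = simulate_roh_genome(
            seed=5, chrom_len=4_000_000, tracts=[(500_000, 900_000),
                                                 (2_000_000, 3_500_000)],
        )
        counts = [
            len(call_roh(gm, ROHParams(min_len_bp=m)))
            for m in (100_000, 500_000, 1_000_000, 2_000_000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_emitted_segments_satisfy_all_invariants(self):
        params = ROHParams()
        for seed in range(4):
            gm, _ = simulate_roh_genome(
                seed=seed, chrom_len=3_000_000, het_rate=0.25,
                tracts=[(1_000_000, 1_600_000)], error_het_rate=0.01,
            )
            for s in call_roh(gm, params):
                assert s.length >= params.min_len_bp
                assert s.n_snps >= params.min_snps
                assert s.length / s.n_snps <= params.min_density_bp_per_snp


class TestAccessibleLength:
    def test_dense_sites_cover_span(self):
        pos = np.arange(1, 2_000_002, 500)
        gm = hom_gm(pos, het_at=range(0, len(pos), 3))
        acc = accessible_length(gm)
        assert acc == pytest.approx(2_000_000, rel=0.01)

    def test_snp_desert_excluded(self):
        left = np.arange(1, 500_002, 500)
        right = left + 500_001 + 2_000_000
        gm = hom_gm(np.concatenate([left, right]), het_at=range(0, 100, 2))
        acc = accessible_length(gm)
        assert acc < 1_100_000  # the 2 Mb desert cannot be accessible

    def test_fully_homozygous_fixed_point(self):
        pos = np.arange(1, 1_000_002, 500)
        gm = hom_gm(pos)
        segs = call_roh(gm)
        acc = accessible_length(gm)
        assert acc == sum(s.length for s in segs) > 0
        summary = summarize_roh(segs, acc)
        assert summary.f_short + summary.f_long == pytest.approx(1.0)


class TestSummaries:
    def _seg(self, length, start=0):
        return ROHSegment("s", "chr1", start, start + length, 200, 0)

    def test_short_fraction_arithmetic(self):
        s = summarize_roh([self._seg(500_000)], 10_000_000)
        assert s.f_short == pytest.approx(0.05) and s.f_long == 0

    def test_long_fraction_arithmetic(self):
        s = summarize_roh([self._seg(2_000_000)], 10_000_000)
        assert s.f_short == 0 and s.f_long == pytest.approx(0.2)

    def test_boundary_1mb_counts_as_short(self):
        s = summarize_roh([self._seg(1_000_000)], 10_000_000)
        assert s.f_short == pytest.approx(0.1) and s.f_long == 0

    def test_empty_segments(self):
        s = summarize_roh([], 10_000_000, sample="x")
        assert s.f_short == s.f_long == 0 and s.n_roh == 0

    def test_zero_accessible_raises(self):
        with pytest.raises(ValueError):
            summarize_roh([], 0)


class TestCountLengthCorrelation:
    def _summary(self, n, total):
        return ROHSummary("s", n, total, 10 * total + 1, 0.0, 0.0)

    def test_perfect_linearity(self):
        s = [self._summary(n, 300_000 * n) for n in (1, 3, 5, 9)]
        r, p = roh_count_length_correlation(s)
        assert r == pytest.approx(1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(8)
        n = rng.integers(1, 100, 20)
        tot = rng.integers(100_000, 10_000_000, 20)
        s = [self._summary(int(a), int(b)) for a, b in zip(n, tot)]
        r, _ = roh_count_length_correlation(s)
        x, y = n.astype(float), tot.astype(float)
        oracle = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum()
                            * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_two_samples_raise(self):
        with pytest.raises(ValueError):
            roh_count_length_correlation(
                [self._summary(1, 100), self._summary(2, 200)]
            )


class TestPlantedRecovery:
    def test_planted_tract_recovered(self):
        tract = (1_000_000, 1_500_000)
        gm, truth = simulate_roh_genome(
            seed=1, chrom_len=4_000_000, snp_density=1 / 500, het_rate=0.3,
            tracts=[tract],
        )
        segs = call_roh(gm)
        assert len(segs) == 1
        (s,) = segs
        # boundaries within one expected inter-SNP interval (~500 bp, allow slack)
        assert abs(s.start - tract[0]) < 10_000
        assert abs(s.end - tract[1]) < 10_000

    def test_no_tracts_no_long_calls(self):
        gm, _ = simulate_roh_genome(seed=2, chrom_len=3_000_000, het_rate=0.15,
                                    tracts=[])
        assert call_roh(gm) == []

    def test_zero_het_rate_one_run(self):
        gm, _ = simulate_roh_genome(seed=3, chrom_len=1_000_000, het_rate=0.0,
                                    tracts=[])
        segs = call_roh(gm)
        assert len(segs) == 1
        assert segs[0].length > 900_000
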