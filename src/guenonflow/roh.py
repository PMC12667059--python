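"""Runs of homozygosity by plink-style scanning-window detection.

The caller follows the classic scanning-window parameterization:
windows of ``scan_window_snps`` consecutive SNPs slide along the
(missing-genotype-free) site list; a window is homozygous-compatible
if it contains at most ``max_het_per_window`` heterozygous calls; a
SNP is a "hit" if at least ``hit_fraction`` of the windows overlapping
it are compatible. Maximal runs of hit SNPs, split at inter-SNP gaps
larger than ``max_gap_bp``, are emitted as segments when they pass all
thresholds simultaneously: minimum length, minimum SNP count, and
minimum SNP density. Segment endpoints are the first and last SNP
positions of the run (SNP-delimited).

Missing genotypes are removed from the site list before scanning, so
missing calls cannot break an otherwise homozygous run.

The accessible-genome denominator is obtained by converting every
heterozygous genotype to homozygous and re-running the same caller:
the total ROH length callable on that artificial genome is the
fraction denominator, so a fully homozygous sample has ROH fraction
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import MISSING, GenotypeMatrix


@dataclass
class ROHParams:
    """Thresholds of the scanning-window ROH caller (plink-style defaults)."""

    min_len_bp: int = 100_000
    min_snps: int = 100
    max_het_per_window: int = 1
    scan_window_snps: int = 50
    hit_fraction: float = 0.05
    min_density_bp_per_snp: int = 50_000
    max_gap_bp: int = 1_000_000

    def validate(self) -> None:
        if min(self.min_len_bp, self.min_snps, self.scan_window_snps,
               self.min_density_bp_per_snp, self.max_gap_bp) <= 0:
            raise ValueError("all ROH thresholds must be positive")
        if not 0 < self.hit_fraction <= 1:
            raise ValueError("hit_fraction must be in (0, 1]")


@dataclass
class ROHSegment:
    """One called run of homozygosity (bp coordinates, half-open)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ROHSummary:
    """Per-sample ROH burden with the accessible-genome denominator."""

    sample: str
    n_roh: int
    total_len_bp: int
    accessible_len_bp: int
    f_short: float  # 100 kb <= len <= 1 Mb
    f_long: float   # len > 1 Mb


def _hit_states(is_het: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP hit state from overlapping scanning windows.

    When fewer SNPs than one window exist, the whole run is evaluated
    as a single (short) window.
    """
    n = len(is_het)
    w = min(params.scan_window_snps, n)
    n_win = n - w + 1
    het = is_het.astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(het)])
    win_het = csum[w:] - csum[:-w]  # hets in window starting at i
    compatible = (win_het <= params.max_het_per_window).astype(np.int64)
    # windows overlapping SNP j start in [j - w + 1, j], clipped to [0, n_win)
    ccomp = np.concatenate([[0], np.cumsum(compatible)])
    j = np.arange(n)
    lo = np.clip(j - w + 1, 0, n_win)
    hi = np.clip(j + 1, 0, n_win)
    n_overlap = hi - lo
    n_comp = ccomp[hi] - ccomp[lo]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_overlap > 0, n_comp / n_overlap, 0.0)
    return frac >= params.hit_fraction


def _runs(mask: np.ndarray):
    """Yield (start_idx, end_idx_exclusive) of maximal True runs."""
    d = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return zip(starts, ends)


def call_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH segments on a single-sample genotype matrix."""
    if gm.n_samples != 1:
        raise ValueError("call_roh operates on a single-sample matrix")
    params = params or ROHParams()
    params.validate()
    sample = gm.samples[0]
    segments: list[ROHSegment] = []
    for c in gm.chromosomes():
        on_c = gm.chrom == c
        dose = gm.G[0, on_c]
        pos = gm.pos[on_c]
        keep = dose != MISSING  # missing genotypes excluded before scanning
        dose, pos = dose[keep], pos[keep]
        if len(pos) == 0:
            continue
        is_het = dose == 1
        hits = _hit_states(is_het, params)
        for i0, i1 in _runs(hits):
            # split candidate runs at gaps exceeding max_gap_bp
            run_pos = pos[i0:i1]
            run_het = is_het[i0:i1]
            gap_break = np.flatnonzero(np.diff(run_pos) > params.max_gap_bp)
            bounds = np.concatenate([[0], gap_break + 1, [len(run_pos)]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                piece_pos = run_pos[a:b]
                n_snps = len(piece_pos)
                if n_snps < params.min_snps:
                    continue
                start = int(piece_pos[0]) - 1  # half-open bp interval
                end = int(piece_pos[-1])
                length = end - start
                if length < params.min_len_bp:
                    continue
                if length / n_snps > params.min_density_bp_per_snp:
                    continue
                segments.append(ROHSegment(
                    sample=sample, chrom=str(c), start=start, end=end,
                    n_snps=n_snps, n_het=int(run_het[a:b].sum()),
                ))
    return segments


def accessible_length(gm: GenotypeMatrix, params: ROHParams | None = None) -> int:
    """Accessible-genome denominator: total ROH length on the
    het-to-hom transformed genotypes of the same site list."""
    if gm.n_samples != 1:
        raise ValueError("accessible_length operates on a single-sample matrix")
    hom = gm.copy()
    hom.G[hom.G == 1] = 2
    return sum(seg.length for seg in call_roh(hom, params))


_SHORT_MIN = 100_000
_SHORT_MAX = 1_000_000


def summarize_roh(
    segments: list[ROHSegment], accessible_len_bp: int, sample: str | None = None
) -> ROHSummary:
    """Per-sample genome fractions in short (100 kb - 1 Mb, inclusive)
    and long (> 1 Mb) ROH, over the accessible-genome denominator."""
    if accessible_len_bp <= 0:
        raise ValueError("accessible length must be positive")
    if sample is None:
        sample = segments[0].sample if segments else "NA"
    lens = np.array([s.length for s in segments], dtype=np.int64)
    short = int(lens[(lens >= _SHORT_MIN) & (lens <= _SHORT_MAX)].sum()) if len(lens) else 0
    long_ = int(lens[lens > _SHORT_MAX].sum()) if len(lens) else 0
    return ROHSummary(
        sample=sample, n_roh=len(segments), total_len_bp=int(lens.sum()) if len(lens) else 0,
        accessible_len_bp=int(accessible_len_bp),
        f_short=short / accessible_len_bp, f_long=long_ / accessible_len_bp,
    )


def roh_count_length_correlation(summaries: list[ROHSummary]) -> tuple[float, float]:
    """Pearson r (with two-sided t-based p) between ROH count and total
    length across samples; the relationship's strength distinguishes
    many-short-ROH from few-long-ROH demographies."""
    if len(summaries) < 3:
        raise ValueError("need >=3 samples for a correlation")
    x = np.array([s.n_roh for s in summaries], dtype=float)
    y = np.array([s.total_len_bp for s in summaries], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in ROH count or total length")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def write_segments_tsv(segments: list[ROHSegment], path) -> None:
    with open(str(path), "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tlength\tn_snps\tn_het\n")
        for s in segments:
            fh.write(f"{s.sample}\t{s.chrom}\t{s.start}\t{s.end}\t"
                     f"{s.length}\t{s.n_snps}\t{s.n_het}\n")


def write_summary_tsv(summaries: list[ROHSummary], path) -> None:
    with open(str(path), "w") as fh:
        fh.write("sample\tn_roh\ttotal_len_bp\taccessible_len_bp\tf_short\tf_long\n")
        for s in summaries:
            fh.write(f"{s.sample}\t{s.n_roh}\t{s.total_len_bp}\t"
                     f"{s.accessible_len_bp}\t{s.f_short:.6g}\t{s.f_long:.6g}\n")
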