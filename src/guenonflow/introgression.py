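"""Four-taxon introgression statistics.

Implements the frequency-weighted ABBA-BABA D statistic with a
weighted block jackknife, the windowed f_dM admixture-proportion
statistic in non-overlapping windows, landscape correlation between
two window sets, and percentile-outlier window calling.

Polarization convention: a site is usable only where the outgroup is
monomorphic and at least one genotype per role is called; the outgroup
allele is ancestral, and per-population derived-allele frequencies
p1, p2, p3, p4 are computed from non-missing dosages. The pattern sums
are the frequency products

    ABBA += (1 - p1) * p2 * p3 * (1 - p4)
    BABA += p1 * (1 - p2) * p3 * (1 - p4)

and D = (ABBA - BABA) / (ABBA + BABA).

f_dM uses the symmetric dynamic-donor denominator: at sites with
p2 >= p1 the donor frequency is PD = max(p2, p3) and the denominator
term is the ABBA-BABA numerator with both P2 and P3 replaced by PD;
at sites with p1 > p2, PD = max(p1, p3) replaces P1 and P3 and the
term enters with a negative sign. This bounds f_dM in [-1, 1] and
makes it symmetric in excess sharing with P1 versus P2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)


@dataclass
class PatternSums:
    """Accumulated ABBA/BABA pattern sums over usable sites."""

    ABBA: float
    BABA: float
    n_sites_used: int
    n_sites_skipped: int = 0  # polymorphic/missing outgroup or missing role


@dataclass
class DResult:
    """Genome-wide D with weighted block-jackknife uncertainty."""

    D: float
    SE: float
    Z: float
    n_blocks: int
    abba: float
    baba: float
    n_sites_used: int


@dataclass
class WindowStat:
    """One genomic window's f_dM summary (coordinates 0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    f_dM: float
    numerator: float = 0.0
    denominator: float = 0.0


def _role_freqs(gm: GenotypeMatrix, pm: PopulationMap):
    """Per-site alt-allele frequencies and call-counts for each role.

    Returns (freqs, n_called) as dicts role -> (L,) arrays; freq is nan
    where no genotype of that role is called.
    """
    freqs, called = {}, {}
    for role in ("P1", "P2", "P3", "OUT"):
        samples = [s for s in pm.role_samples(role) if s in gm.samples]
        if not samples:
            raise ValueError(f"role {role} has no samples in the matrix")
        idx = [gm.sample_index(s) for s in samples]
        sub = gm.G[idx, :].astype(np.float64)
        miss = sub == MISSING
        sub[miss] = 0.0
        n_al = 2.0 * (~miss).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs[role] = np.where(n_al > 0, sub.sum(axis=0) / n_al, np.nan)
        called[role] = n_al
    return freqs, called


def _usable_and_derived(gm: GenotypeMatrix, pm: PopulationMap):
    """Derived-allele frequencies p1..p4 at usable sites.

    A site is usable iff every role has >=1 called genotype and the
    outgroup is monomorphic. The outgroup allele is ancestral, so the
    derived frequency is the alt frequency where the outgroup is
    fixed-ref, and 1 - alt frequency where it is fixed-alt.
    """
    freqs, called = _role_freqs(gm, pm)
    have_all = np.ones(gm.n_sites, dtype=bool)
    for role in ("P1", "P2", "P3", "OUT"):
        have_all &= called[role] > 0
    out_f = freqs["OUT"]
    mono = have_all & ((out_f == 0.0) | (out_f == 1.0))
    flip = out_f == 1.0  # outgroup fixed for alt: ref is derived
    ps = []
    for role in ("P1", "P2", "P3", "OUT"):
        p = freqs[role]
        ps.append(np.where(flip, 1.0 - p, p))
    n_skipped = int(have_all.sum() - mono.sum())
    return mono, ps, n_skipped


def site_patterns(gm: GenotypeMatrix, pm: PopulationMap) -> PatternSums:
    """Accumulate frequency-weighted ABBA and BABA sums genome-wide."""
    pm.validate(gm)
    usable, (p1, p2, p3, p4), n_skipped = _usable_and_derived(gm, pm)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return PatternSums(
        ABBA=float(np.nansum(abba[usable])),
        BABA=float(np.nansum(baba[usable])),
        n_sites_used=int(usable.sum()),
        n_sites_skipped=n_skipped,
    )


def d_statistic(ps: PatternSums) -> float:
    """D = (ABBA - BABA) / (ABBA + BABA); nan when both sums are zero."""
    tot = ps.ABBA + ps.BABA
    if tot == 0:
        return math.nan
    return (ps.ABBA - ps.BABA) / tot


def block_jackknife_d(
    gm: GenotypeMatrix, pm: PopulationMap, block_size: int = 1_000_000
) -> DResult:
    """Genome-wide D with a weighted delete-one-block jackknife.

    Blocks are contiguous ``block_size``-bp tiles per chromosome;
    empty blocks are dropped. The jackknife is weighted by per-block
    informative-site counts (delete-m_j jackknife), so unequal block
    information contents are handled correctly. Z = D / SE.
    """
    pm.validate(gm)
    usable, (p1, p2, p3, p4), _ = _usable_and_derived(gm, pm)
    abba_s = np.where(usable, (1 - p1) * p2 * p3 * (1 - p4), 0.0)
    baba_s = np.where(usable, p1 * (1 - p2) * p3 * (1 - p4), 0.0)
    abba_s = np.nan_to_num(abba_s)
    baba_s = np.nan_to_num(baba_s)

    block_abba, block_baba, block_m = [], [], []
    for c in gm.chromosomes():
        on_c = gm.chrom == c
        pos0 = gm.pos[on_c] - 1
        bidx = pos0 // block_size
        for b in np.unique(bidx):
            sel = on_c.copy()
            sel[on_c] = bidx == b
            m = int(usable[sel].sum())
            if m == 0:
                continue
            block_abba.append(abba_s[sel].sum())
            block_baba.append(baba_s[sel].sum())
            block_m.append(m)
    g = len(block_m)
    if g < 2:
        raise ValueError("block jackknife needs >=2 non-empty blocks")
    if g < 20:
        logger.warning("block jackknife with only %d blocks; SE may be noisy", g)
    block_abba = np.array(block_abba)
    block_baba = np.array(block_baba)
    m = np.array(block_m, dtype=np.float64)

    tot_abba, tot_baba = block_abba.sum(), block_baba.sum()
    if tot_abba + tot_baba == 0:
        return DResult(math.nan, math.nan, math.nan, g, 0.0, 0.0, 0)
    theta = (tot_abba - tot_baba) / (tot_abba + tot_baba)

    loo_abba = tot_abba - block_abba
    loo_baba = tot_baba - block_baba
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_j = (loo_abba - loo_baba) / (loo_abba + loo_baba)
    theta_j = np.nan_to_num(theta_j, nan=theta)

    # weighted delete-m_j jackknife (Busing et al. 1999)
    n = m.sum()
    h = n / m
    theta_dot = g * theta - ((1 - m / n) * theta_j).sum()
    tau = h * theta - (h - 1) * theta_j
    var = float(((tau - theta_dot) ** 2 / (h - 1)).sum() / g)
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        z = theta / se
    else:
        z = 0.0 if theta == 0 else math.copysign(math.inf, theta)
    return DResult(float(theta), se, z, g, float(tot_abba), float(tot_baba),
                   int(m.sum()))


def fdm_windows(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    window: int = 10_000,
    min_snps: int = 100,
) -> list[WindowStat]:
    """f_dM in non-overlapping tiled windows; sparse windows are dropped.

    Windows tile each chromosome from 0 in ``window``-bp steps.
    ``n_snps`` counts the usable (polarized, fully-called) sites in the
    window; windows with fewer than ``min_snps`` such sites, or with a
    zero denominator, are excluded — mirroring the practice of
    discarding windows too sparse for a reliable estimate.
    """
    pm.validate(gm)
    if window <= 0:
        raise ValueError("window size must be positive")
    usable, (p1, p2, p3, p4), _ = _usable_and_derived(gm, pm)

    num_s = (1 - p1) * p2 * p3 * (1 - p4) - p1 * (1 - p2) * p3 * (1 - p4)
    p2_branch = p2 >= p1
    pd2 = np.maximum(p2, p3)
    den2 = (1 - p1) * pd2 * pd2 * (1 - p4) - p1 * (1 - pd2) * pd2 * (1 - p4)
    pd1 = np.maximum(p1, p3)
    den1 = (1 - pd1) * p2 * pd1 * (1 - p4) - pd1 * (1 - p2) * pd1 * (1 - p4)
    den_s = np.where(p2_branch, den2, -den1)
    num_s = np.where(usable, np.nan_to_num(num_s), 0.0)
    den_s = np.where(usable, np.nan_to_num(den_s), 0.0)

    out: list[WindowStat] = []
    n_zero_denom = 0
    for c in gm.chromosomes():
        on_c = np.flatnonzero(gm.chrom == c)
        pos0 = gm.pos[on_c] - 1
        widx = pos0 // window
        for w in np.unique(widx):
            sel = on_c[widx == w]
            n = int(usable[sel].sum())
            if n < min_snps:
                continue
            s_num = float(num_s[sel].sum())
            s_den = float(den_s[sel].sum())
            if s_den == 0:
                n_zero_denom += 1
                continue
            out.append(WindowStat(
                chrom=str(c), start=int(w) * window, end=(int(w) + 1) * window,
                n_snps=n, f_dM=s_num / s_den,
                numerator=s_num, denominator=s_den,
            ))
    if n_zero_denom:
        logger.info("fdm_windows: dropped %d windows with zero denominator",
                    n_zero_denom)
    return out


def landscape_correlation(
    a: list[WindowStat], b: list[WindowStat]
) -> tuple[float, int]:
    """Pearson correlation of f_dM between two landscapes.

    Windows are matched on (chrom, start, end); only windows retained
    in both landscapes contribute. Returns (r, number of shared
    windows). Raises if fewer than 3 windows are shared.
    """
    from .geneset import pearson

    bmap = {(w.chrom, w.start, w.end): w.f_dM for w in b}
    pairs = [(w.f_dM, bmap[(w.chrom, w.start, w.end)]) for w in a
             if (w.chrom, w.start, w.end) in bmap]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} shared windows; need >=3")
    x, y = (np.array(v) for v in zip(*pairs))
    r, _ = pearson(x, y)
    return float(r), len(pairs)


def outlier_windows(
    ws: list[WindowStat], percentile: float = 99.0
) -> list[WindowStat]:
    """Windows whose f_dM is at or above the empirical percentile.

    The threshold is the linear-interpolation empirical quantile over
    the retained windows; ties with the threshold are all included.
    """
    if not ws:
        raise ValueError("no windows supplied")
    vals = np.array([w.f_dM for w in ws])
    thr = float(np.percentile(vals, percentile))
    return [w for w in ws if w.f_dM >= thr]


def write_windows_tsv(ws: list[WindowStat], path) -> None:
    """BED-like TSV: chrom, start, end, n_snps, f_dM."""
    with open(str(path), "w") as fh:
        fh.write("chrom\tstart\tend\tn_snps\tf_dM\n")
        for w in ws:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_snps}\t{w.f_dM:.6g}\n")


def read_windows_tsv(path) -> list[WindowStat]:
    out = []
    with open(str(path)) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ValueError("window TSV must start with its header line")
        for line in fh:
            c, s, e, n, f = line.rstrip("\n").split("\t")
            out.append(WindowStat(c, int(s), int(e), int(n), float(f)))
    return out
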