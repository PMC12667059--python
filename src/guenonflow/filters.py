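"""Genotype-level masks applied before any population statistic.

Two masks are implemented, mirroring common practice for multi-species
panels genotyped against a single reference:

* a depth mask — a genotype whose site depth is below half or above
  twice that sample's mean autosomal depth is set to missing (too-low
  depth under-calls heterozygotes; too-high depth flags collapsed
  repeats);
* an allele-balance mask — a heterozygous call whose minor allele is
  supported by < 25% of the reads is set to missing (likely a
  miscalled homozygote or mapping artefact).

Both masks only ever remove genotypes; they never change a retained
call, and both are idempotent.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import MISSING, AlleleDepths, DepthRecord, GenotypeMatrix

logger = logging.getLogger(__name__)


def apply_depth_mask(gm: GenotypeMatrix, d: DepthRecord) -> GenotypeMatrix:
    """Mask genotypes with site depth < 0.5x or > 2x the sample mean.

    The per-sample mean is the autosomal mean in ``d.mean_depth``; if
    ``d.mean_depth_x`` is provided it is used instead on chromosomes
    named in ``d.x_chroms``. Sites where depth is unavailable (-1) are
    left untouched. Returns a new matrix; the input is not modified.

    Raises
    ------
    KeyError
        If a sample of ``gm`` has no mean depth in ``d``.
    """
    out = gm.copy()
    d_idx = {s: i for i, s in enumerate(d.samples)}
    is_x = np.isin(gm.chrom.astype(str), d.x_chroms)
    for i, sample in enumerate(gm.samples):
        if sample not in d_idx or sample not in d.mean_depth:
            raise KeyError(f"no depth record for sample {sample!r}")
        depth = d.depth[d_idx[sample]]
        mean = d.mean_depth[sample]
        if mean <= 0:
            raise ValueError(f"sample {sample!r} has non-positive mean depth")
        lo, hi = 0.5 * mean, 2.0 * mean
        bad = (depth >= 0) & ((depth < lo) | (depth > hi))
        if d.mean_depth_x is not None and is_x.any():
            mx = d.mean_depth_x.get(sample, mean)
            bad_x = (depth >= 0) & ((depth < 0.5 * mx) | (depth > 2.0 * mx))
            bad = np.where(is_x, bad_x, bad)
        out.G[i, bad] = MISSING
    return out


def apply_allele_balance_mask(
    gm: GenotypeMatrix, ad: AlleleDepths, min_balance: float = 0.25
) -> GenotypeMatrix:
    """Mask heterozygous genotypes with minor-allele read support < ``min_balance``.

    Support is min(ref_reads, alt_reads) / (ref_reads + alt_reads).
    Homozygous genotypes are never touched. A het with zero total reads
    is masked and counted in a warning tally. Returns a new matrix.
    """
    out = gm.copy()
    idx = {s: i for i, s in enumerate(ad.samples)}
    n_zero = 0
    for i, sample in enumerate(gm.samples):
        if sample not in idx:
            raise KeyError(f"no allele depths for sample {sample!r}")
        r = ad.ref_depth[idx[sample]].astype(np.float64)
        a = ad.alt_depth[idx[sample]].astype(np.float64)
        het = out.G[i] == 1
        valid = (r >= 0) & (a >= 0)
        tot = r + a
        zero_tot = het & valid & (tot == 0)
        n_zero += int(zero_tot.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            support = np.minimum(r, a) / tot
        bad = het & valid & ((tot == 0) | (support < min_balance))
        out.G[i, bad] = MISSING
    if n_zero:
        logger.warning(
            "allele-balance mask: %d heterozygous genotypes had zero AD reads "
            "and were masked", n_zero,
        )
    return out
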