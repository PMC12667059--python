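"""Gene-window intersection and gene-set overlap statistics.

``genes_near_windows`` links candidate introgression windows to genes:
a gene is hit when its body or its strand-aware upstream interval
(``upstream_bp`` before the transcription start, clipped at zero)
intersects any window. ``fisher_overlap`` then asks whether two gene
sets (say, window-linked genes and positively selected genes) overlap
more than expected by chance within a declared gene universe, via the
two-sided Fisher exact test (minimum-likelihood summation convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneInterval
from .introgression import WindowStat


@dataclass
class OverlapTable:
    """2x2 overlap of gene sets A and B within a universe of size N."""

    k: int   # |A & B|
    K: int   # |A|
    n: int   # |B|
    N: int   # universe size
    odds_ratio: float
    p_two_sided: float
    zero_cell: bool = False  # odds ratio involved a zero cell

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.k, self.K - self.k),
                (self.n - self.k, self.N - self.K - self.n + self.k))


def upstream_interval(gene: GeneInterval, upstream_bp: int) -> tuple[int, int] | None:
    """Strand-aware upstream interval of exactly ``upstream_bp``, clipped at 0.

    On '+' the interval precedes the gene start; on '-' it follows the
    gene end. Returns None when it is empty after clipping.
    """
    if upstream_bp <= 0:
        return None
    if gene.strand == "+":
        s, e = max(0, gene.start - upstream_bp), gene.start
    else:
        s, e = gene.end, gene.end + upstream_bp
    return (s, e) if s < e else None


def genes_near_windows(
    windows: list[WindowStat],
    genes: list[GeneInterval],
    upstream_bp: int = 10_000,
) -> set[str]:
    """Gene ids whose body or upstream region intersects any window.

    Intersections are half-open: abutting intervals do not overlap.
    With ``upstream_bp=0`` this reduces to plain body intersection.
    """
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end)
    hits: set[str] = set()
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        if tree.overlap(g.start, g.end):
            hits.add(g.gene_id)
            continue
        up = upstream_interval(g, upstream_bp)
        if up is not None and tree.overlap(*up):
            hits.add(g.gene_id)
    return hits


def fisher_overlap(set_a: set[str], set_b: set[str],
                   universe: set[str]) -> OverlapTable:
    """Two-sided Fisher exact test of overlap between two gene sets.

    Both sets must be subsets of the universe (memberships are checked,
    not silently intersected). The two-sided p sums hypergeometric
    point probabilities <= P(observed k), the classical convention.
    The odds ratio is the ratio of table cross-products; a zero cell
    yields inf (or nan for 0/0) and is flagged.
    """
    for name, s in (("setA", set_a), ("setB", set_b)):
        stray = s - universe
        if stray:
            shown = ", ".join(sorted(stray)[:5])
            raise ValueError(f"{name} has {len(stray)} ids outside the "
                             f"universe (e.g. {shown})")
    k = len(set_a & set_b)
    K, n, N = len(set_a), len(set_b), len(universe)
    table = [[k, K - k], [n - k, N - K - n + k]]
    if N == 0:
        raise ValueError("empty universe")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    a, b = table[0]
    c, d = table[1]
    zero_cell = (a * d == 0) or (b * c == 0)
    return OverlapTable(k=k, K=K, n=n, N=N, odds_ratio=float(odds),
                        p_two_sided=float(p), zero_cell=zero_cell)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-based p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need >=3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def read_gene_set(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_overlap_json(table: OverlapTable, path) -> None:
    import json

    with open(str(path), "w") as fh:
        json.dump({
            "k": table.k, "K": table.K, "n": table.n, "N": table.N,
            "odds_ratio": None if math.isnan(table.odds_ratio)
            else (table.odds_ratio if math.isfinite(table.odds_ratio) else "inf"),
            "p_two_sided": table.p_two_sided, "zero_cell": table.zero_cell,
        }, fh, indent=2)
        fh.write("\n")
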