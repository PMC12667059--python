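"""Core data model for multi-sample diploid genotype panels.

Genotypes are stored as alt-allele dosages (0, 1, 2) in a dense
samples x sites matrix, with ``MISSING`` (-1) for uncalled genotypes.
Only biallelic SNPs are modelled: every downstream statistic in this
package (site-pattern sums, f_dM, runs of homozygosity, derived-allele
load) is defined on biallelic dosages, and indels are excluded from the
analyses this package implements.

Coordinate conventions: VCF positions are kept 1-based (``pos``); all
interval arithmetic (genes, windows, ROH segments) is 0-based half-open.
Conversions happen only in the readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Sentinel for an uncalled genotype in a dosage matrix.
MISSING: int = -1

ROLES = ("P1", "P2", "P3", "OUT")


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotype calls for S samples at L sites.

    Attributes
    ----------
    chrom : np.ndarray of str, shape (L,)
        Sequence name per site.
    pos : np.ndarray of int, shape (L,)
        1-based position per site; strictly increasing within a chromosome.
    ref_allele, alt_allele : np.ndarray of str, shape (L,)
        Reference and alternate nucleotide per site.
    G : np.ndarray of int8, shape (S, L)
        Alt-allele dosage per sample per site, in {0, 1, 2, MISSING}.
    samples : list of str
        Ordered sample identifiers (rows of ``G``).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    G: np.ndarray
    samples: list[str]
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.ndim != 2:
            raise ValueError("G must be a 2-D samples x sites matrix")
        if self.G.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"G shape {self.G.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.pos)} sites"
            )
        bad = ~np.isin(self.G, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, MISSING}")
        for c in dict.fromkeys(self.chrom.tolist()):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_sites(self) -> int:
        return self.G.shape[1]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in keep]
        return GenotypeMatrix(
            self.chrom, self.pos, self.ref_allele, self.alt_allele,
            self.G[idx, :], list(keep), self.ploidy,
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.chrom[mask], self.pos[mask], self.ref_allele[mask],
            self.alt_allele[mask], self.G[:, mask], list(self.samples),
            self.ploidy,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.chrom.copy(), self.pos.copy(), self.ref_allele.copy(),
            self.alt_allele.copy(), self.G.copy(), list(self.samples),
            self.ploidy,
        )

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        return list(dict.fromkeys(self.chrom.tolist()))


@dataclass
class PopulationMap:
    """Sample-to-population assignments plus the four-taxon test roles.

    ``roles`` maps a role name (P1, P2, P3, OUT) to a population label;
    all samples of that population fill the role. P1/P2 are the two
    sister lineages contrasted in the four-taxon test, P3 the candidate
    donor, OUT the outgroup used to polarize the ancestral allele.
    """

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def role_samples(self, role: str) -> list[str]:
        if role not in self.roles:
            raise KeyError(f"role {role!r} not assigned")
        return self.samples_of(self.roles[role])

    def validate(self, gm: GenotypeMatrix, roles: Iterable[str] = ROLES) -> None:
        """Check each requested role maps to >=1 sample present in ``gm``
        and that role populations are pairwise disjoint."""
        seen: dict[str, str] = {}
        for role in roles:
            pop = self.roles.get(role)
            if pop is None:
                raise ValueError(f"role {role} not assigned to a population")
            if pop in seen and seen[pop] != role:
                raise ValueError(f"population {pop!r} assigned to two roles")
            seen[pop] = role
            samples = [s for s in self.samples_of(pop) if s in gm.samples]
            if not samples:
                raise ValueError(
                    f"role {role} (population {pop!r}) has no sample in the matrix"
                )


@dataclass
class DepthRecord:
    """Per-sample per-site read depth with per-sample mean autosomal depth.

    ``mean_depth`` maps sample -> mean autosomal depth; ``mean_depth_x``
    optionally carries an X-chromosome mean applied on the chromosomes
    listed in ``x_chroms``.
    """

    depth: np.ndarray  # (S, L) non-negative int; -1 where absent
    samples: list[str]
    mean_depth: dict[str, float]
    mean_depth_x: dict[str, float] | None = None
    x_chroms: tuple[str, ...] = ("chrX", "X")


@dataclass
class AlleleDepths:
    """Per-sample per-site (ref, alt) read counts backing allele-balance checks."""

    ref_depth: np.ndarray  # (S, L)
    alt_depth: np.ndarray  # (S, L)
    samples: list[str]


@dataclass(frozen=True)
class GeneInterval:
    """A gene body interval, 0-based half-open, with strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start
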