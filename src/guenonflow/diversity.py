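"""Heterozygosity, derived-allele polarization and mutation-load ratios.

Heterozygosity is the fraction of heterozygous genotypes among called
genotypes for one sample, over whatever site list the supplied matrix
carries (variant sites, plus any invariant records present). Load is
quantified per functional-impact category as the total number of
derived alleles in that category divided by the number of synonymous
derived alleles — a ratio that cancels per-sample callability as long
as callability is category-independent. Derived alleles are counted as
dosages: a homozygous-derived genotype contributes two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

CATEGORIES = ("synonymous", "moderate", "high", "low")


@dataclass
class ImpactTable:
    """(chrom, pos, allele) -> functional-impact category.

    One category per alt allele; sites absent from the table are
    uncategorized ("none").
    """

    categories: dict[tuple[str, int, str], str]

    def category_of(self, chrom: str, pos: int, allele: str) -> str:
        return self.categories.get((chrom, int(pos), allele), "none")

    def site_categories(self, gm: GenotypeMatrix,
                        alleles: np.ndarray | None = None) -> np.ndarray:
        """Vector of categories for each site of ``gm``; ``alleles``
        defaults to the alt allele."""
        if alleles is None:
            alleles = gm.alt_allele
        return np.array([
            self.category_of(str(gm.chrom[j]), int(gm.pos[j]), str(alleles[j]))
            for j in range(gm.n_sites)
        ], dtype=object)


def read_impact_table(path) -> ImpactTable:
    """TSV with columns chrom, pos, alt, category (header optional)."""
    cats: dict[tuple[str, int, str], str] = {}
    with open(str(path)) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ln == 1 and parts[0] in ("chrom", "CHROM"):
                continue
            if len(parts) < 4:
                raise ValueError(f"impact table line {ln}: need 4 columns")
            key = (parts[0], int(parts[1]), parts[2])
            if key in cats and cats[key] != parts[3]:
                raise ValueError(f"impact table line {ln}: conflicting category "
                                 f"for {key}")
            cats[key] = parts[3]
    return ImpactTable(cats)


def write_impact_table(table: ImpactTable, path) -> None:
    with open(str(path), "w") as fh:
        fh.write("chrom\tpos\talt\tcategory\n")
        for (c, p, a), cat in table.categories.items():
            fh.write(f"{c}\t{p}\t{a}\t{cat}\n")


@dataclass
class DerivedDosage:
    """Per-sample derived-allele dosages at polarizable sites.

    ``derived_allele`` is the nucleotide identified as derived at each
    retained site (the allele the outgroup does not carry).
    """

    chrom: np.ndarray
    pos: np.ndarray
    derived_allele: np.ndarray
    D: np.ndarray  # (S, L') dosages in {0,1,2,MISSING}
    samples: list[str]
    n_sites_skipped: int = 0


@dataclass
class LoadSummary:
    """Derived-allele counts and load ratios for one sample."""

    sample: str
    derived_synonymous: int
    derived_moderate: int
    derived_high: int
    load_moderate: float
    load_high: float


def heterozygosity(gm: GenotypeMatrix, sample: str | None = None) -> float:
    """Fraction of heterozygous among called genotypes for one sample."""
    if sample is None:
        if gm.n_samples != 1:
            raise ValueError("specify a sample for a multi-sample matrix")
        i = 0
    else:
        i = gm.sample_index(sample)
    row = gm.G[i]
    called = row != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("no called genotypes")
    return float((row[called] == 1).sum() / n_called)


def polarize_derived(gm: GenotypeMatrix, pm: PopulationMap,
                     outgroup: str | None = None) -> DerivedDosage:
    """Re-express dosages relative to the derived allele.

    The outgroup population (``pm.roles['OUT']`` unless given) must be
    monomorphic and fully informative at a site for it to be retained:
    its allele is ancestral and the other allele derived. Where the
    outgroup is fixed for the alt allele, dosages flip (2 - dosage).
    Sites with a polymorphic or entirely missing outgroup are skipped
    and tallied.
    """
    pop = outgroup or pm.roles.get("OUT")
    if pop is None:
        raise ValueError("no outgroup population given or assigned to OUT")
    out_samples = [s for s in pm.samples_of(pop) if s in gm.samples]
    if not out_samples:
        raise ValueError(f"outgroup population {pop!r} has no samples in matrix")
    idx = [gm.sample_index(s) for s in out_samples]
    sub = gm.G[idx, :]
    miss = sub == MISSING
    any_called = (~miss).sum(axis=0) > 0
    mx = np.where(miss, -9, sub).max(axis=0)
    mn = np.where(miss, 9, sub).min(axis=0)
    fixed_ref = any_called & (mx == 0)
    fixed_alt = any_called & (mn == 2)
    keep = fixed_ref | fixed_alt
    n_skipped = int(gm.n_sites - keep.sum())

    others = [s for s in gm.samples if s not in out_samples]
    oidx = [gm.sample_index(s) for s in others]
    G = gm.G[oidx][:, keep].astype(np.int8)
    flip = fixed_alt[keep]
    missing = G == MISSING
    Gp = np.where(flip[np.newaxis, :], 2 - G, G).astype(np.int8)
    Gp[missing] = MISSING
    derived = np.where(flip, gm.ref_allele[keep], gm.alt_allele[keep])
    return DerivedDosage(
        chrom=gm.chrom[keep], pos=gm.pos[keep], derived_allele=derived,
        D=Gp, samples=others, n_sites_skipped=n_skipped,
    )


def load_ratios(derived: DerivedDosage, impacts: ImpactTable,
                sample: str) -> LoadSummary:
    """Per-impact derived-allele counts and their ratios to synonymous.

    A site contributes only when its derived allele is the allele the
    impact table categorizes; derived dosages are summed per category.
    """
    i = derived.samples.index(sample)
    cats = np.array([
        impacts.category_of(str(derived.chrom[j]), int(derived.pos[j]),
                            str(derived.derived_allele[j]))
        for j in range(len(derived.pos))
    ], dtype=object)
    dose = np.where(derived.D[i] == MISSING, 0, derived.D[i]).astype(np.int64)
    n_syn = int(dose[cats == "synonymous"].sum())
    n_mod = int(dose[cats == "moderate"].sum())
    n_high = int(dose[cats == "high"].sum())
    if n_syn == 0:
        raise ValueError(f"sample {sample!r}: no synonymous derived alleles — "
                         "load ratios undefined")
    return LoadSummary(
        sample=sample, derived_synonymous=n_syn, derived_moderate=n_mod,
        derived_high=n_high, load_moderate=n_mod / n_syn,
        load_high=n_high / n_syn,
    )


def heterozygosity_by_impact(
    gm: GenotypeMatrix, impacts: ImpactTable, sample: str | None = None
) -> dict[str, float]:
    """Per-impact-category heterozygosity for one sample.

    Categories with no called genotype are omitted with a warning;
    elevated heterozygosity in damaging categories relative to
    synonymous sites is the signature of purifying selection keeping
    deleterious alleles rare.
    """
    if sample is None:
        if gm.n_samples != 1:
            raise ValueError("specify a sample for a multi-sample matrix")
        sample = gm.samples[0]
    i = gm.sample_index(sample)
    cats = impacts.site_categories(gm)
    row = gm.G[i]
    out: dict[str, float] = {}
    for c in sorted(set(cats.tolist()) - {"none"}):
        sel = cats == c
        called = (row != MISSING) & sel
        n_called = int(called.sum())
        if n_called == 0:
            logger.warning("category %r has no called genotypes for %s; omitted",
                           c, sample)
            continue
        out[c] = float((row[called] == 1).sum() / n_called)
    return out


def write_load_tsv(summaries: list[LoadSummary], path) -> None:
    with open(str(path), "w") as fh:
        fh.write("sample\tderived_synonymous\tderived_moderate\tderived_high\t"
                 "load_moderate\tload_high\n")
        for s in summaries:
            fh.write(f"{s.sample}\t{s.derived_synonymous}\t{s.derived_moderate}\t"
                     f"{s.derived_high}\t{s.load_moderate:.6g}\t{s.load_high:.6g}\n")
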