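"""Truth-known synthetic data generators.

Four generators cover the statistical structure the analysis chain
assumes:

* ``simulate_snp_data`` — coalescent-with-recombination genotypes for a
  four-population species tree ((P1,P2),P3),OUT with one optional
  admixture pulse from P3 (donor) into a recipient lineage; the
  outgroup is a sampled population so derived alleles can be polarized.
  A five-population variant with two sister recipient lineages supports
  landscape-comparison experiments (one shared ancestral pulse versus
  independent pulses into each recipient).
* ``simulate_roh_genome`` — a single diploid chromosome with planted
  autozygous tracts for exercising the run-of-homozygosity caller.
* ``simulate_impact_table`` — functional-impact labels at given
  per-category rates, with per-sample derived-allele truth counts.
* ``simulate_codon_alignments`` — per-gene codon alignments with
  planted group-private convergent amino-acid columns, plus optional
  internal stops and missing stretches to exercise the filters.

All generators are deterministic under a fixed seed. The coalescent
machinery is delegated to msprime; this module owns the demography,
the genotype-matrix conversion and the truth bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import msprime
import numpy as np
from Bio.Data import CodonTable

from .core import MISSING, GenotypeMatrix, PopulationMap

_NUC = np.array(list("ACGT"))


@dataclass
class Pulse:
    """One admixture pulse: ``fraction`` of the recipient's ancestry
    replaced by the donor lineage at ``time`` generations ago."""

    donor: str = "P3"
    recipient: str = "P2"
    time: float = 5_000.0
    fraction: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("pulse fraction must be in [0, 1]")
        if self.fraction > 0 and self.donor == self.recipient:
            raise ValueError("pulse donor and recipient must differ")


@dataclass
class SimConfig:
    """Demography and mutation parameters for the SNP-panel generator.

    Split times are in generations before present and must satisfy
    T12 < T123 < Troot. ``t_recipients`` is only used by the
    five-population (two-recipient) topology, where the two recipient
    lineages P2a and P2b split ``t_recipients`` generations ago.
    Defaults are desk-scale fixture choices: a 4-population tree with
    Ne = 10,000 per branch and splits at 10/40/100 thousand generations
    simulates in seconds at a few megabases while giving window-level
    SNP densities sufficient for the statistics under test.
    """

    seed: int = 1
    samples_per_pop: int = 2
    t12: float = 10_000.0
    t123: float = 40_000.0
    t_root: float = 100_000.0
    t_recipients: float = 4_000.0
    ne: float = 10_000.0
    mu: float = 1e-8
    seq_len: float = 5e6
    recomb_rate: float = 1e-8
    pulse: Pulse = field(default_factory=Pulse)
    chrom: str = "chr1"

    def validate(self) -> None:
        if not (0 < self.t12 < self.t123 < self.t_root):
            raise ValueError("split times must satisfy 0 < T12 < T123 < Troot")
        if self.pulse.fraction > 0 and self.pulse.time >= self.t12:
            raise ValueError("pulse must be younger than the P1/P2 divergence")
        self.pulse.validate()
        if self.seq_len <= 0 or self.mu < 0 or self.ne <= 0:
            raise ValueError("seq_len, mu, Ne must be positive")


@dataclass
class SimTruth:
    """Generator-side record of planted features for downstream scoring."""

    f_true: float | None = None
    pulse_time: float | None = None
    roh_tracts: list[tuple[str, str, int, int]] = field(default_factory=list)
    convergent_columns: list[tuple[str, int]] = field(default_factory=list)
    derived_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "f_true": self.f_true,
            "pulse_time": self.pulse_time,
            "roh_tracts": [list(t) for t in self.roh_tracts],
            "convergent_columns": [list(c) for c in self.convergent_columns],
            "derived_counts": self.derived_counts,
        }


def _sub_seed(seed: int, k: int) -> int:
    # deterministic child seeds, kept below 2**31 for msprime
    return (seed * 1_000_003 + k) % (2**31 - 1) + 1


def _four_pop_demography(cfg: SimConfig) -> msprime.Demography:
    dem = msprime.Demography()
    for name in ("P1", "P2", "P3", "OUT"):
        dem.add_population(name=name, initial_size=cfg.ne)
    for name in ("A12", "A123", "AROOT"):
        dem.add_population(name=name, initial_size=cfg.ne)
    if cfg.pulse.fraction > 0:
        dem.add_mass_migration(
            time=cfg.pulse.time, source=cfg.pulse.recipient,
            dest=cfg.pulse.donor, proportion=cfg.pulse.fraction,
        )
    dem.add_population_split(time=cfg.t12, derived=["P1", "P2"], ancestral="A12")
    dem.add_population_split(time=cfg.t123, derived=["A12", "P3"], ancestral="A123")
    dem.add_population_split(time=cfg.t_root, derived=["A123", "OUT"],
                             ancestral="AROOT")
    dem.sort_events()
    return dem


def _two_recipient_demography(cfg: SimConfig, shared_pulse: bool) -> msprime.Demography:
    if not cfg.t_recipients < cfg.t12:
        raise ValueError("recipient split must predate (be younger than) T12")
    dem = msprime.Demography()
    for name in ("P1", "P2a", "P2b", "P3", "OUT"):
        dem.add_population(name=name, initial_size=cfg.ne)
    for name in ("A2", "A12", "A123", "AROOT"):
        dem.add_population(name=name, initial_size=cfg.ne)
    f = cfg.pulse.fraction
    if f > 0:
        if shared_pulse:
            if not (cfg.t_recipients < cfg.pulse.time < cfg.t12):
                raise ValueError(
                    "a shared pulse must fall between the recipient split and T12"
                )
            dem.add_mass_migration(time=cfg.pulse.time, source="A2",
                                   dest="P3", proportion=f)
        else:
            t = cfg.pulse.time
            if not t < cfg.t_recipients:
                raise ValueError(
                    "independent pulses must be younger than the recipient split"
                )
            dem.add_mass_migration(time=t, source="P2a", dest="P3", proportion=f)
            dem.add_mass_migration(time=t, source="P2b", dest="P3", proportion=f)
    dem.add_population_split(time=cfg.t_recipients, derived=["P2a", "P2b"],
                             ancestral="A2")
    dem.add_population_split(time=cfg.t12, derived=["P1", "A2"], ancestral="A12")
    dem.add_population_split(time=cfg.t123, derived=["A12", "P3"], ancestral="A123")
    dem.add_population_split(time=cfg.t_root, derived=["A123", "OUT"],
                             ancestral="AROOT")
    dem.sort_events()
    return dem


def _ts_to_genotype_matrix(mts, pops: Sequence[str], samples_per_pop: int,
                           chrom: str) -> tuple[GenotypeMatrix, PopulationMap]:
    """Convert mutated tree sequence to a dosage matrix (ref = ancestral)."""
    sample_names = [f"{p}_{i}" for p in pops for i in range(samples_per_pop)]
    n_ind = len(sample_names)
    chroms, poss, refs, alts, doses = [], [], [], [], []
    last_pos = 0
    for var in mts.variants():
        alleles = [a for a in var.alleles if a is not None]
        if len(alleles) != 2:
            continue
        pos = int(var.site.position) + 1  # 1-based
        if pos <= last_pos:
            continue
        last_pos = pos
        g = var.genotypes  # haploid allele indices, individuals contiguous
        dose = g.reshape(n_ind, 2).sum(axis=1).astype(np.int8)
        chroms.append(chrom)
        poss.append(pos)
        refs.append(alleles[0])  # ancestral state
        alts.append(alleles[1])
        doses.append(dose)
    G = (np.stack(doses, axis=1) if poss
         else np.zeros((n_ind, 0), dtype=np.int8))
    gm = GenotypeMatrix(
        np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object), np.array(alts, dtype=object),
        G, sample_names,
    )
    assignments = {f"{p}_{i}": p for p in pops for i in range(samples_per_pop)}
    return gm, PopulationMap(assignments, {})


def simulate_snp_data(cfg: SimConfig) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Simulate the four-taxon SNP panel ((P1,P2),P3),OUT.

    Runs a coalescent with recombination under the configured species
    tree, with one optional pulse of admixture, then sprinkles biallelic
    mutations. The reference allele is the ancestral state, so in this
    generator the alt dosage is the derived dosage. Deterministic under
    a fixed seed.
    """
    cfg.validate()
    dem = _four_pop_demography(cfg)
    ts = msprime.sim_ancestry(
        samples={p: cfg.samples_per_pop for p in ("P1", "P2", "P3", "OUT")},
        demography=dem, sequence_length=cfg.seq_len,
        recombination_rate=cfg.recomb_rate, random_seed=_sub_seed(cfg.seed, 1),
    )
    mts = msprime.sim_mutations(ts, rate=cfg.mu,
                                random_seed=_sub_seed(cfg.seed, 2))
    gm, pm = _ts_to_genotype_matrix(mts, ("P1", "P2", "P3", "OUT"),
                                    cfg.samples_per_pop, cfg.chrom)
    pm.roles = {"P1": "P1", "P2": "P2", "P3": "P3", "OUT": "OUT"}
    truth = SimTruth(f_true=cfg.pulse.fraction, pulse_time=cfg.pulse.time)
    return gm, pm, truth


def simulate_two_recipient_data(
    cfg: SimConfig, shared_pulse: bool = True
) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Five-population panel with two sister recipient lineages P2a, P2b.

    With ``shared_pulse`` the donor P3 admixes once into the common
    ancestor of P2a and P2b (between their split and T12), so both
    recipients inherit the same introgressed material and their windowed
    admixture landscapes should correlate strongly. Without it, two
    independent pulses of the same fraction enter P2a and P2b after
    their split, decorrelating the landscapes.
    """
    cfg.validate()
    dem = _two_recipient_demography(cfg, shared_pulse)
    pops = ("P1", "P2a", "P2b", "P3", "OUT")
    ts = msprime.sim_ancestry(
        samples={p: cfg.samples_per_pop for p in pops}, demography=dem,
        sequence_length=cfg.seq_len, recombination_rate=cfg.recomb_rate,
        random_seed=_sub_seed(cfg.seed, 3),
    )
    mts = msprime.sim_mutations(ts, rate=cfg.mu,
                                random_seed=_sub_seed(cfg.seed, 4))
    gm, pm = _ts_to_genotype_matrix(mts, pops, cfg.samples_per_pop, cfg.chrom)
    truth = SimTruth(f_true=cfg.pulse.fraction, pulse_time=cfg.pulse.time)
    return gm, pm, truth


def landscape_scenario_config(
    seed: int,
    fraction: float = 0.2,
    shared: bool = True,
    seq_len: float = 1e7,
) -> SimConfig:
    """Frozen demography for landscape-comparison experiments.

    Emulates an old admixture event into the deep common ancestor of
    the recipient radiation: the pulse (30,000 generations ago) predates
    the recipient split (5,000 generations ago) by 2.5 Ne generations,
    long enough for introgressed tracts to sort to fixation or loss in
    the shared ancestor, so both recipients inherit the same
    introgression mosaic. The mutation rate is raised to 5e-8 so that
    10-kb windows typically carry >=100 usable SNPs — the retained-
    window regime of real multi-species panels. With ``shared=False``
    the same fraction enters each recipient independently 2,500
    generations ago, decorrelating the landscapes.
    """
    return SimConfig(
        seed=seed, samples_per_pop=2, t12=40_000.0, t123=80_000.0,
        t_root=160_000.0, t_recipients=5_000.0, ne=10_000.0, mu=5e-8,
        seq_len=seq_len, recomb_rate=1e-8,
        pulse=Pulse(donor="P3", recipient="A2" if shared else "P2a",
                    time=30_000.0 if shared else 2_500.0, fraction=fraction),
    )


def simulate_roh_genome(
    seed: int,
    chrom_len: int = 10_000_000,
    snp_density: float = 1 / 500,
    het_rate: float = 0.3,
    tracts: Sequence[tuple[int, int]] = (),
    error_het_rate: float = 0.0,
    chrom: str = "chr1",
    sample: str = "S0",
) -> tuple[GenotypeMatrix, SimTruth]:
    """One diploid chromosome with planted autozygous tracts.

    SNPs are placed uniformly at ``snp_density`` per bp. Outside the
    planted tracts each SNP is heterozygous with probability
    ``het_rate`` (otherwise homozygous); inside a tract SNPs are
    homozygous, except for an optional genotyping-error het rate.
    Tracts are 0-based half-open bp intervals and must not overlap.
    """
    tracts = sorted(tuple(t) for t in tracts)
    for (s, e) in tracts:
        if not (0 <= s < e <= chrom_len):
            raise ValueError(f"tract ({s}, {e}) outside chromosome")
    for (s1, e1), (s2, e2) in zip(tracts, tracts[1:]):
        if s2 < e1:
            raise ValueError("tracts must not overlap")
    rng = np.random.default_rng(seed)
    n_snps = int(round(chrom_len * snp_density))
    pos0 = np.sort(rng.choice(chrom_len, size=min(n_snps, chrom_len),
                              replace=False))
    in_tract = np.zeros(len(pos0), dtype=bool)
    for (s, e) in tracts:
        in_tract |= (pos0 >= s) & (pos0 < e)
    u = rng.random(len(pos0))
    het = np.where(in_tract, u < error_het_rate, u < het_rate)
    hom_alt = rng.random(len(pos0)) < 0.5
    dose = np.where(het, 1, np.where(hom_alt, 2, 0)).astype(np.int8)
    ref = _NUC[rng.integers(0, 4, len(pos0))]
    alt_shift = rng.integers(1, 4, len(pos0))
    alt = _NUC[(np.searchsorted(_NUC, ref) + alt_shift) % 4]
    gm = GenotypeMatrix(
        np.full(len(pos0), chrom, dtype=object), pos0 + 1,
        ref.astype(object), alt.astype(object),
        dose[np.newaxis, :], [sample],
    )
    truth = SimTruth(roh_tracts=[(sample, chrom, int(s), int(e))
                                 for (s, e) in tracts])
    return gm, truth


def simulate_impact_table(
    seed: int, gm: GenotypeMatrix, rates: dict[str, float]
) -> tuple["ImpactTable", SimTruth]:
    """Label each site's alt allele with a functional-impact category.

    ``rates`` gives the probability of {synonymous, moderate, high}
    (summing to at most 1; the remainder is uncategorized). In this
    generator the reference allele is taken as ancestral — as produced
    by ``simulate_snp_data`` — so the truth per-sample derived-allele
    counts per category are the alt-dosage sums over that category's
    sites (missing genotypes contribute nothing).
    """
    from .diversity import ImpactTable

    p_syn = rates.get("synonymous", 0.0)
    p_mod = rates.get("moderate", 0.0)
    p_high = rates.get("high", 0.0)
    if min(p_syn, p_mod, p_high) < 0 or p_syn + p_mod + p_high > 1 + 1e-12:
        raise ValueError("rates must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    cats = np.array(["synonymous", "moderate", "high", "none"], dtype=object)
    probs = [p_syn, p_mod, p_high, max(0.0, 1.0 - p_syn - p_mod - p_high)]
    draw = rng.choice(4, size=gm.n_sites, p=np.asarray(probs) / sum(probs))
    site_cat = cats[draw]
    table = ImpactTable({
        (str(gm.chrom[j]), int(gm.pos[j]), str(gm.alt_allele[j])): str(site_cat[j])
        for j in range(gm.n_sites)
        if site_cat[j] != "none"
    })
    truth = SimTruth()
    dose = np.where(gm.G == MISSING, 0, gm.G).astype(np.int64)
    for i, s in enumerate(gm.samples):
        truth.derived_counts[s] = {
            c: int(dose[i, site_cat == c].sum())
            for c in ("synonymous", "moderate", "high")
        }
    return table, truth


_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: one representative codon per amino acid (deterministic choice)
AA_TO_CODON: dict[str, str] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    AA_TO_CODON.setdefault(_aa, _codon)
STOP_CODON = sorted(_STANDARD.stop_codons)[0]
_SENSE_CODONS = sorted(_STANDARD.forward_table)


def simulate_codon_alignments(
    seed: int,
    n_genes: int,
    n_codons: int,
    groups: dict[str, list[str]],
    planted: Sequence[tuple[str, int, str]] = (),
    focal_groups: tuple[str, str] = ("focalA", "focalB"),
    noise_substitutions: Sequence[tuple[str, int, str, str]] = (),
    internal_stops: Sequence[tuple[str, str]] = (),
    missing_sequences: Sequence[tuple[str, str, float]] = (),
) -> tuple[dict[str, dict[str, str]], SimTruth]:
    """Per-gene codon alignments with planted convergent columns.

    Genes are named ``gene0001`` .. ``gene{n_genes:04d}``. Every
    sequence starts as the gene's random ancestral sense-codon sequence.
    ``planted`` entries (gene, AA column 0-based, amino acid) set that
    amino acid in *all* samples of the two focal groups, leaving the
    background on the ancestral amino acid (which is re-drawn if it
    collides with the planted one). ``noise_substitutions`` (gene,
    column, group, AA) change a single group only — shared-but-not-
    private or private-but-not-shared patterns that must not be called
    convergent. ``internal_stops`` plant an in-frame stop mid-sequence;
    ``missing_sequences`` replace the given fraction of codons with
    'NNN'. Returns {gene: {sample: codon string}} plus the truth.
    """
    names = [f"gene{k + 1:04d}" for k in range(n_genes)]
    for gene, col, aa in planted:
        if gene not in names:
            raise ValueError(f"planted gene {gene!r} not among generated genes")
        if not 0 <= col < n_codons:
            raise ValueError(f"planted column {col} beyond {n_codons} codons")
        if aa not in AA_TO_CODON:
            raise ValueError(f"{aa!r} is not a codable amino acid")
    rng = np.random.default_rng(seed)
    all_samples = [s for g in groups.values() for s in g]
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("a sample may appear in only one group")
    fa, fb = focal_groups
    focal_samples = set(groups.get(fa, [])) | set(groups.get(fb, []))

    alignments: dict[str, dict[str, str]] = {}
    truth = SimTruth()
    planted_by_gene: dict[str, list[tuple[int, str]]] = {}
    for gene, col, aa in planted:
        planted_by_gene.setdefault(gene, []).append((col, aa))
        truth.convergent_columns.append((gene, col))
    for gene in names:
        codons = [ _SENSE_CODONS[k]
                   for k in rng.integers(0, len(_SENSE_CODONS), n_codons) ]
        for col, aa in planted_by_gene.get(gene, []):
            if _STANDARD.forward_table[codons[col]] == aa:
                # re-draw the background so the planted state is truly private
                alt = [c for c in _SENSE_CODONS
                       if _STANDARD.forward_table[c] != aa]
                codons[col] = alt[int(rng.integers(0, len(alt)))]
        seqs = {s: list(codons) for s in all_samples}
        for col, aa in planted_by_gene.get(gene, []):
            for s in focal_samples:
                seqs[s][col] = AA_TO_CODON[aa]
        for (g2, col, group, aa) in noise_substitutions:
            if g2 != gene:
                continue
            for s in groups[group]:
                seqs[s][col] = AA_TO_CODON[aa]
        for (g2, s) in internal_stops:
            if g2 == gene:
                seqs[s][n_codons // 2] = STOP_CODON
        for (g2, s, frac) in missing_sequences:
            if g2 != gene:
                continue
            k = int(np.ceil(frac * n_codons))
            cols = rng.choice(n_codons, size=min(k, n_codons), replace=False)
            for c in cols:
                seqs[s][c] = "NNN"
        alignments[gene] = {s: "".join(cs) for s, cs in seqs.items()}
    return alignments, truth
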