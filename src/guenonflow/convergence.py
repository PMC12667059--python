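"""Convergent amino-acid substitution detection from codon alignments.

A column is *convergent* between two focal groups when every
non-missing residue in both groups carries one and the same amino
acid, and that amino acid is absent from every non-missing background
residue — a fixed, private, shared state. Ancestral-state
reconstruction is deliberately avoided: the predicate is evaluated
directly on the extant alignment, which is conservative for deep
backgrounds.

Quality filters applied before detection, per gene: a sequence is
excluded if its translation contains an internal stop codon or is more
than 50% missing; the gene itself is dropped when more than half of
the samples in either focal group were excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

MISSING_AA = frozenset({"X", "-"})


@dataclass
class CodonAlignment:
    """One gene's in-frame codon alignment (gaps '---', ambiguity 'NNN')."""

    gene_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: sequences differ in length")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise ValueError(f"{self.gene_id}: alignment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values()))) // 3


@dataclass
class FilterReport:
    """Which sequences survived translation filtering, and why others fell."""

    gene_id: str
    retained: dict[str, str]  # sample -> AA string
    excluded: dict[str, str] = field(default_factory=dict)  # sample -> reason
    gene_dropped: bool = False
    drop_reason: str | None = None


@dataclass
class ConvergenceResult:
    """Convergent columns for one gene.

    ``convergent_columns`` holds (0-based AA column, shared amino acid,
    sorted background amino acids at that column).
    """

    gene_id: str
    convergent_columns: list[tuple[int, str, tuple[str, ...]]]
    n_convergent: int
    retained_samples: dict[str, list[str]]
    n_columns_skipped: int = 0


def translate_codons(codon_seq: str) -> str:
    """Codon-wise translation: '---' -> '-', any N or partial gap -> 'X'."""
    if len(codon_seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    out = []
    for i in range(0, len(codon_seq), 3):
        codon = codon_seq[i:i + 3].upper()
        if codon == "---":
            out.append("-")
        elif "N" in codon or "-" in codon:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


def translate_and_filter(
    aln: CodonAlignment,
    groups: dict[str, list[str]],
    focal_groups: tuple[str, str] = ("focalA", "focalB"),
    max_missing: float = 0.5,
) -> FilterReport:
    """Translate every sequence and apply the per-sequence and per-gene
    exclusion rules.

    A sequence is excluded when >``max_missing`` of its amino-acid
    positions are missing ('X'/'-') or when it contains an internal
    stop (a terminal stop is permitted and trimmed to missing). The
    gene is dropped when more than half the samples of either focal
    group were excluded.
    """
    retained: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for sample, seq in aln.sequences.items():
        aa = translate_codons(seq)
        if aa.endswith("*"):
            aa = aa[:-1] + "-"
        if "*" in aa:
            excluded[sample] = "internal_stop"
            continue
        n_missing = sum(ch in MISSING_AA for ch in aa)
        if len(aa) and n_missing / len(aa) > max_missing:
            excluded[sample] = "missing_gt_50pct"
            continue
        retained[sample] = aa
    report = FilterReport(aln.gene_id, retained, excluded)
    for g in focal_groups:
        members = groups.get(g, [])
        present = [s for s in members if s in aln.sequences]
        if not present:
            report.gene_dropped = True
            report.drop_reason = f"group {g} absent from alignment"
            return report
        kept = sum(1 for s in present if s in retained)
        if kept < len(present) / 2:  # more than half filtered out
            report.gene_dropped = True
            report.drop_reason = f"more than half of group {g} filtered out"
            return report
    return report


def convergent_sites(
    aa_seqs: dict[str, str],
    focal_a: list[str],
    focal_b: list[str],
    background: list[str],
    gene_id: str = "NA",
) -> ConvergenceResult:
    """Columns with a fixed private amino-acid state shared by both
    focal groups.

    Fixation is evaluated over non-missing residues; a column where any
    of the three groups is entirely missing is skipped and tallied.
    """
    fa = [s for s in focal_a if s in aa_seqs]
    fb = [s for s in focal_b if s in aa_seqs]
    bg = [s for s in background if s in aa_seqs]
    if not (fa and fb and bg):
        raise ValueError("each of focalA, focalB and background needs >=1 "
                         "retained sample")
    n_cols = len(next(iter(aa_seqs.values())))
    cols: list[tuple[int, str, tuple[str, ...]]] = []
    n_skipped = 0
    for j in range(n_cols):
        a_res = {aa_seqs[s][j] for s in fa} - MISSING_AA
        b_res = {aa_seqs[s][j] for s in fb} - MISSING_AA
        g_res = {aa_seqs[s][j] for s in bg} - MISSING_AA
        if not a_res or not b_res or not g_res:
            n_skipped += 1
            continue
        shared = a_res | b_res
        if len(shared) == 1:
            x = next(iter(shared))
            if x not in g_res:
                cols.append((j, x, tuple(sorted(g_res))))
    return ConvergenceResult(
        gene_id=gene_id, convergent_columns=cols, n_convergent=len(cols),
        retained_samples={"focalA": fa, "focalB": fb, "background": bg},
        n_columns_skipped=n_skipped,
    )


def scan_genes(
    alignments: dict[str, dict[str, str]],
    groups: dict[str, list[str]],
    focal_groups: tuple[str, str] = ("focalA", "focalB"),
    background_group: str = "background",
) -> dict[str, ConvergenceResult]:
    """Filter and scan every gene; genes dropped by the filters are omitted."""
    out: dict[str, ConvergenceResult] = {}
    fa_name, fb_name = focal_groups
    for gene, seqs in alignments.items():
        report = translate_and_filter(CodonAlignment(gene, seqs), groups,
                                      focal_groups)
        if report.gene_dropped:
            continue
        out[gene] = convergent_sites(
            report.retained,
            [s for s in groups[fa_name] if s in report.retained],
            [s for s in groups[fb_name] if s in report.retained],
            [s for s in groups[background_group] if s in report.retained],
            gene_id=gene,
        )
    return out


def write_convergence_tsv(results: dict[str, ConvergenceResult], path) -> None:
    with open(str(path), "w") as fh:
        fh.write("gene\tcolumn\tshared_AA\tbackground_AAs\tn_convergent_in_gene\n")
        for gene, res in results.items():
            for (col, aa, bg) in res.convergent_columns:
                fh.write(f"{gene}\t{col}\t{aa}\t{','.join(bg)}\t"
                         f"{res.n_convergent}\n")
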