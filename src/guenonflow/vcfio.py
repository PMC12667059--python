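"""Standard-format I/O: VCF, population maps, gene annotations, impact tables.

VCF parsing goes through cyvcf2; only biallelic SNP records are kept
(multiallelic records and indels are skipped — the data model is
biallelic by construction). FORMAT/DP and FORMAT/AD are returned when
present so the depth and allele-balance masks can be applied downstream.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .core import MISSING, AlleleDepths, DepthRecord, GeneInterval, GenotypeMatrix

logger = logging.getLogger(__name__)

_NUCS = frozenset("ACGT")
_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


class VcfParseError(ValueError):
    pass


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_vcf(path, region: str | None = None):
    """Read a VCF into a GenotypeMatrix plus optional depth/AD records.

    Parameters
    ----------
    path : str or Path
        VCF 4.x file, plain or bgzipped.
    region : str, optional
        ``chrom`` or ``chrom:start-end`` (1-based inclusive); records
        outside it are dropped. A region with no records yields an empty
        matrix, not an error.

    Returns
    -------
    (GenotypeMatrix, DepthRecord | None, AlleleDepths | None)
        DP/AD components are None when the FORMAT fields are absent.
        DepthRecord.mean_depth is filled with each sample's mean DP over
        the sites read (callers may overwrite it with a genome-wide mean).
    """
    chrom_q = start_q = end_q = None
    if region is not None:
        m = _REGION_RE.match(region)
        if m is None:
            raise ValueError(f"malformed region {region!r}")
        chrom_q = m.group(1)
        if m.group(2):
            start_q, end_q = int(m.group(2)), int(m.group(3))

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    has_dp = "DP" in [f["ID"] for f in vcf.header_iter() if f.type == "FORMAT"]
    has_ad = "AD" in [f["ID"] for f in vcf.header_iter() if f.type == "FORMAT"]

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    dosages: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    ads_ref: list[np.ndarray] = []
    ads_alt: list[np.ndarray] = []
    n_skipped = 0

    for var in vcf:
        if chrom_q is not None:
            if var.CHROM != chrom_q:
                continue
            if start_q is not None and not (start_q <= var.POS <= end_q):
                continue
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if ref not in _NUCS or alt not in _NUCS:
            n_skipped += 1
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        dose = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            a = gt[:-1]
            if len(a) != 2 or a[0] < 0 or a[1] < 0:
                dose[i] = MISSING
            else:
                dose[i] = a[0] + a[1]
        dosages.append(dose)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(ref)
        alts.append(alt)
        if has_dp:
            dp = var.format("DP")
            dp = (
                np.full(len(samples), -1, dtype=np.int32)
                if dp is None
                else np.where(dp.ravel() < 0, -1, dp.ravel()).astype(np.int32)
            )
            dps.append(dp)
        if has_ad:
            ad = var.format("AD")
            if ad is None:
                ads_ref.append(np.full(len(samples), -1, dtype=np.int32))
                ads_alt.append(np.full(len(samples), -1, dtype=np.int32))
            else:
                ads_ref.append(np.where(ad[:, 0] < 0, -1, ad[:, 0]).astype(np.int32))
                ads_alt.append(np.where(ad[:, 1] < 0, -1, ad[:, 1]).astype(np.int32))
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    L = len(poss)
    G = (
        np.stack(dosages, axis=1)
        if L
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object), np.array(alts, dtype=object), G, samples,
    )
    depth = None
    if has_dp:
        dmat = (
            np.stack(dps, axis=1) if L else np.zeros((len(samples), 0), np.int32)
        )
        means = {}
        for i, s in enumerate(samples):
            ok = dmat[i] >= 0
            means[s] = float(dmat[i][ok].mean()) if ok.any() else 0.0
        depth = DepthRecord(dmat, samples, means)
    ad_rec = None
    if has_ad:
        rmat = (
            np.stack(ads_ref, axis=1) if L else np.zeros((len(samples), 0), np.int32)
        )
        amat = (
            np.stack(ads_alt, axis=1) if L else np.zeros((len(samples), 0), np.int32)
        )
        ad_rec = AlleleDepths(rmat, amat, samples)
    return gm, depth, ad_rec


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, depth: DepthRecord | None = None,
              ad: AlleleDepths | None = None) -> None:
    """Write a GenotypeMatrix as VCF 4.2 (GT, plus DP/AD when given)."""
    fmt_fields = ["GT"]
    if depth is not None:
        fmt_fields.append("DP")
    if ad is not None:
        fmt_fields.append("AD")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in gm.chromosomes():
            last = gm.pos[gm.chrom == c].max() if gm.n_sites else 1
            fh.write(f"##contig=<ID={c},length={int(last) + 1_000_000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if ad is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples) + "\n"
        )
        for j in range(gm.n_sites):
            fields = [
                str(gm.chrom[j]), str(int(gm.pos[j])), ".",
                str(gm.ref_allele[j]), str(gm.alt_allele[j]), ".", "PASS", ".",
                ":".join(fmt_fields),
            ]
            for i in range(gm.n_samples):
                parts = [_GT_STR[int(gm.G[i, j])]]
                if depth is not None:
                    d = int(depth.depth[i, j])
                    parts.append("." if d < 0 else str(d))
                if ad is not None:
                    r, a = int(ad.ref_depth[i, j]), int(ad.alt_depth[i, j])
                    parts.append(".,." if r < 0 else f"{r},{a}")
                fields.append(":".join(parts))
            fh.write("\t".join(fields) + "\n")


def read_population_map(path):
    """Read a sample<TAB>population[<TAB>role] TSV into a PopulationMap."""
    from .core import PopulationMap

    assignments: dict[str, str] = {}
    roles: dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"population map line lacks a population: {line!r}")
            sample, pop = parts[0], parts[1]
            assignments[sample] = pop
            if len(parts) >= 3 and parts[2]:
                roles[parts[2]] = pop
    return PopulationMap(assignments, roles)


def write_population_map(pm, path) -> None:
    inv_roles = {pop: role for role, pop in pm.roles.items()}
    with open(str(path), "w") as fh:
        for sample, pop in pm.assignments.items():
            role = inv_roles.get(pop, "")
            fh.write(f"{sample}\t{pop}\t{role}\n" if role else f"{sample}\t{pop}\n")


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_intervals(path, dialect: str = "gff3") -> list[GeneInterval]:
    """Read gene intervals from GFF3 or BED (6+ columns).

    GFF3 1-based inclusive coordinates are converted to 0-based
    half-open. A gene appearing in several records (gene plus its
    mRNAs, or several transcripts) is collapsed to the union span of
    its records. Records with strand '.' are rejected with a warning —
    the strand is needed for upstream-region arithmetic downstream.
    """
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "bed":
        out = []
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 6:
                    raise ValueError(f"BED line {ln} has <6 columns")
                strand = parts[5]
                if strand not in ("+", "-"):
                    logger.warning("BED line %d: strand %r rejected", ln, strand)
                    continue
                out.append(
                    GeneInterval(parts[3], parts[0], int(parts[1]), int(parts[2]),
                                 strand)
                )
        return out

    spans: dict[str, list] = {}  # gene_id -> [chrom, start0, end, strand]
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"GFF3 line {ln} has <9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            if ftype not in ("gene", "mRNA", "transcript"):
                continue
            a = _gff3_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID") or a.get("gene_id") or a.get("Name")
            else:
                gid = a.get("Parent") or a.get("gene_id") or a.get("ID")
            if gid is None:
                logger.warning("GFF3 line %d: no gene identifier, skipped", ln)
                continue
            if strand not in ("+", "-"):
                logger.warning("GFF3 line %d (%s): strand %r rejected", ln, gid,
                               strand)
                continue
            s0, e = int(start) - 1, int(end)
            rec = spans.get(gid)
            if rec is None:
                spans[gid] = [chrom, s0, e, strand]
            else:
                rec[1] = min(rec[1], s0)
                rec[2] = max(rec[2], e)
    return [
        GeneInterval(gid, chrom, s0, e, strand)
        for gid, (chrom, s0, e, strand) in spans.items()
    ]
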