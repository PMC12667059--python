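"""End-to-end orchestration: one declarative config, staged execution,
a JSON manifest with parameter echo for provenance.

Stages run in dependency order (simulate -> filters -> statistics);
each stage writes plain-text tables into the run directory and
registers them in ``manifest.json``. Identical config plus inputs
yield byte-identical outputs, which the test suite checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import yaml

from . import convergence, diversity, geneset, introgression, roh, simulate, vcfio
from .core import GenotypeMatrix, PopulationMap
from .filters import apply_allele_balance_mask, apply_depth_mask

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "filters", "dstat", "fdm", "roh", "diversity",
              "converge", "overlap")


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    out_dir: str
    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # inputs (ignored by stages that do not need them; the simulate
    # stage generates vcf/popmap/impacts itself)
    vcf: str | None = None
    popmap: str | None = None
    genes: str | None = None
    impacts: str | None = None
    selected_genes: str | None = None
    universe: str | None = None
    alignments: str | None = None  # directory of per-gene FASTA
    groups: str | None = None      # sample<TAB>group TSV for converge
    # parameters
    window_bp: int = 10_000
    min_snps: int = 100
    block_size_bp: int = 1_000_000
    percentile: float = 99.0
    upstream_bp: int = 10_000
    roh_params: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)  # forwarded to SimConfig / Pulse

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        stray = set(raw) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        return cls(**raw)

    def validate(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        needs_inputs = set(self.stages) - {"simulate"}
        if "simulate" not in self.stages and needs_inputs & {
            "filters", "dstat", "fdm", "roh", "diversity"
        }:
            for name in ("vcf", "popmap"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"config input {name!r} missing or nonexistent: {p}"
                    )
        for name in ("genes", "impacts", "selected_genes", "universe",
                     "alignments", "groups"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config input {name!r} does not exist: {p}")


def _sim_config(cfg: RunConfig) -> simulate.SimConfig:
    sim = dict(cfg.sim)
    pulse = simulate.Pulse(**sim.pop("pulse", {}))
    return simulate.SimConfig(seed=cfg.seed, pulse=pulse, **sim)


def run(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Any stage failure raises after writing a partial manifest, so a
    caller can see which outputs were produced before the failure.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "guenonflow",
        "version": _pkg_version("guenonflow"),
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in asdict(cfg).items() if k not in ("out_dir",)
        },
        "outputs": {},
    }

    def register(key: str, path: Path) -> None:
        manifest["outputs"][key] = str(path)

    def flush_manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    gm: GenotypeMatrix | None = None
    pm: PopulationMap | None = None
    impacts = None
    depth = ad = None

    try:
        if "simulate" in cfg.stages:
            scfg = _sim_config(cfg)
            gm, pm, truth = simulate.simulate_snp_data(scfg)
            impacts, imp_truth = simulate.simulate_impact_table(
                cfg.seed, gm, {"synonymous": 0.05, "moderate": 0.02,
                               "high": 0.005},
            )
            truth.derived_counts = imp_truth.derived_counts
            vcf_path = out / "sim.vcf"
            vcfio.write_vcf(gm, vcf_path)
            vcfio.write_population_map(pm, out / "sim.popmap.tsv")
            diversity.write_impact_table(impacts, out / "sim.impacts.tsv")
            with open(out / "sim.truth.json", "w") as fh:
                json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
            for key, name in [("vcf", "sim.vcf"), ("popmap", "sim.popmap.tsv"),
                              ("impacts", "sim.impacts.tsv"),
                              ("truth", "sim.truth.json")]:
                register(key, out / name)
        else:
            gm, depth, ad = vcfio.read_vcf(cfg.vcf)
            pm = vcfio.read_population_map(cfg.popmap)
            if cfg.impacts:
                impacts = diversity.read_impact_table(cfg.impacts)

        if "filters" in cfg.stages and gm is not None:
            if depth is not None:
                gm = apply_depth_mask(gm, depth)
            if ad is not None:
                gm = apply_allele_balance_mask(gm, ad)

        if "dstat" in cfg.stages:
            res = introgression.block_jackknife_d(gm, pm, cfg.block_size_bp)
            p = out / "dstat.tsv"
            with open(p, "w") as fh:
                fh.write("P1\tP2\tP3\tOUT\tD\tSE\tZ\tn_blocks\tABBA\tBABA\n")
                fh.write(
                    f"{pm.roles['P1']}\t{pm.roles['P2']}\t{pm.roles['P3']}\t"
                    f"{pm.roles['OUT']}\t{res.D:.6g}\t{res.SE:.6g}\t"
                    f"{res.Z:.6g}\t{res.n_blocks}\t{res.abba:.6g}\t"
                    f"{res.baba:.6g}\n"
                )
            register("dstat", p)

        windows = None
        if "fdm" in cfg.stages:
            windows = introgression.fdm_windows(gm, pm, cfg.window_bp,
                                               cfg.min_snps)
            p = out / "fdm_windows.tsv"
            introgression.write_windows_tsv(windows, p)
            register("fdm_windows", p)

        if "roh" in cfg.stages:
            params = roh.ROHParams(**cfg.roh_params)
            segs, summaries = [], []
            for s in gm.samples:
                sub = gm.subset_samples([s])
                seg = roh.call_roh(sub, params)
                acc = roh.accessible_length(sub, params)
                segs.extend(seg)
                if acc > 0:
                    summaries.append(roh.summarize_roh(seg, acc, s))
            roh.write_segments_tsv(segs, out / "roh_segments.tsv")
            roh.write_summary_tsv(summaries, out / "roh_summary.tsv")
            register("roh_segments", out / "roh_segments.tsv")
            register("roh_summary", out / "roh_summary.tsv")

        if "diversity" in cfg.stages:
            p = out / "heterozygosity.tsv"
            with open(p, "w") as fh:
                fh.write("sample\theterozygosity\n")
                for s in gm.samples:
                    fh.write(f"{s}\t{diversity.heterozygosity(gm, s):.6g}\n")
            register("heterozygosity", p)
            if impacts is not None and pm.roles.get("OUT"):
                derived = diversity.polarize_derived(gm, pm)
                loads = []
                for s in derived.samples:
                    try:
                        loads.append(diversity.load_ratios(derived, impacts, s))
                    except ValueError as e:
                        logger.warning("load skipped: %s", e)
                diversity.write_load_tsv(loads, out / "load.tsv")
                register("load", out / "load.tsv")

        if "converge" in cfg.stages and cfg.alignments and cfg.groups:
            from Bio import SeqIO

            grp: dict[str, list[str]] = {}
            for line in Path(cfg.groups).read_text().splitlines():
                if line.strip():
                    sample, g = line.split("\t")[:2]
                    grp.setdefault(g, []).append(sample)
            alns = {
                f.stem: {r.id: str(r.seq) for r in SeqIO.parse(str(f), "fasta")}
                for f in sorted(Path(cfg.alignments).glob("*.fa*"))
            }
            results = convergence.scan_genes(alns, grp)
            convergence.write_convergence_tsv(results,
                                              out / "convergent_columns.tsv")
            register("convergence", out / "convergent_columns.tsv")

        if "overlap" in cfg.stages and windows is not None and cfg.genes:
            genes = vcfio.read_gene_intervals(cfg.genes, _gene_dialect(cfg.genes))
            top = introgression.outlier_windows(windows, cfg.percentile)
            near = geneset.genes_near_windows(top, genes, cfg.upstream_bp)
            p = out / "outlier_genes.txt"
            with open(p, "w") as fh:
                for gid in sorted(near):
                    fh.write(gid + "\n")
            register("outlier_genes", p)
            if cfg.selected_genes and cfg.universe:
                universe = geneset.read_gene_set(cfg.universe)
                sel = geneset.read_gene_set(cfg.selected_genes) & universe
                table = geneset.fisher_overlap(near & universe, sel, universe)
                geneset.write_overlap_json(table, out / "overlap.json")
                register("overlap", out / "overlap.json")
    except Exception:
        flush_manifest()
        raise
    flush_manifest()
    return manifest


def _gene_dialect(path: str) -> str:
    return "bed" if str(path).rstrip(".gz").endswith(".bed") else "gff3"
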