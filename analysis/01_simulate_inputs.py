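#!/usr/bin/env python
"""Generate the synthetic study inputs with known truth.

Writes a four-population SNP panel (10% admixture pulse from P3 into
P2), its population map, a functional-impact table, per-gene codon
alignments with planted convergent columns, and the truth record,
under results/sim/. Downstream drivers consume these files.
"""

import json
from pathlib import Path

from guenonflow import write_population_map, write_vcf
from guenonflow.diversity import write_impact_table
from guenonflow.simulate import (
    Pulse,
    SimConfig,
    simulate_codon_alignments,
    simulate_impact_table,
    simulate_snp_data,
)

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "scratch" / "sim"

GROUPS = {"focalA": ["a1", "a2"], "focalB": ["b1", "b2"],
          "background": ["c1", "c2", "c3"]}
PLANTED = [("gene0002", 4, "M"), ("gene0005", 11, "W"), ("gene0005", 30, "C")]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED, seq_len=2e6, pulse=Pulse(fraction=0.1))
    gm, pm, truth = simulate_snp_data(cfg)
    impacts, imp_truth = simulate_impact_table(
        SEED, gm, {"synonymous": 0.05, "moderate": 0.02, "high": 0.005}
    )
    truth.derived_counts = imp_truth.derived_counts
    alns, conv_truth = simulate_codon_alignments(
        seed=SEED, n_genes=6, n_codons=40, groups=GROUPS, planted=PLANTED,
    )
    truth.convergent_columns = conv_truth.convergent_columns

    write_vcf(gm, OUT / "panel.vcf")
    write_population_map(pm, OUT / "panel.popmap.tsv")
    write_impact_table(impacts, OUT / "panel.impacts.tsv")
    aln_dir = OUT / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for gene, seqs in alns.items():
        with open(aln_dir / f"{gene}.fa", "w") as fh:
            for s, seq in seqs.items():
                fh.write(f">{s}\n{seq}\n")
    with open(OUT / "groups.tsv", "w") as fh:
        for g, members in GROUPS.items():
            for s in members:
                fh.write(f"{s}\t{g}\n")
    with open(OUT / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    print(f"panel: {gm.n_sites} biallelic SNPs x {gm.n_samples} samples "
          f"(true admixture fraction {truth.f_true})")
    print(f"impact table: {len(impacts.categories)} categorized alleles")
    print(f"alignments: {len(alns)} genes, "
          f"{len(truth.convergent_columns)} planted convergent columns")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
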