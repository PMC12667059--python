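#!/usr/bin/env python
"""Outlier-window gene content and gene-set overlap tests.

Computes the windowed f_dM landscape of the simulated panel, takes the
99th-percentile windows, links them to a synthetic gene annotation
(gene bodies or <10 kb upstream), and runs two Fisher exact overlap
tests against gene sets with known relationships: a random set (no
enrichment expected) and a set containing every outlier gene
(enrichment expected). Writes results under results/overlap/.
"""

from pathlib import Path

import numpy as np

from guenonflow import read_population_map, read_vcf
from guenonflow.core import GeneInterval
from guenonflow.geneset import fisher_overlap, genes_near_windows
from guenonflow.introgression import fdm_windows, outlier_windows, write_windows_tsv

SIM = Path(__file__).resolve().parent.parent / "scratch" / "sim"
OUT = Path(__file__).resolve().parent.parent / "results" / "overlap"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm, _, _ = read_vcf(SIM / "panel.vcf")
    pm = read_population_map(SIM / "panel.popmap.tsv")
    windows = fdm_windows(gm, pm, 10_000, min_snps=10)
    write_windows_tsv(windows, OUT / "fdm_windows.tsv")
    top = outlier_windows(windows, 99)
    print(f"{len(windows)} retained 10-kb windows; "
          f"{len(top)} in the 99th percentile "
          f"(threshold f_dM >= {min(w.f_dM for w in top):.3f})")

    # synthetic annotation: 10-kb genes every 20 kb, alternating strand
    rng = np.random.default_rng(5)
    genes = [
        GeneInterval(f"G{i:03d}", "chr1", s, s + 10_000,
                     "+" if i % 2 == 0 else "-")
        for i, s in enumerate(range(0, 1_990_000, 20_000))
    ]
    near = genes_near_windows(top, genes, upstream_bp=10_000)
    print(f"{len(near)} of {len(genes)} genes have a body or <10 kb "
          f"upstream region in an outlier window")

    universe = {g.gene_id for g in genes}
    random_set = set(rng.choice(sorted(universe), 20, replace=False))
    t_rand = fisher_overlap(near, random_set, universe)
    seeded = set(near) | set(rng.choice(sorted(universe - near), 10,
                                        replace=False))
    t_seed = fisher_overlap(near, seeded, universe)

    with open(OUT / "overlap_tests.tsv", "w") as fh:
        fh.write("test\tk\tK\tn\tN\todds_ratio\tp_two_sided\n")
        for name, t in (("random_set", t_rand), ("seeded_set", t_seed)):
            fh.write(f"{name}\t{t.k}\t{t.K}\t{t.n}\t{t.N}\t"
                     f"{t.odds_ratio:.4g}\t{t.p_two_sided:.4g}\n")
    print(f"random gene set: k = {t_rand.k}, p = {t_rand.p_two_sided:.3f} "
          f"(no enrichment expected)")
    print(f"seeded gene set: k = {t_seed.k}, p = {t_seed.p_two_sided:.2g} "
          f"(enrichment expected)")
    print(f"tables under {OUT}")


if __name__ == "__main__":
    main()
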