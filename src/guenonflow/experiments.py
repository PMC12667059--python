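"""Replicate studies on truth-known simulations.

Each function runs one self-contained experiment — generate synthetic
data with known truth, apply the corresponding statistic, score the
result — and returns plain numbers. The analysis drivers narrate these;
the acceptance machinery re-runs them from scratch.

Desk-scale problem sizes are deliberate: 5-Mb chromosomes for the
D-statistic replicate studies (with 250-kb jackknife blocks, giving 20
blocks) and a 10-Mb chromosome for the landscape comparison. These
sizes give stable test behaviour while each study completes in well
under a minute per replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import roh as roh_mod
from .introgression import (
    block_jackknife_d,
    fdm_windows,
    landscape_correlation,
)
from .core import PopulationMap
from .simulate import (
    Pulse,
    SimConfig,
    landscape_scenario_config,
    simulate_roh_genome,
    simulate_snp_data,
    simulate_two_recipient_data,
)

#: jackknife block size used on 5-Mb simulated chromosomes (20 blocks)
SIM_BLOCK_BP = 250_000
#: window SNP filter matched to simulated SNP density at mu = 1e-8
SIM_MIN_SNPS = 10


@dataclass
class DStudy:
    """Replicate D-statistic study summary."""

    d_values: list[float]
    z_values: list[float]
    n_exceed_z3: int  # replicates with |Z| > 3
    n_detect: int     # replicates with Z > +3
    mean_d: float


def d_replicates(seeds, fraction: float, seq_len: float = 5e6,
                 block_size: int = SIM_BLOCK_BP) -> DStudy:
    """D with jackknife Z over replicate simulations at one admixture level."""
    ds, zs = [], []
    for seed in seeds:
        cfg = SimConfig(seed=int(seed), seq_len=seq_len,
                        pulse=Pulse(fraction=fraction))
        gm, pm, _ = simulate_snp_data(cfg)
        res = block_jackknife_d(gm, pm, block_size)
        ds.append(res.D)
        zs.append(res.Z)
    return DStudy(
        d_values=ds, z_values=zs,
        n_exceed_z3=sum(abs(z) > 3 for z in zs),
        n_detect=sum(z > 3 for z in zs),
        mean_d=float(np.mean(ds)),
    )


def mean_fdm_null(seed: int, seq_len: float = 5e6) -> tuple[float, int]:
    """Genome-wide mean windowed f_dM under no gene flow."""
    gm, pm, _ = simulate_snp_data(
        SimConfig(seed=seed, seq_len=seq_len, pulse=Pulse(fraction=0.0))
    )
    ws = fdm_windows(gm, pm, 10_000, SIM_MIN_SNPS)
    return float(np.mean([w.f_dM for w in ws])), len(ws)


@dataclass
class LandscapeStudy:
    r_shared: float
    n_shared: int
    r_independent: float
    n_independent: int

    @property
    def fisher_z_difference(self) -> float:
        """Fisher z-statistic for r_shared > r_independent."""
        za = math.atanh(min(self.r_shared, 0.999999))
        zb = math.atanh(max(min(self.r_independent, 0.999999), -0.999999))
        se = math.sqrt(1 / (self.n_shared - 3) + 1 / (self.n_independent - 3))
        return (za - zb) / se


def landscape_study(seed: int, fraction: float = 0.2,
                    seq_len: float = 1e7) -> LandscapeStudy:
    """Correlation of the two recipients' 10-kb f_dM landscapes under a
    shared ancestral pulse versus independent pulses."""

    def correlate(shared: bool) -> tuple[float, int]:
        cfg = landscape_scenario_config(seed, fraction, shared, seq_len)
        gm, pm, _ = simulate_two_recipient_data(cfg, shared)

        def windows(p2: str):
            pmx = PopulationMap(dict(pm.assignments),
                                {"P1": "P1", "P2": p2, "P3": "P3",
                                 "OUT": "OUT"})
            return fdm_windows(gm, pmx, 10_000, 100)

        return landscape_correlation(windows("P2a"), windows("P2b"))

    r_sh, n_sh = correlate(True)
    r_in, n_in = correlate(False)
    return LandscapeStudy(r_sh, n_sh, r_in, n_in)


@dataclass
class RohRecovery:
    precision: float
    recall: float
    n_segments: int
    roh_fraction_fully_hom: float  # accessible-genome fixed point


def _interval_union_len(intervals) -> int:
    total, last_end = 0, -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
        last_end = max(last_end, e)
    return total


def _intersection_len(a, b) -> int:
    out, j = 0, 0
    b = sorted(b)
    for s, e in sorted(a):
        for bs, be in b:
            lo, hi = max(s, bs), min(e, be)
            if hi > lo:
                out += hi - lo
    return out


def roh_recovery_study(
    seed: int,
    chrom_len: int = 12_000_000,
    tracts=((1_000_000, 1_300_000), (4_000_000, 5_000_000),
            (7_000_000, 10_000_000)),
    het_rate: float = 0.3,
) -> RohRecovery:
    """Base-pair precision/recall of planted autozygous tracts, plus the
    fully-homozygous fixed point of the accessible-genome normalization."""
    gm, truth = simulate_roh_genome(seed, chrom_len, 1 / 500, het_rate,
                                    list(tracts))
    segs = roh_mod.call_roh(gm)
    called = [(s.start, s.end) for s in segs]
    true_iv = [(s, e) for (_, _, s, e) in truth.roh_tracts]
    inter = _intersection_len(called, true_iv)
    called_len = _interval_union_len(called)
    true_len = _interval_union_len(true_iv)
    precision = inter / called_len if called_len else 0.0
    recall = inter / true_len if true_len else 0.0

    hom_gm, _ = simulate_roh_genome(seed + 1, 2_000_000, 1 / 500, 0.0, [])
    hom_segs = roh_mod.call_roh(hom_gm)
    acc = roh_mod.accessible_length(hom_gm)
    summary = roh_mod.summarize_roh(hom_segs, acc)
    return RohRecovery(precision, recall, len(segs),
                       summary.f_short + summary.f_long)
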