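import numpy as np
import pytest

from guenonflow.core import GenotypeMatrix, PopulationMap


def make_gm(dosages, pos=None, chrom="chr1", samples=None, ref="A", alt="T"):
    """Build a small GenotypeMatrix from a samples x sites dosage list."""
    G = np.asarray(dosages, dtype=np.int8)
    S, L = G.shape
    if pos is None:
        pos = np.arange(1, L + 1)
    pos = np.asarray(pos)
    if samples is None:
        samples = [f"S{i}" for i in range(S)]
    chroms = np.full(L, chrom, dtype=object) if isinstance(chrom, str) else np.asarray(chrom, dtype=object)
    return GenotypeMatrix(
        chroms, pos,
        np.full(L, ref, dtype=object), np.full(L, alt, dtype=object),
        G, list(samples),
    )


@pytest.fixture
def quartet_pm():
    """One diploid sample per role: P1, P2, P3, OUT."""
    return PopulationMap(
        {"S0": "P1", "S1": "P2", "S2": "P3", "S3": "OUT"},
        {"P1": "P1", "P2": "P2", "P3": "P3", "OUT": "OUT"},
    )
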