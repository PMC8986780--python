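import matplotlib

matplotlib.use("Agg")

from fractions import Fraction
from math import comb

import pytest

from trapfish import GeneModel, InsertionSite


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational two-sided Fisher p by enumerating all tables with the
    observed margins; independent of the log-space implementation.

    Tables whose point mass is within a 1e-7 relative tolerance of the
    observed mass count as "at most as probable" (integer comparison, so the
    tolerance only matters for exact ties).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("all-zero table")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    obs = comb(r1, a) * comb(r2, c1 - a)
    total = comb(n, c1)
    acc = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        m = comb(r1, k) * comb(r2, c1 - k)
        if m * 10**9 <= obs * (10**9 + 100):  # m <= obs * (1 + 1e-7)
            acc += m
    return float(Fraction(acc, total))


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel("GENEA", "chr1", 100, 1100, "+"),
        GeneModel("GENEB", "chr1", 2000, 3000, "-"),
        GeneModel("GENEC", "chr2", 0, 500, "+"),
    ]


def site(chrom: str, pos: int, strand: str, channel: str = "HIGH") -> InsertionSite:
    return InsertionSite(chrom=chrom, pos=pos, strand=strand, channel=channel)
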