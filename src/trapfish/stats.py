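"""Per-gene enrichment statistics for sorted-channel gene-trap screens.

For each gene the 2x2 table

    ======================  ==========  =========
                             HIGH       LOW
    ----------------------  ----------  ---------
    sense insertions in g    a           c
    all other mutations      b           d
    ======================  ==========  =========

is tested with a two-sided Fisher's exact test; p-values are corrected by
Benjamini-Hochberg across the tested genes.  The effect size reported is
the mutation ratio: the gene's insertion frequency in the HIGH channel
divided by its frequency in the LOW channel.

The Fisher computation works entirely in log-space (lgamma factorials) so
it stays finite at screen scale (~10^7 insertions per channel), and sums
with ``math.fsum`` so that swapping rows or columns of the table yields a
bit-identical p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .genes import GeneCountTable

# relative tolerance when comparing point probabilities: tables whose mass is
# within (1 + _REL_TOL) of the observed mass count as "at most as probable"
_REL_TOL = 1e-7

Direction = Literal["HIGH_ENRICHED", "LOW_ENRICHED", "NONE"]


def _log_binom(n: int, k: int) -> float:
    # grouped so that k and n-k are interchangeable bit-for-bit, which makes
    # the two-sided p exactly invariant under row and column swaps
    return math.lgamma(n + 1) - (math.lgamma(k + 1) + math.lgamma(n - k + 1))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric masses of all tables with the observed margins
    whose point probability is at most the observed one (up to a 1e-7
    relative tolerance absorbing floating-point ties).  Exact in log-space,
    valid for arbitrarily large counts.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table: Fisher's exact test is undefined")
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # a zero margin admits a single table
    log_denom = _log_binom(n, c1)
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    log_obs = _log_binom(r1, a) + _log_binom(r2, c1 - a) - log_denom
    cutoff = log_obs + math.log1p(_REL_TOL)
    masses = []
    for k in range(k_min, k_max + 1):
        lp = _log_binom(r1, k) + _log_binom(r2, c1 - k) - log_denom
        if lp <= cutoff:
            masses.append(math.exp(lp))
    p = math.fsum(masses)
    return min(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, aligned to the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def mutation_ratio(
    sense_high: int,
    total_high: int,
    sense_low: int,
    total_low: int,
    pseudocount: float = 0.0,
) -> float:
    """HIGH-channel insertion frequency of a gene divided by its LOW frequency.

    ((sense_high + pc) / total_high) / ((sense_low + pc) / total_low).
    With ``pseudocount=0`` both counts must be positive; callers wanting a
    plottable display value for zero counts pass ``pseudocount=1``.
    """
    if total_high <= 0 or total_low <= 0:
        raise ValueError("channel totals must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    num = (sense_high + pseudocount) / total_high
    den = (sense_low + pseudocount) / total_low
    if den == 0:
        raise ValueError(
            "mutation ratio undefined: zero LOW count with zero pseudocount"
        )
    if num == 0 and pseudocount == 0:
        raise ValueError(
            "mutation ratio undefined: zero HIGH count with zero pseudocount"
        )
    return num / den


@dataclass(frozen=True)
class EnrichmentResult:
    """Counts, test and effect size for one gene."""

    gene: str
    sense_high: int
    sense_low: int
    other_high: int
    other_low: int
    p: float
    p_adj: float
    ratio: float
    combined_unique: int
    direction: Direction
    significant: bool


def _direction(ratio: float) -> Direction:
    if ratio > 1:
        return "HIGH_ENRICHED"
    if ratio < 1:
        return "LOW_ENRICHED"
    return "NONE"


def run_screen_enrichment(
    counts: GeneCountTable,
    alpha: float = 0.05,
    min_combined: int = 1,
) -> list[EnrichmentResult]:
    """Fisher + BH-FDR over every gene with >= min_combined sense insertions.

    FDR is computed across exactly the tested set.  The mutation ratio uses
    raw counts; a pseudocount of 1 is applied only when either channel's
    count is zero so the ratio stays finite and plottable.  Results are
    sorted by adjusted p, then gene name.
    """
    df = counts.counts
    tested = df[(df["sense_high"] + df["sense_low"]) >= min_combined]
    if tested.empty:
        raise ValueError("no genes meet the min_combined threshold")
    rows = []
    for gene, sh, sl in tested[["gene", "sense_high", "sense_low"]].itertuples(index=False):
        sh, sl = int(sh), int(sl)
        oh = counts.total_high - sh
        ol = counts.total_low - sl
        p = fisher_exact_two_sided(sh, oh, sl, ol)
        pc = 1.0 if (sh == 0 or sl == 0) else 0.0
        ratio = mutation_ratio(sh, counts.total_high, sl, counts.total_low, pc)
        rows.append((str(gene), sh, sl, oh, ol, p, ratio))
    p_adj = bh_fdr([r[5] for r in rows])
    results = [
        EnrichmentResult(
            gene=gene,
            sense_high=sh,
            sense_low=sl,
            other_high=oh,
            other_low=ol,
            p=p,
            p_adj=q,
            ratio=ratio,
            combined_unique=sh + sl,
            direction=_direction(ratio),
            significant=q < alpha,
        )
        for (gene, sh, sl, oh, ol, p, ratio), q in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.gene))
    return results


def results_to_frame(results: Iterable[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "sense_high": r.sense_high,
                "sense_low": r.sense_low,
                "other_high": r.other_high,
                "other_low": r.other_low,
                "p": r.p,
                "p_adj": r.p_adj,
                "ratio": r.ratio,
                "combined_unique": r.combined_unique,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in results
        ]
    )
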