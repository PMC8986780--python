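"""Model/Results interface for sorted-channel screen enrichment.

``ScreenEnrichment`` is constructed from the data (a per-gene count table,
or site catalogs plus an annotation); ``fit()`` runs the per-gene two-sided
Fisher's exact tests with Benjamini-Hochberg correction and returns a
``ScreenEnrichmentResults`` carrying the estimates (mutation ratios), the
raw and adjusted p-values, a ``summary()`` table and the fishtail plot.

    >>> model = ScreenEnrichment.from_sites(sites_high, sites_low, genes)
    >>> res = model.fit(alpha=0.05)
    >>> print(res.summary())
    >>> res.plot_fishtail()
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .catalog import InsertionSite
from .fishtail import FishtailPoint, fishtail_coordinates, plot_fishtail, write_report
from .genes import GeneCountTable, GeneModel, count_sense_insertions
from .stats import EnrichmentResult, results_to_frame, run_screen_enrichment


class ScreenEnrichment:
    """Per-gene enrichment model for a two-channel sorted insertional screen.

    Parameters
    ----------
    counts
        Per-gene unique sense-insertion counts in the HIGH and LOW sorted
        channels together with the per-channel totals of all unique
        insertions ("all other mutations" universe).
    """

    def __init__(self, counts: GeneCountTable):
        self.counts = counts

    @classmethod
    def from_sites(
        cls,
        sites_high: set[InsertionSite],
        sites_low: set[InsertionSite],
        genes: list[GeneModel],
        universe: Literal["all", "sense-genic"] = "all",
    ) -> "ScreenEnrichment":
        """Build the model from deduplicated site catalogs and gene models."""
        return cls(count_sense_insertions(sites_high, sites_low, genes, universe=universe))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, total_high: int | None = None, total_low: int | None = None
    ) -> "ScreenEnrichment":
        """Build from a frame with gene/sense_high/sense_low (+ optional totals)."""
        if total_high is None:
            total_high = int(df["total_high"].iloc[0])
        if total_low is None:
            total_low = int(df["total_low"].iloc[0])
        return cls(
            GeneCountTable(
                counts=df[["gene", "sense_high", "sense_low"]].copy(),
                total_high=total_high,
                total_low=total_low,
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScreenEnrichment":
        return cls(GeneCountTable.from_tsv(path))

    def fit(self, alpha: float = 0.05, min_combined: int = 1) -> "ScreenEnrichmentResults":
        """Run Fisher + BH over all genes with >= min_combined sense insertions."""
        results = run_screen_enrichment(self.counts, alpha=alpha, min_combined=min_combined)
        return ScreenEnrichmentResults(self, results, alpha=alpha, min_combined=min_combined)


class ScreenEnrichmentResults:
    """Fitted per-gene enrichment results.

    Attributes
    ----------
    results : list[EnrichmentResult]
        Per-gene counts, p, adjusted p, mutation ratio and direction,
        sorted by adjusted p then gene name.
    alpha : float
        Significance level applied to the adjusted p-values.
    """

    def __init__(
        self,
        model: ScreenEnrichment,
        results: Sequence[EnrichmentResult],
        alpha: float,
        min_combined: int,
    ):
        self.model = model
        self.results = list(results)
        self.alpha = alpha
        self.min_combined = min_combined

    @property
    def frame(self) -> pd.DataFrame:
        return results_to_frame(self.results)

    @property
    def significant(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.significant]

    @property
    def significant_genes(self) -> list[str]:
        return [r.gene for r in self.significant]

    def __getitem__(self, gene: str) -> EnrichmentResult:
        for r in self.results:
            if r.gene == gene:
                return r
        raise KeyError(gene)

    def fishtail_points(self) -> list[FishtailPoint]:
        return fishtail_coordinates(self.results, alpha=self.alpha)

    def plot_fishtail(self, ax=None, **kwargs):
        return plot_fishtail(self.fishtail_points(), ax=ax, **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_report(self, plot_path: str | Path, table_path: str | Path) -> None:
        write_report(self.fishtail_points(), self.results, plot_path, table_path)

    def summary(self, max_rows: int = 20) -> str:
        """Plain-text summary table of the top genes by adjusted p."""
        c = self.model.counts
        lines = [
            "Sorted-channel screen enrichment (two-sided Fisher + BH-FDR)",
            "=" * 64,
            f"genes tested: {len(self.results)}   "
            f"significant (p_adj < {self.alpha:g}): {len(self.significant)}",
            f"unique insertions: HIGH {c.total_high}, LOW {c.total_low}   "
            f"min combined sense insertions: {self.min_combined}",
            "-" * 64,
            f"{'gene':<14}{'high':>6}{'low':>6}{'ratio':>10}{'p':>12}{'p_adj':>12}  dir",
        ]
        for r in self.results[:max_rows]:
            lines.append(
                f"{r.gene:<14}{r.sense_high:>6}{r.sense_low:>6}{r.ratio:>10.3g}"
                f"{r.p:>12.3g}{r.p_adj:>12.3g}  {r.direction}"
            )
        if len(self.results) > max_rows:
            lines.append(f"... {len(self.results) - max_rows} more genes")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ScreenEnrichmentResults: {len(self.results)} genes, "
            f"{len(self.significant)} significant at alpha={self.alpha:g}>"
        )
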