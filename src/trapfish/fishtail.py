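"""Fishtail-plot coordinates and report writing.

The fishtail plot is the field's standard view of a sorted-channel
insertional screen: per gene, the HIGH/LOW mutation ratio (y, log scale)
against the combined number of unique sense insertions in both channels
(x, log scale).  Genes significantly enriched in either channel (BH-adjusted
p below alpha) flare out of the nonsignificant "tail".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .stats import EnrichmentResult, results_to_frame

Classification = Literal["SIG_HIGH", "SIG_LOW", "NONSIG"]


@dataclass(frozen=True)
class FishtailPoint:
    gene: str
    x: int  # combined unique sense insertions
    y: float  # mutation ratio (pseudocount display value when a count is 0)
    cls: Classification


def fishtail_coordinates(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> list[FishtailPoint]:
    """One point per tested gene; classification by significance and ratio."""
    points = []
    for r in results:
        sig = r.p_adj < alpha
        if sig and r.ratio > 1:
            cls: Classification = "SIG_HIGH"
        elif sig and r.ratio < 1:
            cls = "SIG_LOW"
        else:
            cls = "NONSIG"
        points.append(FishtailPoint(gene=r.gene, x=r.combined_unique, y=r.ratio, cls=cls))
    return points


_DEFAULT_COLORS = {"SIG_HIGH": "#c0392b", "SIG_LOW": "#2471a3", "NONSIG": "#b3b3b3"}


def plot_fishtail(
    points: Sequence[FishtailPoint],
    ax=None,
    colors: dict[str, str] | None = None,
    label_significant: bool = True,
):
    """Scatter the fishtail on log-log axes; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if not points:
        raise ValueError("no points to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    palette = {**_DEFAULT_COLORS, **(colors or {})}
    for cls in ("NONSIG", "SIG_HIGH", "SIG_LOW"):
        sub = [p for p in points if p.cls == cls]
        if sub:
            ax.scatter(
                [p.x for p in sub],
                [p.y for p in sub],
                s=12,
                c=palette[cls],
                label=cls,
                zorder=2 if cls == "NONSIG" else 3,
            )
    if label_significant:
        for p in points:
            if p.cls != "NONSIG":
                ax.annotate(p.gene, (p.x, p.y), fontsize=7,
                            xytext=(2, 2), textcoords="offset points")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.axhline(1.0, color="k", lw=0.5, zorder=1)
    ax.set_xlabel("combined unique sense insertions")
    ax.set_ylabel("mutation ratio (HIGH / LOW)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def write_report(
    points: Sequence[FishtailPoint],
    results: Sequence[EnrichmentResult],
    plot_path: str | Path,
    table_path: str | Path,
) -> None:
    """Write the rendered fishtail plot and a deterministic TSV report.

    The TSV is ordered by adjusted p then gene name, so identical inputs
    produce byte-identical files.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not results or not points:
        raise ValueError("empty results: nothing to report")
    df = results_to_frame(sorted(results, key=lambda r: (r.p_adj, r.gene)))
    cls = {p.gene: p.cls for p in points}
    df["class"] = df["gene"].map(cls)
    df.to_csv(table_path, sep="\t", index=False, float_format="%.6g")
    ax = plot_fishtail(points)
    ax.figure.savefig(plot_path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
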