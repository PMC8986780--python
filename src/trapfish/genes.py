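"""Gene models and strand-aware (sense-orientation) insertion counting.

A gene-trap cassette disrupts a gene only when it integrates in the gene's
transcriptional orientation, so enrichment counting considers sense
insertions only.  Gene models are per-symbol unions of transcript spans:
trap insertions are disruptive anywhere in the locus, so exon-level
resolution is deliberately not used.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from intervaltree import IntervalTree

from .catalog import InsertionSite


@dataclass(frozen=True)
class GeneModel:
    """A named, stranded genomic interval (0-based half-open)."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"{self.symbol}: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.symbol}: strand must be '+' or '-'")


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted(ivals)
    merged = [ivals[0]]
    for s, e in ivals[1:]:
        ps, pe = merged[-1]
        if s <= pe:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def _finalize(raw: dict[tuple[str, str, str], list[tuple[int, int]]]) -> list[GeneModel]:
    # union per (symbol, chrom, strand); suffix symbols spanning >1 chromosome
    chroms_per_symbol: dict[str, set[str]] = defaultdict(set)
    for sym, chrom, _ in raw:
        chroms_per_symbol[sym].add(chrom)
    models: list[GeneModel] = []
    for (sym, chrom, strand), ivals in raw.items():
        name = sym if len(chroms_per_symbol[sym]) == 1 else f"{sym}_{chrom}"
        for s, e in _merge_intervals(ivals):
            models.append(GeneModel(name, chrom, s, e, strand))
    models.sort(key=lambda g: (g.chrom, g.start, g.end, g.symbol))
    return models


def _load_bed6(path: str) -> list[GeneModel]:
    raw: dict[tuple[str, str, str], list[tuple[int, int]]] = defaultdict(list)
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith(("#", "track", "browser")):
                continue
            if len(row) < 6:
                raise ValueError(f"{path}: row {i}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = row[:6]
            raw[(name, chrom, strand)].append((int(start), int(end)))
    return _finalize(raw)


def _load_gtf(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    raw: dict[tuple[str, str, str], list[tuple[int, int]]] = defaultdict(list)
    feature_types = set(db.featuretypes())
    use = "gene" if "gene" in feature_types else "transcript"
    if use not in feature_types:
        raise ValueError(f"{path}: GTF has neither 'gene' nor 'transcript' features")
    for feat in db.features_of_type(use):
        name = (
            feat.attributes.get("gene_name")
            or feat.attributes.get("gene_id")
            or [None]
        )[0]
        if name is None:
            raise ValueError(f"{path}: feature at {feat.seqid}:{feat.start} lacks a gene identifier")
        # gffutils exposes GTF 1-based inclusive coordinates
        raw[(name, feat.seqid, feat.strand)].append((feat.start - 1, feat.end))
    return _finalize(raw)


def load_gene_models(path: str | Path, fmt: Literal["bed", "bed6", "gtf"]) -> list[GeneModel]:
    """Load a gene annotation; same-symbol intervals are unioned per strand."""
    fmt = fmt.lower()
    if fmt in ("bed", "bed6"):
        return _load_bed6(str(path))
    if fmt == "gtf":
        return _load_gtf(str(path))
    raise ValueError(f"unknown annotation format {fmt!r} (expected bed or gtf)")


@dataclass
class GeneCountTable:
    """Per-gene sense counts in both sorted channels plus channel totals.

    ``total_high`` / ``total_low`` are the numbers of all unique insertions
    in each channel (any strand, genic or intergenic), the universe against
    which a gene's sense insertions are contrasted.
    """

    counts: pd.DataFrame  # columns: gene, sense_high, sense_low
    total_high: int
    total_low: int

    def __post_init__(self) -> None:
        need = {"gene", "sense_high", "sense_low"}
        if not need.issubset(self.counts.columns):
            raise ValueError(f"counts frame needs columns {sorted(need)}")
        if (self.counts[["sense_high", "sense_low"]] < 0).any().any():
            raise ValueError("negative counts")
        if self.total_high < 0 or self.total_low < 0:
            raise ValueError("negative totals")
        for col, tot in (("sense_high", self.total_high), ("sense_low", self.total_low)):
            if (self.counts[col] > tot).any():
                raise ValueError(f"{col} exceeds its channel total")

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df["total_high"] = self.total_high
        df["total_low"] = self.total_low
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCountTable":
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise ValueError(f"{path}: empty counts table")
        return cls(
            counts=df[["gene", "sense_high", "sense_low"]].copy(),
            total_high=int(df["total_high"].iloc[0]),
            total_low=int(df["total_low"].iloc[0]),
        )


def _gene_trees(genes: Iterable[GeneModel]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[(g.chrom, g.strand)].addi(g.start, g.end, g.symbol)
    return trees


def count_sense_insertions(
    sites_high: set[InsertionSite],
    sites_low: set[InsertionSite],
    genes: list[GeneModel],
    universe: Literal["all", "sense-genic"] = "all",
) -> GeneCountTable:
    """Count unique sense insertions per gene and channel.

    A site contributes to gene *g* iff it falls in an interval of *g*
    (half-open) and shares *g*'s strand; a site overlapping several sense
    genes contributes to each.  With ``universe="all"`` the channel totals
    are all unique insertions; with ``"sense-genic"`` only sites assigned
    to at least one sense gene count toward the totals.
    """
    trees = _gene_trees(genes)
    symbols = sorted({g.symbol for g in genes})
    counts = {sym: [0, 0] for sym in symbols}
    genic = [0, 0]
    for idx, sites in ((0, sites_high), (1, sites_low)):
        for site in sites:
            tree = trees.get((site.chrom, site.strand))
            hits = tree[site.pos] if tree is not None else ()
            if hits:
                genic[idx] += 1
            for iv in hits:
                counts[iv.data][idx] += 1
    df = pd.DataFrame(
        {
            "gene": symbols,
            "sense_high": [counts[s][0] for s in symbols],
            "sense_low": [counts[s][1] for s in symbols],
        }
    )
    if universe == "all":
        totals = (len(sites_high), len(sites_low))
    elif universe == "sense-genic":
        totals = tuple(genic)
    else:
        raise ValueError(f"unknown universe {universe!r}")
    return GeneCountTable(counts=df, total_high=totals[0], total_low=totals[1])
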