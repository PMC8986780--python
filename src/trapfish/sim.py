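"""Seeded generative simulator of haploid gene-trap screens.

The simulator is the synthetic stand-in for the sorted-cell sequencing
libraries: two channels (HIGH / LOW sorted populations) of insertion reads
over a toy genome with non-overlapping genes.  Baseline insertions land
uniformly over the genome; a planted regulator (gene, channel, fold)
multiplies that gene's sampling weight in that channel only, emulating the
enrichment a true hit accumulates in its sorted gate.  In-gene insertions
are sense with probability ``sense_prob``; intergenic strands are uniform.
PCR duplication is emulated by emitting a second read at the same
coordinate with probability ``duplicate_rate``; the catalog stage collapses
these, so the simulator exercises deduplication end to end.

All randomness flows from the single config seed; there is no hidden
global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .catalog import AlignmentRecord, InsertionSite, extract_insertion_sites, HIGH, LOW
from .genes import GeneModel
from .stats import EnrichmentResult

READ_LENGTH = 50  # single-end trap-sequencing read length emulated


@dataclass(frozen=True)
class PlantedRegulator:
    gene: str
    channel: Literal["HIGH", "LOW"]
    fold: float  # >= 1, sampling-weight multiplier in the enriched channel

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("planted fold must be >= 1")
        if self.channel not in (HIGH, LOW):
            raise ValueError("channel must be HIGH or LOW")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Generative parameters of a synthetic screen.

    Defaults describe a desk-scale screen: one 5 Mb chromosome carrying 500
    non-overlapping 2 kb genes (20% genic fraction) and 10^4 insertions per
    channel, i.e. ~20 expected insertions (~10 sense) per gene per channel.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 5_000_000
    n_genes: int = 500
    gene_length: int = 2_000
    n_insertions_high: int = 10_000
    n_insertions_low: int = 10_000
    sense_prob: float = 0.5
    duplicate_rate: float = 0.2
    planted: tuple[PlantedRegulator, ...] = ()

    def __post_init__(self) -> None:
        for p, name in ((self.sense_prob, "sense_prob"), (self.duplicate_rate, "duplicate_rate")):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_genes * self.gene_length > self.n_chroms * self.chrom_length:
            raise ValueError("genes cannot fit in the genome without overlap")

    def with_planted(self, *planted: PlantedRegulator) -> "ScreenSimConfig":
        return replace(self, planted=tuple(planted))


@dataclass
class SimTruth:
    """Planted ground truth plus realized per-gene unique sense counts."""

    planted: tuple[PlantedRegulator, ...]
    realized_sense_high: dict[str, int]
    realized_sense_low: dict[str, int]


def _gene_symbol(i: int) -> str:
    return f"G{i:04d}"


def simulate_annotation(config: ScreenSimConfig) -> list[GeneModel]:
    """Place non-overlapping genes with random strands, deterministically.

    Gene starts are a sorted uniform draw over the slack left after
    reserving every gene body, so placements are disjoint by construction.
    """
    rng = np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    for ci, idx in enumerate(per_chrom):
        k = len(idx)
        if k == 0:
            continue
        slack = config.chrom_length - k * config.gene_length
        if slack < 0:
            raise ValueError("genes cannot fit on chromosome")
        offsets = np.sort(rng.integers(0, slack + 1, size=k))
        strands = rng.choice(["+", "-"], size=k)
        for j, gi in enumerate(idx):
            start = int(offsets[j] + j * config.gene_length)
            genes.append(
                GeneModel(
                    symbol=_gene_symbol(int(gi)),
                    chrom=f"chr{ci + 1}",
                    start=start,
                    end=start + config.gene_length,
                    strand=str(strands[j]),
                )
            )
    return genes


def _channel_weights(
    config: ScreenSimConfig, genes: list[GeneModel], channel: str
) -> np.ndarray:
    """Sampling weight per region: one entry per gene, then intergenic."""
    fold = {p.gene: p.fold for p in config.planted if p.channel == channel}
    known = {g.symbol for g in genes}
    for p in config.planted:
        if p.gene not in known:
            raise ValueError(f"planted gene {p.gene!r} is not in the annotation")
    w = np.array([fold.get(g.symbol, 1.0) * (g.end - g.start) for g in genes], dtype=float)
    intergenic = config.n_chroms * config.chrom_length - sum(g.end - g.start for g in genes)
    return np.append(w, float(intergenic))


def _simulate_channel_reads(
    config: ScreenSimConfig,
    genes: list[GeneModel],
    channel: str,
    n: int,
    rng: np.random.Generator,
) -> list[AlignmentRecord]:
    weights = _channel_weights(config, genes, channel)
    probs = weights / weights.sum()
    region_counts = rng.multinomial(n, probs)

    chroms: list[str] = []
    pos_parts: list[np.ndarray] = []
    strand_parts: list[np.ndarray] = []

    # genic insertions: uniform within the gene body, sense with sense_prob
    for g, k in zip(genes, region_counts[:-1]):
        k = int(k)
        if k == 0:
            continue
        positions = rng.integers(g.start, g.end, size=k)
        sense = rng.random(k) < config.sense_prob
        other = "-" if g.strand == "+" else "+"
        chroms.extend([g.chrom] * k)
        pos_parts.append(positions)
        strand_parts.append(np.where(sense, g.strand, other))

    # intergenic insertions: uniform over the genome, rejection-sampled out of
    # gene bodies via sorted-span lookup (genes are disjoint by construction)
    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    for c in {g.chrom for g in genes}:
        spans = sorted((g.start, g.end) for g in genes if g.chrom == c)
        starts_by_chrom[c] = np.array([s for s, _ in spans])
        ends_by_chrom[c] = np.array([e for _, e in spans])
    n_inter = int(region_counts[-1])
    while n_inter > 0:
        ci = rng.integers(1, config.n_chroms + 1, size=n_inter)
        p = rng.integers(0, config.chrom_length, size=n_inter)
        s = rng.choice(np.array(["+", "-"]), size=n_inter)
        keep = np.ones(n_inter, dtype=bool)
        for c in starts_by_chrom:
            mask = ci == int(c[3:])
            if not mask.any():
                continue
            idx = np.searchsorted(starts_by_chrom[c], p[mask], side="right") - 1
            in_gene = (idx >= 0) & (p[mask] < ends_by_chrom[c][np.maximum(idx, 0)])
            sub = keep[mask]
            sub[in_gene] = False
            keep[mask] = sub
        ci, p, s = ci[keep], p[keep], s[keep]
        chroms.extend(f"chr{int(c)}" for c in ci)
        pos_parts.append(p)
        strand_parts.append(s)
        n_inter -= int(keep.sum())

    if pos_parts:
        pos = np.concatenate(pos_parts)
        strands = np.concatenate(strand_parts)
    else:
        pos = np.empty(0, dtype=int)
        strands = np.empty(0, dtype="U1")
    # PCR duplication: a site is emitted as two reads with duplicate_rate
    dup = rng.random(len(pos)) < config.duplicate_rate

    records: list[AlignmentRecord] = []
    prefix = channel.lower()
    for i, (chrom, pvt, strand, d) in enumerate(zip(chroms, pos, strands, dup)):
        pvt = int(pvt)
        if strand == "+":
            start, end = pvt, pvt + READ_LENGTH
        else:
            start, end = max(0, pvt - READ_LENGTH + 1), pvt + 1
        rec = AlignmentRecord(
            read_id=f"{prefix}_{i}", chrom=chrom, start=start, end=end,
            strand=str(strand), mapq=60,
        )
        records.append(rec)
        if d:
            records.append(rec)
    return records


def simulate_screen(
    config: ScreenSimConfig, genes: list[GeneModel] | None = None
) -> tuple[set[InsertionSite], set[InsertionSite], SimTruth]:
    """Simulate both sorted channels and collapse reads to unique sites."""
    if genes is None:
        genes = simulate_annotation(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    reads_high = _simulate_channel_reads(config, genes, HIGH, config.n_insertions_high, rng)
    reads_low = _simulate_channel_reads(config, genes, LOW, config.n_insertions_low, rng)
    sites_high = extract_insertion_sites(reads_high, HIGH)
    sites_low = extract_insertion_sites(reads_low, LOW)

    from .genes import count_sense_insertions

    table = count_sense_insertions(sites_high, sites_low, genes)
    truth = SimTruth(
        planted=config.planted,
        realized_sense_high=dict(zip(table.counts["gene"], table.counts["sense_high"].astype(int))),
        realized_sense_low=dict(zip(table.counts["gene"], table.counts["sense_low"].astype(int))),
    )
    return sites_high, sites_low, truth


@dataclass
class RecoveryReport:
    """Detection outcome per planted regulator plus the realized FDP."""

    rows: list[dict]
    n_significant: int
    n_false: int

    @property
    def recall(self) -> float:
        if not self.rows:
            return float("nan")
        return sum(r["detected"] and r["direction_correct"] for r in self.rows) / len(self.rows)

    @property
    def fdp(self) -> float:
        return self.n_false / max(1, self.n_significant)


def evaluate_recovery(
    results: Sequence[EnrichmentResult],
    truth: SimTruth,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Score a screen's results against the simulator's planted truth."""
    by_gene = {r.gene: r for r in results}
    planted_names = {p.gene for p in truth.planted}
    known = set(truth.realized_sense_high)
    rows = []
    for p in truth.planted:
        if p.gene not in known:
            raise ValueError(f"planted gene {p.gene!r} absent from the simulated annotation")
        r = by_gene.get(p.gene)
        detected = bool(r and r.p_adj < alpha)
        want = "HIGH_ENRICHED" if p.channel == HIGH else "LOW_ENRICHED"
        rows.append(
            {
                "gene": p.gene,
                "channel": p.channel,
                "fold": p.fold,
                "detected": detected,
                "direction_correct": bool(detected and r.direction == want),
            }
        )
    significant = [r for r in results if r.p_adj < alpha]
    n_false = sum(r.gene not in planted_names for r in significant)
    return RecoveryReport(rows=rows, n_significant=len(significant), n_false=n_false)
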