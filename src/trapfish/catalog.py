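"""Insertion-site catalogs from aligned gene-trap reads.

A haploid gene-trap screen sequences the genomic junction next to each
retroviral cassette integration.  Every mapped read therefore marks one
candidate insertion; PCR amplification produces many reads at identical
coordinates, which must be collapsed so that each unique integration event
is counted once.  The integration-proximal base is the 5' end of the read
in read orientation: the leftmost aligned base for a plus-strand read and
the rightmost for a minus-strand read.

Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

HIGH = "HIGH"
LOW = "LOW"
CHANNELS = (HIGH, LOW)


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read (or a BED6 row standing in for one)."""

    read_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    mapq: int = 0
    is_unmapped: bool = False
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if not self.is_unmapped:
            if self.start < 0 or self.start >= self.end:
                raise ValueError(
                    f"invalid interval [{self.start}, {self.end}) for read {self.read_id!r}"
                )
            if self.strand not in ("+", "-"):
                raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True, order=True)
class InsertionSite:
    """One deduplicated gene-trap integration event.

    Identity within a channel is (chrom, pos, strand); ``pos`` is the
    0-based coordinate of the integration-proximal base.
    """

    chrom: str
    pos: int
    strand: str
    channel: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")


def _iter_sam(path: str, mode: str) -> Iterator[AlignmentRecord]:
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            yield AlignmentRecord(
                read_id=aln.query_name or "",
                chrom=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                mapq=aln.mapping_quality,
            )


def _iter_bed6(path: str) -> Iterator[AlignmentRecord]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=1):
            if not row or row[0].startswith(("#", "track", "browser")):
                continue
            if len(row) < 6:
                raise ValueError(f"{path}: row {i}: BED6 needs 6 columns, got {len(row)}")
            chrom, start, end, name, score, strand = row[:6]
            try:
                start_i, end_i = int(start), int(end)
                score_i = int(float(score))
            except ValueError as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
            yield AlignmentRecord(
                read_id=name, chrom=chrom, start=start_i, end=end_i,
                strand=strand, mapq=score_i,
            )


def read_alignments(path: str | Path, fmt: str) -> Iterator[AlignmentRecord]:
    """Stream mapped primary alignments from SAM, BAM or BED6.

    Unmapped and secondary records are skipped.  For BED6 input the score
    column is carried as ``mapq``.
    """
    path = str(path)
    fmt = fmt.lower()
    if fmt == "sam":
        return _iter_sam(path, "r")
    if fmt == "bam":
        return _iter_sam(path, "rb")
    if fmt in ("bed", "bed6"):
        return _iter_bed6(path)
    raise ValueError(f"unknown alignment format {fmt!r} (expected sam, bam or bed)")


def insertion_coordinate(record: AlignmentRecord) -> int:
    """5'-most aligned base in read orientation (trap-proximal base)."""
    return record.start if record.strand == "+" else record.end - 1


def extract_insertion_sites(
    alignments: Iterable[AlignmentRecord],
    channel: str,
    min_mapq: int = 0,
) -> set[InsertionSite]:
    """Collapse reads to unique insertion sites keyed by (chrom, pos, strand).

    Reads mapping to identical coordinates are counted only once; records
    below ``min_mapq`` are dropped.
    """
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
    sites: set[InsertionSite] = set()
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary or rec.mapq < min_mapq:
            continue
        sites.add(
            InsertionSite(
                chrom=rec.chrom,
                pos=insertion_coordinate(rec),
                strand=rec.strand,
                channel=channel,
            )
        )
    return sites


def write_sites_bed(sites: Iterable[InsertionSite], path: str | Path) -> None:
    """Write unique sites as BED6 (name = channel, score = 0)."""
    rows = sorted(sites)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for s in rows:
            w.writerow([s.chrom, s.pos, s.pos + 1, s.channel, 0, s.strand])


def read_sites_bed(path: str | Path, channel: str) -> set[InsertionSite]:
    """Read a BED6 of unique 1-bp sites back into a channel's catalog."""
    return {
        InsertionSite(chrom=r.chrom, pos=r.start, strand=r.strand, channel=channel)
        for r in _iter_bed6(str(path))
    }
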