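"""Sequence-feature scans for mitochondrial presequences (MTS).

Matrix processing peptidase (MPP) removes N-terminal presequences and
prefers substrates with an arginine two or three residues upstream of the
scissile bond (the "arginine rules", R-2 / R-3).  These scans inventory
arginines near the N-terminus, enumerate arginine-rule cleavage candidates,
compute sliding-window hydropathy (Kyte-Doolittle by default), and locate
runs of mostly uncharged/apolar residues of the kind that can stall import
at the inner-membrane translocase and act as stop-transfer elements.

All residue positions reported are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Kyte & Doolittle hydropathy index
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

CHARGED_DEFAULT = frozenset("DEKRH")


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[ProteinSequence]:
    from Bio import SeqIO

    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def arginine_positions(seq: ProteinSequence, first_n: int = 50) -> list[int]:
    """1-based positions of arginines within the first ``first_n`` residues."""
    if first_n < 1:
        raise ValueError("first_n must be >= 1")
    limit = min(first_n, len(seq))
    return [i + 1 for i in range(limit) if seq.residues[i] == "R"]


@dataclass(frozen=True)
class CleavageCandidate:
    """MPP cleavage candidate: scissile bond after residue ``after``."""

    after: int  # cleavage between residues after and after+1 (1-based)
    rules: tuple[str, ...]  # triggering rules, e.g. ("R-2",) or ("R-2", "R-3")
    arginines: tuple[int, ...]  # the arginine position(s) behind each rule


_RULE_OFFSETS = {"R-2": 2, "R-3": 3, "R-10": 10}


def mpp_candidate_sites(
    seq: ProteinSequence, rules: Iterable[str] = ("R-2", "R-3")
) -> list[CleavageCandidate]:
    """Arginine-rule cleavage candidates.

    Rule ``R-j`` places the scissile bond after residue ``k`` when residue
    ``k - j + 1`` is arginine (the arginine sits j positions upstream of the
    bond).  A bond beyond the final residue is not a cleavage and is not
    reported.  Candidates at the same bond via different rules are merged.
    """
    if len(seq) < 3:
        raise ValueError("sequence too short for arginine-rule scanning")
    rules = tuple(rules)
    for r in rules:
        if r not in _RULE_OFFSETS:
            raise ValueError(f"unknown rule {r!r}; known: {sorted(_RULE_OFFSETS)}")
    hits: dict[int, list[tuple[str, int]]] = {}
    for pos in arginine_positions(seq, first_n=len(seq)):
        for rule in rules:
            after = pos + _RULE_OFFSETS[rule] - 1
            if after >= len(seq):  # bond would fall beyond the chain
                continue
            hits.setdefault(after, []).append((rule, pos))
    return [
        CleavageCandidate(
            after=k,
            rules=tuple(r for r, _ in sorted(hits[k])),
            arginines=tuple(p for _, p in sorted(hits[k])),
        )
        for k in sorted(hits)
    ]


@dataclass(frozen=True)
class HydropathyProfile:
    positions: tuple[int, ...]  # 1-based window centers
    scores: tuple[float, ...]
    window: int
    scale_name: str


def hydropathy_scan(
    seq: ProteinSequence,
    window: int = 9,
    scale: dict[str, float] | None = None,
    scale_name: str = "Kyte-Doolittle",
) -> HydropathyProfile:
    """Sliding-window mean hydropathy; score at each window center."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    scale = scale or KYTE_DOOLITTLE
    vals = np.array([scale[r] for r in seq.residues], dtype=float)
    kernel = np.ones(window) / window
    scores = np.convolve(vals, kernel, mode="valid")
    half = window // 2
    positions = tuple(range(half + 1, half + 1 + len(scores)))
    return HydropathyProfile(
        positions=positions,
        scores=tuple(float(s) for s in scores),
        window=window,
        scale_name=scale_name,
    )


def uncharged_segments(
    seq: ProteinSequence,
    min_len: int = 15,
    max_charged_frac: float = 0.2,
    charged_set: frozenset[str] = CHARGED_DEFAULT,
) -> list[tuple[int, int]]:
    """Maximal mostly-uncharged runs (1-based inclusive start/end).

    A window of length ``min_len`` qualifies when its charged-residue
    fraction is at most ``max_charged_frac``.  Reported segments are the
    maximal runs of residues covered by at least one qualifying window, so
    they are disjoint, sorted and each at least ``min_len`` long; every
    residue in a segment lies in some window satisfying the charge bound.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    n = len(seq)
    if n < min_len:
        return []
    charged = np.array([r in charged_set for r in seq.residues], dtype=int)
    cum = np.concatenate([[0], np.cumsum(charged)])
    max_charged = max_charged_frac * min_len
    ok = [
        (cum[i + min_len] - cum[i]) <= max_charged + 1e-12
        for i in range(n - min_len + 1)
    ]
    segments: list[tuple[int, int]] = []
    for i, good in enumerate(ok):
        if not good:
            continue
        start, end = i + 1, i + min_len  # 1-based inclusive residue span
        if segments and start <= segments[-1][1] + 1:
            segments[-1] = (segments[-1][0], max(segments[-1][1], end))
        else:
            segments.append((start, end))
    return segments
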