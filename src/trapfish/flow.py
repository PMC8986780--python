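"""Flow-cytometry-derived quantifications.

Three small procedures used around a FACS reporter system:

* ``chop_neon_ratio`` — the transfection-gated reporter ratio: mean reporter
  (mNeon) intensity of the top fraction of marker-positive (mCherry+)
  events divided by the mean reporter intensity of marker-negative events,
  optionally after background subtraction.
* ``competition_normalize`` — competitive-growth timecourses of sgRNA-
  carrying (lineage-marked) cells, normalized per day to a non-targeting
  control (NTC) and to a reference day.
* ``growth_ratio`` — elementwise treated/control cell-count ratios.

Events are plain tabular text, one row per event; binary cytometry formats
are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

NTC = "NTC"


@dataclass
class FlowEventTable:
    """Per-event fluorescence intensities over named channels."""

    sample_id: str
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if self.events.empty:
            raise ValueError("event table must contain at least one event")
        if (self.events.select_dtypes("number") < 0).any().any():
            raise ValueError("intensities must be non-negative")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.events.columns:
            raise KeyError(f"channel {name!r} not in event table ({list(self.events.columns)})")
        return self.events[name].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "FlowEventTable":
        return cls(sample_id=sample_id or str(path), events=pd.read_csv(path, sep="\t"))


def marker_threshold_from_control(
    control: FlowEventTable, marker: str, quantile: float = 0.999
) -> float:
    """Positivity gate from an untransfected control: its 99.9th percentile."""
    return float(np.quantile(control.channel(marker), quantile))


def chop_neon_ratio(
    events: FlowEventTable,
    reporter: str,
    marker: str,
    positive_threshold: float,
    top_frac: float = 0.10,
    subtract_background: float | None = None,
) -> float:
    """Transfection-gated reporter ratio.

    Marker-positive events are those above ``positive_threshold``; the
    numerator is the mean reporter intensity over the top ``top_frac`` of
    marker-positive events ranked by marker intensity, the denominator the
    mean reporter intensity of marker-negative events.  An optional
    background intensity is subtracted from both means before division.
    Ties at the top-fraction boundary are broken by stable event order.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    rep = events.channel(reporter)
    mk = events.channel(marker)
    positive = mk > positive_threshold
    negative = ~positive
    if not positive.any():
        raise ValueError("empty marker-positive gate")
    if not negative.any():
        raise ValueError("empty marker-negative gate")
    pos_idx = np.flatnonzero(positive)
    order = pos_idx[np.argsort(-mk[pos_idx], kind="stable")]
    n_top = max(1, int(np.floor(top_frac * len(pos_idx))))
    numerator = float(rep[order[:n_top]].mean())
    denominator = float(rep[negative].mean())
    if subtract_background is not None:
        numerator -= subtract_background
        denominator -= subtract_background
    if denominator <= 0:
        raise ValueError("marker-negative mean is non-positive after background subtraction")
    return numerator / denominator


@dataclass
class CompetitionTimecourse:
    """Percent lineage-marker-positive cells per sgRNA label per day."""

    table: pd.DataFrame  # index: sgRNA label, columns: day (numeric), values: percent

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError("percentages must lie in [0, 100]")
        if NTC not in self.table.index:
            raise ValueError(f"timecourse must contain the {NTC!r} reference label")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompetitionTimecourse":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = [float(c) for c in df.columns]
        return cls(df)


def competition_normalize(
    tc: CompetitionTimecourse, reference_day: float = 7
) -> pd.DataFrame:
    """Normalize each sgRNA's marker-positive percentage to NTC and a reference day.

    value(sg, d) = [pct(sg, d) / pct(NTC, d)] / [pct(sg, ref) / pct(NTC, ref)].
    The NTC row maps to 1.0 at every day.
    """
    df = tc.table.astype(float)
    if reference_day not in df.columns:
        raise ValueError(f"reference day {reference_day} not present in the timecourse")
    ntc = df.loc[NTC]
    if (ntc == 0).any():
        raise ValueError("NTC percentage is zero at some day; normalization undefined")
    ref = df[reference_day]
    if (ref == 0).any():
        raise ValueError("zero percentage at the reference day; normalization undefined")
    per_day = df.div(ntc, axis=1)
    return per_day.div(per_day[reference_day], axis=0)


def growth_ratio(counts_treated, counts_control) -> np.ndarray:
    """Elementwise treated/control cell-count ratios over matched timepoints."""
    t = np.asarray(counts_treated, dtype=float)
    c = np.asarray(counts_control, dtype=float)
    if t.shape != c.shape:
        raise ValueError("treated and control series must have matching timepoints")
    if np.any(c <= 0):
        raise ValueError("control counts must be positive")
    return t / c


def simulate_flow_events(
    seed: int,
    n_events: int = 10_000,
    transfected_frac: float = 0.3,
    reporter_shift: float = 5.0,
    marker_mu: float = np.log(100.0),
    marker_sigma: float = 0.5,
    marker_shift: float = 50.0,
    reporter_mu: float = np.log(100.0),
    reporter_sigma: float = 0.3,
    sample_id: str = "sim",
) -> FlowEventTable:
    """Synthetic two-channel event table with a transfected subpopulation.

    Marker and reporter intensities are log-normal; transfected events have
    their marker multiplied by ``marker_shift`` and their reporter by
    ``reporter_shift``, emulating co-transfection of the marker with an
    activating construct.
    """
    rng = np.random.default_rng(seed)
    transfected = rng.random(n_events) < transfected_frac
    marker = rng.lognormal(marker_mu, marker_sigma, n_events)
    reporter = rng.lognormal(reporter_mu, reporter_sigma, n_events)
    marker = np.where(transfected, marker * marker_shift, marker)
    reporter = np.where(transfected, reporter * reporter_shift, reporter)
    return FlowEventTable(
        sample_id=sample_id,
        events=pd.DataFrame({"mCherry": marker, "mNeon": reporter}),
    )
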