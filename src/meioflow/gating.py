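"""Threshold gating of bi-fluorescent protoplast events.

Events are classified into four genotype classes — RFP, GFP, GFP_RFP (double
positive) and WT — from two fluorescence channels only: ``FITC.A`` (GFP
readout) and ``PE.CF594.A`` (RFP readout).  A cell is GFP-positive when
``560 < FITC.A < 10000`` and RFP-positive when ``1000 < PE.CF594.A < 10000``;
the 10,000 cap keeps saturated cells out of the fluorescent classes (they
fall to WT, so counts stay conserved).  All comparisons are strict, so an
event sitting exactly on a cut falls to the negative side.

Two gate variants exist: fluorescence-only, and a quality variant that first
keeps only events strictly inside scatter/autofluorescence bounds
(FSC.H > 55000, FSC.A < 200000, 450 < SSC.H < 3500, BV605.A > 800,
BV510.A > 800) before classifying.  Classification is on linear intensities;
log10 scaling is purely for display.

For downstream modelling the four classes collapse to three categories:
RFP, GFP+GFP_RFP combined, and WT.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import MissingChannelError
from .fcs import EventTable

__all__ = [
    "GateVariant",
    "ClassLabel",
    "ThresholdSet",
    "ClassCounts",
    "default_thresholds",
    "apply_quality_filter",
    "classify_event",
    "classify_events",
    "tabulate_counts",
]

Bounds = tuple[float | None, float | None]  # (min, max); None = no bound


class GateVariant(str, enum.Enum):
    """Which thresholding recipe to apply."""

    RFP_GFP_ONLY = "rfp_gfp_only"
    QUALITY_RFP_GFP = "quality_rfp_gfp"


class ClassLabel(str, enum.Enum):
    RFP = "RFP"
    GFP = "GFP"
    GFP_RFP = "GFP_RFP"
    WT = "WT"


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel min/max cuts defining the gates.

    ``fluorescence`` holds the positivity windows for the GFP and RFP readout
    channels; ``quality`` holds optional pre-filter bounds on scatter and
    autofluorescence channels (empty for the fluorescence-only variant).
    Wherever both bounds are set, min < max.
    """

    fluorescence: dict[str, Bounds] = field(
        default_factory=lambda: {"FITC.A": (560.0, 10_000.0), "PE.CF594.A": (1_000.0, 10_000.0)}
    )
    quality: dict[str, Bounds] = field(default_factory=dict)
    gfp_channel: str = "FITC.A"
    rfp_channel: str = "PE.CF594.A"

    def __post_init__(self) -> None:
        for block in (self.fluorescence, self.quality):
            for ch, (lo, hi) in block.items():
                if lo is not None and hi is not None and not lo < hi:
                    raise ValueError(f"{ch}: min {lo} must be < max {hi}")
        for ch in (self.gfp_channel, self.rfp_channel):
            lo, _ = self.fluorescence[ch]
            if lo is not None and lo <= 0:
                raise ValueError(f"{ch}: fluorescence positive-cut must be positive")


#: The published mean-fluorescence-intensity cuts for the quality block.
_QUALITY_BOUNDS: dict[str, Bounds] = {
    "FSC.H": (55_000.0, None),
    "FSC.A": (None, 200_000.0),
    "SSC.H": (450.0, 3_500.0),
    "BV605.A": (800.0, None),
    "BV510.A": (800.0, None),
}


def default_thresholds(variant: GateVariant | str = GateVariant.QUALITY_RFP_GFP) -> ThresholdSet:
    """Return the published threshold values for a gate variant.

    Both variants share the same fluorescence cuts (FITC.A window 560–10,000,
    PE.CF594.A window 1,000–10,000); only the quality variant carries the
    scatter/autofluorescence pre-filter bounds.
    """
    variant = GateVariant(variant)
    quality = dict(_QUALITY_BOUNDS) if variant is GateVariant.QUALITY_RFP_GFP else {}
    return ThresholdSet(quality=quality)


@dataclass(frozen=True)
class ClassCounts:
    """Three-category counts for one sample after gating.

    ``y1`` counts RFP, ``y2`` counts GFP plus GFP_RFP combined, ``y3`` counts
    WT; ``n_total`` is the number of quality-passing events, and
    ``y1 + y2 + y3 == n_total`` always.
    """

    sample_id: str
    y1: int
    y2: int
    y3: int

    def __post_init__(self) -> None:
        if min(self.y1, self.y2, self.y3) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.y1 + self.y2 + self.y3

    def as_array(self) -> np.ndarray:
        return np.array([self.y1, self.y2, self.y3], dtype=float)


def _strict_window(values: np.ndarray, bounds: Bounds) -> np.ndarray:
    lo, hi = bounds
    mask = np.ones(len(values), dtype=bool)
    if lo is not None:
        mask &= values > lo
    if hi is not None:
        mask &= values < hi
    return mask


def apply_quality_filter(table: EventTable, thresholds: ThresholdSet) -> EventTable:
    """Keep only events strictly inside every configured quality bound.

    With no quality bounds configured (the fluorescence-only variant) the
    input is returned unchanged.  Raises :class:`MissingChannelError` if a
    bounded channel is absent.
    """
    if not thresholds.quality:
        return table
    mask = np.ones(len(table), dtype=bool)
    for ch, bounds in thresholds.quality.items():
        mask &= _strict_window(table.column(ch), bounds)
    return table.select(mask)


#: Integer codes used internally; index order matches _CODE_LABELS.
_CODE_LABELS = (ClassLabel.WT, ClassLabel.RFP, ClassLabel.GFP, ClassLabel.GFP_RFP)


def _classify_codes(table: EventTable, thresholds: ThresholdSet) -> np.ndarray:
    """Per-event integer codes: 0=WT, 1=RFP, 2=GFP, 3=GFP_RFP."""
    gfp = _strict_window(table.column(thresholds.gfp_channel),
                         thresholds.fluorescence[thresholds.gfp_channel])
    rfp = _strict_window(table.column(thresholds.rfp_channel),
                         thresholds.fluorescence[thresholds.rfp_channel])
    return rfp.astype(np.int8) + 2 * gfp.astype(np.int8)


def classify_events(table: EventTable, thresholds: ThresholdSet) -> list[ClassLabel]:
    """Classify every event into exactly one :class:`ClassLabel`.

    GFP-positive and RFP-positive are strict windows on the two readout
    channels; double positives are GFP_RFP, and anything outside both
    windows (including saturated events beyond a cap) is WT.
    """
    codes = _classify_codes(table, thresholds)
    return [_CODE_LABELS[c] for c in codes]


def classify_event(event: Mapping[str, float] | "np.ndarray", thresholds: ThresholdSet,
                   channels: list[str] | None = None) -> ClassLabel:
    """Classify a single event given as a channel->value mapping."""
    if channels is not None:
        event = dict(zip(channels, np.asarray(event, dtype=float)))
    for ch in (thresholds.gfp_channel, thresholds.rfp_channel):
        if ch not in event:
            raise MissingChannelError(ch)
    table = EventTable("_one", list(event.keys()), np.array([list(event.values())], dtype=float))
    return classify_events(table, thresholds)[0]


def tabulate_counts(table: EventTable, thresholds: ThresholdSet) -> ClassCounts:
    """Collapse class labels into the three modelling categories.

    The input is expected to be quality-filtered already (or gated with the
    fluorescence-only variant).  GFP and GFP_RFP are pooled because the two
    populations are not separable on these channels.
    """
    codes = _classify_codes(table, thresholds)
    tally = np.bincount(codes, minlength=4)
    y1 = int(tally[1])          # RFP only
    y2 = int(tally[2] + tally[3])  # GFP pooled with GFP_RFP
    y3 = int(tally[0])          # WT
    assert y1 + y2 + y3 == len(table)
    return ClassCounts(table.sample_id, y1, y2, y3)
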