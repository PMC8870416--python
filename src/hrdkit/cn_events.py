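"""Copy-number event calling from segmented profiles.

The pipeline is: significance filter -> purity adjustment -> gain/loss
classification -> merge of adjacent same-state events -> minimum-length
artifact filter.  Merging precedes the length filter because sub-megabase
fragments of one biological event are segmentation artifacts, not events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .genome import GenomeModel, SegmentProfile

__all__ = [
    "CNEvent",
    "CNEventSet",
    "purity_adjust",
    "call_events",
    "baf_borderline_filter",
    "events_to_bed",
]

#: Default calling thresholds on purity-adjusted copy number: half-integer
#: midpoints between diploid (2) and a single-copy change.
GAIN_CN = 2.5
LOSS_CN = 1.5
SIGNIFICANCE = 0.001
MIN_LENGTH = 1_000_000
BAF_BAND = (0.3, 0.7)


@dataclass(frozen=True)
class CNEvent:
    chromosome: str
    start: int
    end: int
    state: str  # "gain" | "loss"
    copy_number: float  # purity-adjusted
    mean_baf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.state not in ("gain", "loss"):
            raise ValueError(f"unknown event state {self.state!r}")
        if self.start >= self.end:
            raise ValueError("event must have positive length")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CNEventSet:
    """Filtered gain/loss events for one sample plus the filter provenance."""

    sample_id: str
    events: list[CNEvent]
    provenance: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def total_length(self) -> int:
        return sum(e.length for e in self.events)

    def subset(self, state: str) -> "CNEventSet":
        return CNEventSet(
            sample_id=self.sample_id,
            events=[e for e in self.events if e.state == state],
            provenance=dict(self.provenance),
        )


def purity_adjust(log2_ratio, purity: float):
    """Tumor copy number from an observed log2 ratio under the two-component
    tumor/normal mixture with a diploid normal.

    The observed ratio is ``p * n_t / 2 + (1 - p)``; inverting gives
    ``n_t = (2 * 2**log2 - 2 * (1 - p)) / p``, clamped at zero.  At purity 1
    this reduces to ``2 * 2**log2``.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity {purity} outside (0, 1]")
    ratio = np.power(2.0, np.asarray(log2_ratio, dtype=float))
    n_t = (2.0 * ratio - 2.0 * (1.0 - purity)) / purity
    result = np.maximum(n_t, 0.0)
    return float(result) if np.isscalar(log2_ratio) else result


def _classify(cn: float, gain_cn: float, loss_cn: float) -> Optional[str]:
    if cn >= gain_cn:
        return "gain"
    if cn <= loss_cn:
        return "loss"
    return None


def call_events(
    profile: SegmentProfile,
    gain_cn: float = GAIN_CN,
    loss_cn: float = LOSS_CN,
    significance: float = SIGNIFICANCE,
    min_length: int = MIN_LENGTH,
    merge: bool = True,
    merge_gap: int = 0,
) -> CNEventSet:
    """Call gain/loss events from a segmented profile.

    Order of operations: (1) drop segments whose p-value exceeds
    ``significance`` (segments without a p-value pass); (2) purity-adjust and
    classify each segment; (3) merge adjacent same-state events whose gap is
    at most ``merge_gap`` (when ``merge``); (4) drop events shorter than
    ``min_length``.  Copy-neutral segments never produce events.
    """
    raw: list[CNEvent] = []
    for seg in profile:
        if seg.p_value is not None and seg.p_value > significance:
            continue
        cn = purity_adjust(seg.log2_ratio, profile.purity)
        state = _classify(cn, gain_cn, loss_cn)
        if state is None:
            continue
        raw.append(
            CNEvent(
                chromosome=seg.chromosome,
                start=seg.start,
                end=seg.end,
                state=state,
                copy_number=cn,
                mean_baf=seg.mean_baf,
            )
        )

    if merge:
        raw = _merge_adjacent(raw, merge_gap)

    events = [e for e in raw if e.length >= min_length]
    return CNEventSet(
        sample_id=profile.sample_id,
        events=events,
        provenance={
            "significance": significance,
            "min_length": min_length,
            "gain_cn": gain_cn,
            "loss_cn": loss_cn,
            "merge": merge,
            "merge_gap": merge_gap,
            "purity": profile.purity,
        },
    )


def _merge_adjacent(events: list[CNEvent], merge_gap: int) -> list[CNEvent]:
    """Merge consecutive same-state events on one chromosome separated by at
    most ``merge_gap`` bp; copy number and BAF are length-weighted."""
    merged: list[CNEvent] = []
    for ev in events:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.chromosome == ev.chromosome
            and prev.state == ev.state
            and ev.start - prev.end <= merge_gap
        ):
            w1, w2 = prev.length, ev.length
            bafs = [(b, w) for b, w in ((prev.mean_baf, w1), (ev.mean_baf, w2)) if b is not None]
            baf = sum(b * w for b, w in bafs) / sum(w for _, w in bafs) if bafs else None
            merged[-1] = CNEvent(
                chromosome=prev.chromosome,
                start=prev.start,
                end=ev.end,
                state=prev.state,
                copy_number=(prev.copy_number * w1 + ev.copy_number * w2) / (w1 + w2),
                mean_baf=baf,
            )
        else:
            merged.append(ev)
    return merged


def baf_borderline_filter(
    events: CNEventSet, band: tuple[float, float] = BAF_BAND
) -> CNEventSet:
    """Remove events whose mean BAF falls strictly inside the balanced band.

    Events with BAF inside the open interval ``(low, high)`` look allelically
    balanced and are treated as borderline; events lacking a BAF are kept.
    """
    low, high = band
    if low >= high:
        raise ValueError(f"invalid BAF band {band}: low must be < high")
    kept = [
        e for e in events if e.mean_baf is None or not (low < e.mean_baf < high)
    ]
    provenance = dict(events.provenance)
    provenance["baf_band"] = band
    return CNEventSet(sample_id=events.sample_id, events=kept, provenance=provenance)


def events_to_bed(events: CNEventSet) -> pd.DataFrame:
    """Events as a BED-like frame: name = state, score = adjusted CN x 100."""
    return pd.DataFrame(
        [
            {
                "chromosome": e.chromosome,
                "start": e.start,
                "end": e.end,
                "name": e.state,
                "score": int(round(e.copy_number * 100)),
            }
            for e in events
        ],
        columns=["chromosome", "start", "end", "name", "score"],
    )
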