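"""The genomic-instability (GI) parameter vector and median/quartile binning.

The vector summarizes one sample's filtered copy-number events and LOH
segments as named burden statistics: counts, summed lengths, and percentages
of the autosomal genome, on the unfiltered and BAF-borderline-filtered event
tiers, plus long-LOH (>10 Mb and >15 Mb) spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cn_events import CNEventSet
from .genome import GenomeModel
from .loh import LOHSegment, long_loh_events

logger = logging.getLogger(__name__)

__all__ = [
    "PARAMETER_NAMES",
    "CategorizedParameter",
    "compute_gi_vector",
    "categorize",
    "gi_table",
]

LOH_SPAN_LONG = 15_000_000
LOH_SPAN_SHORT = 10_000_000

#: Stable column order for the GI vector.  The loss tier carries count,
#: length and percentage alike (which of the three the original 24 comprised
#: is ambiguous; all are emitted).
PARAMETER_NAMES: tuple[str, ...] = (
    "n_events", "mean_event_length", "altered_length", "pct_genome_altered",
    "n_events_baf", "mean_event_length_baf", "altered_length_baf", "pct_genome_altered_baf",
    "n_gains", "gain_length", "pct_genome_gains",
    "n_gains_baf", "gain_length_baf", "pct_genome_gains_baf",
    "n_losses", "loss_length", "pct_genome_losses",
    "loh_length", "pct_genome_loh",
    "n_loh_gt15mb", "loh_gt15mb_length", "pct_genome_loh_gt15mb",
    "n_loh_gt10mb", "loh_gt10mb_length", "pct_genome_loh_gt10mb",
)


def _tier(events: CNEventSet, denom: int) -> dict[str, float]:
    n = len(events)
    total = events.total_length
    return {
        "n": float(n),
        "mean_length": total / n if n else 0.0,
        "length": float(total),
        "pct": 100.0 * total / denom,
    }


def compute_gi_vector(
    events: CNEventSet,
    events_baf_filtered: CNEventSet,
    loh: Sequence[LOHSegment],
    genome: GenomeModel,
) -> pd.Series:
    """Compute the named GI parameters for one sample.

    Percentages are ``100 * length / autosomal genome length``; the mean event
    length is 0 when there are no events (kept finite so vectors stay
    sortable).
    """
    if events.sample_id != events_baf_filtered.sample_id:
        raise ValueError(
            f"event sets belong to different samples: "
            f"{events.sample_id!r} vs {events_baf_filtered.sample_id!r}"
        )
    denom = genome.autosomal_length
    all_t = _tier(events, denom)
    all_b = _tier(events_baf_filtered, denom)
    gains = _tier(events.subset("gain"), denom)
    gains_b = _tier(events_baf_filtered.subset("gain"), denom)
    losses = _tier(events.subset("loss"), denom)

    loh_len = float(sum(s.length for s in loh))
    loh15 = long_loh_events(loh, LOH_SPAN_LONG)
    loh10 = long_loh_events(loh, LOH_SPAN_SHORT)
    loh15_len = float(sum(s.length for s in loh15))
    loh10_len = float(sum(s.length for s in loh10))

    values = {
        "n_events": all_t["n"],
        "mean_event_length": all_t["mean_length"],
        "altered_length": all_t["length"],
        "pct_genome_altered": all_t["pct"],
        "n_events_baf": all_b["n"],
        "mean_event_length_baf": all_b["mean_length"],
        "altered_length_baf": all_b["length"],
        "pct_genome_altered_baf": all_b["pct"],
        "n_gains": gains["n"],
        "gain_length": gains["length"],
        "pct_genome_gains": gains["pct"],
        "n_gains_baf": gains_b["n"],
        "gain_length_baf": gains_b["length"],
        "pct_genome_gains_baf": gains_b["pct"],
        "n_losses": losses["n"],
        "loss_length": losses["length"],
        "pct_genome_losses": losses["pct"],
        "loh_length": loh_len,
        "pct_genome_loh": 100.0 * loh_len / denom,
        "n_loh_gt15mb": float(len(loh15)),
        "loh_gt15mb_length": loh15_len,
        "pct_genome_loh_gt15mb": 100.0 * loh15_len / denom,
        "n_loh_gt10mb": float(len(loh10)),
        "loh_gt10mb_length": loh10_len,
        "pct_genome_loh_gt10mb": 100.0 * loh10_len / denom,
    }
    return pd.Series(values, index=list(PARAMETER_NAMES), name=events.sample_id)


def gi_table(vectors: Iterable[pd.Series]) -> pd.DataFrame:
    """Stack per-sample GI vectors into a samples x parameters table."""
    df = pd.DataFrame(list(vectors))
    df.index.name = "sample"
    return df


@dataclass
class CategorizedParameter:
    """Median (2-bin) or quartile (4-bin) categorization of one parameter."""

    name: str
    scheme: str  # "median" | "quartile"
    labels: pd.Series  # per-sample category label; missing values -> NA
    cuts: tuple[float, ...]


def categorize(values: pd.Series, scheme: str = "median", name: Optional[str] = None) -> CategorizedParameter:
    """Bin a cohort's parameter values at the median or quartiles.

    Cuts are right-closed: a value exactly at a cut goes to the lower bin.
    Quartiles use linear interpolation between order statistics.  Missing
    values keep a missing label.
    """
    values = pd.Series(values, dtype=float)
    name = name or (values.name if values.name is not None else "parameter")
    nonmiss = values.dropna()
    if scheme == "median":
        if len(nonmiss) < 2:
            raise ValueError("median categorization needs >= 2 non-missing values")
        cuts = (float(np.median(nonmiss)),)
        bin_labels = ["low", "high"]
    elif scheme == "quartile":
        if len(nonmiss) < 4:
            raise ValueError("quartile categorization needs >= 4 non-missing values")
        cuts = tuple(float(q) for q in np.quantile(nonmiss, [0.25, 0.5, 0.75], method="linear"))
        bin_labels = ["q1", "q2", "q3", "q4"]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    if nonmiss.nunique() == 1:
        logger.warning("parameter %s is constant; categorization is degenerate", name)

    def _label(v: float) -> Optional[str]:
        if np.isnan(v):
            return None
        for cut, lab in zip(cuts, bin_labels):
            if v <= cut:
                return lab
        return bin_labels[len(cuts)]

    labels = values.map(_label).astype("string")
    labels.name = name
    return CategorizedParameter(name=name, scheme=scheme, labels=labels, cuts=cuts)
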