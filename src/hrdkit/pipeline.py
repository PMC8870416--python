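"""End-to-end helpers wiring segmentation input to GI vectors.

These are thin compositions of :mod:`cn_events`, :mod:`loh` and
:mod:`gi_features` used by the CLI, the tests and the acceptance script.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .cn_events import (
    BAF_BAND,
    GAIN_CN,
    LOSS_CN,
    MIN_LENGTH,
    SIGNIFICANCE,
    baf_borderline_filter,
    call_events,
)
from .genome import SegmentProfile, SNPSite
from .gi_features import compute_gi_vector, gi_table
from .loh import MIN_HET_CONTROLS, MIN_SNPS, HetMask, build_het_mask, call_loh

__all__ = ["gi_for_sample", "cohort_gi_table"]


def gi_for_sample(
    profile: SegmentProfile,
    sites: Optional[Sequence[SNPSite]] = None,
    mask: Optional[HetMask] = None,
    gain_cn: float = GAIN_CN,
    loss_cn: float = LOSS_CN,
    significance: float = SIGNIFICANCE,
    min_length: int = MIN_LENGTH,
    baf_band: tuple[float, float] = BAF_BAND,
    min_snps: int = MIN_SNPS,
    min_het_controls: int = MIN_HET_CONTROLS,
) -> pd.Series:
    """Run event calling, BAF filtering and LOH calling for one sample and
    return its GI parameter vector."""
    events = call_events(
        profile, gain_cn=gain_cn, loss_cn=loss_cn,
        significance=significance, min_length=min_length,
    )
    events_baf = baf_borderline_filter(events, band=baf_band)
    loh_segments = []
    if sites:
        if mask is None:
            if isinstance(sites, dict):
                raise ValueError("array-form sites need an explicit HetMask")
            mask = build_het_mask(sites, min_het_controls=min_het_controls)
        loh_segments = call_loh(
            profile, sites, mask, baf_band=baf_band,
            min_snps=min_snps, min_length=min_length,
        )
    return compute_gi_vector(events, events_baf, loh_segments, profile.genome)


def cohort_gi_table(cohort, **kwargs) -> pd.DataFrame:
    """GI vectors for every sample of a synthetic cohort.

    The heterozygosity mask is built once from the shared control panel.
    """
    mask: Optional[HetMask] = None
    if cohort.backbone is not None:
        mask = cohort.het_mask(kwargs.get("min_het_controls", MIN_HET_CONTROLS))
    vectors = []
    for profile in cohort.profiles:
        sites = cohort.baf_arrays(profile.sample_id) if cohort.backbone is not None else None
        vectors.append(gi_for_sample(profile, sites, mask=mask, **kwargs))
    return gi_table(vectors)
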