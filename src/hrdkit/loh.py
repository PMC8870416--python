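"""Loss-of-heterozygosity calling from tumor B-allele frequencies.

Constitutively heterozygous positions come from a small panel of normal
controls; the tumor's BAF at those positions, summarized per segment, decides
allelic imbalance.  Because the shifted allele is arbitrary, BAFs are folded
onto the upper half (``0.5 + |b - 0.5|``) before taking the median, so a
region where half the SNPs drift to 0 and half to 1 is still called.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cn_events import BAF_BAND, MIN_LENGTH
from .genome import GenomeModel, SegmentProfile, SNPSite

__all__ = [
    "HetMask",
    "LOHSegment",
    "build_het_mask",
    "call_loh",
    "long_loh_events",
    "loh_to_bed",
]

MIN_HET_CONTROLS = 3
MIN_SNPS = 10
TILE_SIZE = 10_000_000


@dataclass
class HetMask:
    """Per-chromosome sorted arrays of constitutively heterozygous positions."""

    positions: dict[str, np.ndarray]
    min_het_controls: int

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"mask positions on {chrom} not strictly increasing")
            self.positions[chrom] = arr

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())


@dataclass(frozen=True)
class LOHSegment:
    chromosome: str
    start: int
    end: int
    n_informative_snps: int
    baf_deviation: float  # median folded deviation |BAF - 0.5|, in [0, 0.5]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("LOH segment must have positive length")
        if not (0.0 <= self.baf_deviation <= 0.5):
            raise ValueError(f"baf_deviation {self.baf_deviation} outside [0, 0.5]")

    @property
    def length(self) -> int:
        return self.end - self.start


def build_het_mask(
    sites: Iterable[SNPSite], min_het_controls: int = MIN_HET_CONTROLS
) -> HetMask:
    """Sites enter the mask iff no control genotype is missing and at least
    ``min_het_controls`` controls are heterozygous."""
    by_chrom: dict[str, list[int]] = {}
    for site in sites:
        if "missing" in site.control_genotypes:
            continue
        n_het = sum(g == "het" for g in site.control_genotypes)
        if n_het >= min_het_controls:
            by_chrom.setdefault(site.chromosome, []).append(site.position)
    positions = {c: np.asarray(sorted(set(p)), dtype=np.int64) for c, p in by_chrom.items()}
    return HetMask(positions=positions, min_het_controls=min_het_controls)


def _intervals_for_loh(profile: SegmentProfile, tile_size: int) -> list[tuple[str, int, int]]:
    """Evaluation intervals: the CN segmentation's own intervals, plus uncovered
    chromosome spans tiled so cnLOH in segment-free regions stays detectable."""
    intervals: list[tuple[str, int, int]] = []
    covered: dict[str, list[tuple[int, int]]] = {}
    for seg in profile:
        intervals.append((seg.chromosome, seg.start, seg.end))
        covered.setdefault(seg.chromosome, []).append((seg.start, seg.end))
    for chrom in profile.genome.names:
        length = profile.genome.lengths[chrom]
        gaps, cursor = [], 0
        for start, end in sorted(covered.get(chrom, [])):
            if start > cursor:
                gaps.append((cursor, start))
            cursor = max(cursor, end)
        if cursor < length:
            gaps.append((cursor, length))
        for gstart, gend in gaps:
            for tstart in range(gstart, gend, tile_size):
                intervals.append((chrom, tstart, min(tstart + tile_size, gend)))
    order = profile.genome.order
    intervals.sort(key=lambda iv: (order(iv[0]), iv[1]))
    return intervals


BafArrays = dict  # chrom -> (positions int64, tumor BAF float) array pair


def call_loh(
    profile: SegmentProfile,
    sites: Union[Sequence[SNPSite], BafArrays],
    mask: HetMask,
    baf_band: tuple[float, float] = BAF_BAND,
    min_snps: int = MIN_SNPS,
    min_length: int = MIN_LENGTH,
    tile_size: int = TILE_SIZE,
) -> list[LOHSegment]:
    """Call LOH segments on a profile's intervals from masked-SNP tumor BAFs.

    Per interval: collect tumor BAF at masked SNPs inside it; with at least
    ``min_snps`` informative SNPs and a median folded BAF outside the open
    balanced band, the interval is emitted as LOH.  Adjacent emitted intervals
    merge; the final minimum-length artifact filter matches event calling.
    """
    low, high = baf_band
    if low >= high:
        raise ValueError(f"invalid BAF band {baf_band}")
    # Index tumor BAF by chromosome for the masked positions only.  ``sites``
    # may be a list of SNPSite records or pre-built per-chromosome
    # (positions, BAF) array pairs.
    if isinstance(sites, dict):
        tmp = {
            chrom: (np.asarray(pos, dtype=np.int64), np.asarray(baf, dtype=float))
            for chrom, (pos, baf) in sites.items()
        }
    else:
        lists: dict[str, list[tuple[int, float]]] = {}
        for site in sites:
            if site.tumor_baf is None or np.isnan(site.tumor_baf):
                continue
            lists.setdefault(site.chromosome, []).append((site.position, site.tumor_baf))
        tmp = {}
        for chrom, pairs in lists.items():
            pairs.sort()
            tmp[chrom] = (
                np.asarray([p for p, _ in pairs], dtype=np.int64),
                np.asarray([b for _, b in pairs], dtype=float),
            )
    baf_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (pos, baf) in tmp.items():
        mask_pos = mask.positions.get(chrom)
        if mask_pos is None or len(mask_pos) == 0:
            continue
        ok = ~np.isnan(baf)
        pos, baf = pos[ok], baf[ok]
        keep = np.isin(pos, mask_pos)
        baf_by_chrom[chrom] = (pos[keep], baf[keep])

    called: list[LOHSegment] = []
    for chrom, start, end in _intervals_for_loh(profile, tile_size):
        if chrom not in baf_by_chrom:
            continue
        pos, baf = baf_by_chrom[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        if hi - lo < min_snps:
            continue
        folded = 0.5 + np.abs(baf[lo:hi] - 0.5)
        med = float(np.median(folded))
        if med > high:  # outside the open balanced band
            called.append(
                LOHSegment(
                    chromosome=chrom,
                    start=start,
                    end=end,
                    n_informative_snps=int(hi - lo),
                    baf_deviation=med - 0.5,
                )
            )

    merged = _merge_adjacent_loh(called)
    return [s for s in merged if s.length >= min_length]


def _merge_adjacent_loh(segments: list[LOHSegment]) -> list[LOHSegment]:
    merged: list[LOHSegment] = []
    for seg in segments:
        prev = merged[-1] if merged else None
        if prev is not None and prev.chromosome == seg.chromosome and seg.start <= prev.end:
            w1, w2 = prev.length, seg.length
            merged[-1] = LOHSegment(
                chromosome=prev.chromosome,
                start=prev.start,
                end=max(prev.end, seg.end),
                n_informative_snps=prev.n_informative_snps + seg.n_informative_snps,
                baf_deviation=(prev.baf_deviation * w1 + seg.baf_deviation * w2) / (w1 + w2),
            )
        else:
            merged.append(seg)
    return merged


def long_loh_events(
    loh: Iterable[LOHSegment], span_threshold: int
) -> list[LOHSegment]:
    """Subset of LOH segments strictly longer than ``span_threshold`` bp
    (10 or 15 Mb are the HRD-signature spans)."""
    return [s for s in loh if s.length > span_threshold]


def loh_to_bed(loh: Iterable[LOHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": s.chromosome,
                "start": s.start,
                "end": s.end,
                "name": "LOH",
                "score": int(round(s.baf_deviation * 1000)),
            }
            for s in loh
        ],
        columns=["chromosome", "start", "end", "name", "score"],
    )
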