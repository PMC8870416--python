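"""Core data model: genomes, segments, SNP sites, variants, clinical records.

All genomic intervals are held internally as 0-based half-open ``[start, end)``
coordinates in base pairs.  On-disk SEG-dialect files are 1-based inclusive;
the conversion lives in :mod:`hrdkit.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "GenomeModel",
    "Segment",
    "SegmentProfile",
    "SNPSite",
    "VariantRecord",
    "PatientClinicalRecord",
    "default_genome",
    "RESPONSE_CATEGORIES",
    "TUMOR_TYPES",
]

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
TUMOR_TYPES = ("ovarian", "endometrial", "breast")

# GRCh37 autosome lengths (bp), the usual reference for targeted CN panels.
_HG19_AUTOSOMES = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566,
}
_SEX_CHROMS = {"chrX": 155_270_560, "chrY": 59_373_566}


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome universe and lengths; the denominator of every
    percent-of-genome-altered statistic."""

    names: tuple[str, ...]
    lengths: dict[str, int]
    include_sex: bool = False

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        for name in self.names:
            if name not in self.lengths:
                raise ValueError(f"no length for chromosome {name!r}")
            if self.lengths[name] <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")
        if self.autosomal_length <= 0:
            raise ValueError("total autosomal length must be positive")

    @property
    def autosomal_length(self) -> int:
        """Summed length of the non-sex chromosomes."""
        return sum(
            self.lengths[n] for n in self.names if n not in ("chrX", "chrY", "X", "Y")
        )

    def order(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths and chrom in self.names

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        """Validate ``[start, end)`` against this genome; raise on violation."""
        if chrom not in self:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.lengths[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds "
                f"[0, {self.lengths[chrom]})"
            )


def default_genome(scale: float = 1.0, include_sex: bool = False) -> GenomeModel:
    """The GRCh37 autosome set, optionally down-scaled.

    ``scale=0.1`` gives the 1/10-size desk genome used by the simulator.
    """
    lengths = {c: max(1, int(round(length * scale))) for c, length in _HG19_AUTOSOMES.items()}
    names = tuple(_HG19_AUTOSOMES)
    if include_sex:
        lengths.update(
            {c: max(1, int(round(length * scale))) for c, length in _SEX_CHROMS.items()}
        )
        names = names + tuple(_SEX_CHROMS)
    return GenomeModel(names=names, lengths=lengths, include_sex=include_sex)


@dataclass(frozen=True)
class Segment:
    """One segmented interval of a copy-number profile (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    log2_ratio: float
    mean_baf: Optional[float] = None
    n_snps: int = 0
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.chromosome}:{self.start}-{self.end} has non-positive length"
            )
        if self.mean_baf is not None and not (0.0 <= self.mean_baf <= 1.0):
            raise ValueError(f"mean_baf {self.mean_baf} outside [0, 1]")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentProfile:
    """One sample's segmented genome plus its purity estimate."""

    sample_id: str
    genome: GenomeModel
    segments: list[Segment]
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity {self.purity} outside (0, 1]")
        for seg in self.segments:  # bounds before sorting: order() needs known names
            self.genome.check_interval(seg.chromosome, seg.start, seg.end)
        self.segments = sorted(
            self.segments, key=lambda s: (self.genome.order(s.chromosome), s.start)
        )
        prev: Optional[Segment] = None
        for seg in self.segments:
            if prev is not None and prev.chromosome == seg.chromosome and seg.start < prev.end:
                raise ValueError(
                    f"overlapping segments on {seg.chromosome}: "
                    f"{prev.start}-{prev.end} and {seg.start}-{seg.end}"
                )
            prev = seg

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


#: Four-state genotype code for control-panel SNPs.
GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")


@dataclass(frozen=True)
class SNPSite:
    """One SNP of the genotyping backbone: panel genotypes plus tumor BAF."""

    chromosome: str
    position: int  # 0-based
    control_genotypes: tuple[str, ...]
    tumor_baf: Optional[float] = None

    def __post_init__(self) -> None:
        for g in self.control_genotypes:
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype code {g!r}")
        if self.tumor_baf is not None and not (
            0.0 <= self.tumor_baf <= 1.0 or math.isnan(self.tumor_baf)
        ):
            raise ValueError(f"tumor_baf {self.tumor_baf} outside [0, 1]")


@dataclass(frozen=True)
class VariantRecord:
    """One curated panel variant after upstream calling and annotation."""

    sample_id: str
    gene: str
    coverage: int
    vaf: float
    classification: str  # P | LP | VUS | other
    sift_call: Optional[str] = None  # pathogenic | tolerated | None
    polyphen_call: Optional[str] = None  # pathogenic | benign | None
    pathogenic_prediction: bool = False

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")


@dataclass(frozen=True)
class PatientClinicalRecord:
    """Per-patient trial outcomes: best RECIST response and survival."""

    patient_id: str
    tumor_type: str
    histology: str
    prior_lines: int
    best_response: str
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool

    def __post_init__(self) -> None:
        if self.best_response not in RESPONSE_CATEGORIES:
            raise ValueError(
                f"unknown best_response {self.best_response!r}; "
                f"expected one of {RESPONSE_CATEGORIES}"
            )
        if self.tumor_type not in TUMOR_TYPES:
            raise ValueError(f"unknown tumor_type {self.tumor_type!r}")
        for label, months in (("pfs", self.pfs_months), ("os", self.os_months)):
            if not math.isfinite(months) or months < 0:
                raise ValueError(f"{label}_months must be finite and >= 0")
        if self.prior_lines < 0:
            raise ValueError("prior_lines must be >= 0")
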