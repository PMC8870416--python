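"""Variant qualification and the mutational HRD surrogate.

A sample is HRD when it carries at least one qualifying small variant in a
homologous-recombination-repair (HRR) gene.  Qualification demands adequate
coverage and allele frequency plus a pathogenicity rule: P/LP classification,
or a VUS with a pathogenic annotation, or a VUS called pathogenic by both
in-silico predictors (SIFT and PolyPhen).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cn_events import purity_adjust
from .genome import SegmentProfile, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PANEL_GENES",
    "HRR_GENES",
    "SampleHRDStatus",
    "qualify_variant",
    "hrd_status",
    "gene_cn_call",
]

MIN_COVERAGE = 100
MIN_VAF = 0.05  # strict: a variant at exactly 5% does not qualify
AMP_CN = 5.0
DEL_CN = 1.0

#: The 35-gene DNA-repair panel.  "RECQL" appears in some panel listings as
#: "REQL"; the default maps it to RECQL.
PANEL_GENES: tuple[str, ...] = (
    "BRCA1", "BRCA2", "BARD1", "BRIP1", "CHEK1", "CHEK2", "FAM175A", "NBN",
    "PALB2", "ATM", "MRE11A", "RAD51B", "RAD51C", "RAD51D", "RAD54L",
    "FANCI", "FANCM", "FANCA", "ERCC1", "ERCC2", "ERCC6", "RECQL", "XRCC4",
    "HELQ", "SLX4", "WRN", "ATR", "PTEN", "CCNE1", "EMSY", "TP53",
    "MLH1", "MSH2", "MSH6", "PMS2",
)

#: Default HRR gene set: the panel minus TP53, the MMR genes, the CN-only
#: targets CCNE1/EMSY, and PTEN (panel member but predominantly a PI3K-pathway
#: gene; configurable).
_NON_HRR = {"TP53", "MLH1", "MSH2", "MSH6", "PMS2", "CCNE1", "EMSY", "PTEN"}
HRR_GENES: frozenset[str] = frozenset(g for g in PANEL_GENES if g not in _NON_HRR)


@dataclass
class SampleHRDStatus:
    sample_id: str
    hrd: bool
    qualifying: list[tuple[str, str]] = field(default_factory=list)  # (gene, rule)
    gene_cn_calls: dict[str, str] = field(default_factory=dict)


def qualify_variant(
    v: VariantRecord,
    min_coverage: int = MIN_COVERAGE,
    min_vaf: float = MIN_VAF,
) -> tuple[bool, Optional[str]]:
    """Return whether a variant qualifies and the rule that fired.

    Gates: coverage >= ``min_coverage`` and VAF strictly above ``min_vaf``.
    Then: P/LP classification; or VUS with an upstream pathogenic-prediction
    flag; or VUS with both SIFT and PolyPhen pathogenic.
    """
    if v.coverage < min_coverage or v.vaf <= min_vaf:
        return False, None
    if v.classification in ("P", "LP"):
        return True, "P/LP"
    if v.classification == "VUS":
        if v.pathogenic_prediction:
            return True, "VUS+prediction"
        if v.sift_call == "pathogenic" and v.polyphen_call == "pathogenic":
            return True, "VUS+SIFT&PolyPhen"
    return False, None


def hrd_status(
    sample_id: str,
    variants: Iterable[VariantRecord],
    hrr_gene_set: Iterable[str] = HRR_GENES,
    panel_genes: Iterable[str] = PANEL_GENES,
    min_coverage: int = MIN_COVERAGE,
    min_vaf: float = MIN_VAF,
) -> SampleHRDStatus:
    """HRD is true iff any variant in an HRR gene qualifies.

    Variants in genes outside the panel are ignored with a warning.
    """
    hrr = set(hrr_gene_set)
    panel = set(panel_genes)
    qualifying: list[tuple[str, str]] = []
    for v in variants:
        if v.sample_id != sample_id:
            continue
        if v.gene not in panel:
            logger.warning(
                "sample %s: variant gene %s not in the panel; ignored", sample_id, v.gene
            )
            continue
        ok, rule = qualify_variant(v, min_coverage=min_coverage, min_vaf=min_vaf)
        if ok and v.gene in hrr:
            qualifying.append((v.gene, rule))
    return SampleHRDStatus(sample_id=sample_id, hrd=bool(qualifying), qualifying=qualifying)


def hrd_table(
    variants: Sequence[VariantRecord],
    sample_ids: Iterable[str],
    hrr_gene_set: Iterable[str] = HRR_GENES,
    **kwargs,
) -> pd.DataFrame:
    """Per-sample HRD report over a cohort's variant table."""
    rows = []
    for sid in sample_ids:
        status = hrd_status(sid, variants, hrr_gene_set=hrr_gene_set, **kwargs)
        rows.append(
            {
                "sample": sid,
                "hrd": status.hrd,
                "n_qualifying": len(status.qualifying),
                "genes": ",".join(g for g, _ in status.qualifying),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def gene_cn_call(
    profile: SegmentProfile,
    gene_intervals: pd.DataFrame,
    amp_cn: float = AMP_CN,
    del_cn: float = DEL_CN,
) -> dict[str, str]:
    """Gene-level CN calls from the length-weighted mean adjusted copy number
    over the gene interval.  Genes with no overlapping segment are "neutral
    (no data)".

    ``gene_intervals`` is a BED-style frame (chromosome, start, end, name).
    """
    calls: dict[str, str] = {}
    for row in gene_intervals.itertuples(index=False):
        chrom, gstart, gend, gene = str(row.chromosome), int(row.start), int(row.end), str(row.name)
        weighted, total_w = 0.0, 0
        for seg in profile:
            if seg.chromosome != chrom:
                continue
            ov = min(seg.end, gend) - max(seg.start, gstart)
            if ov > 0:
                weighted += purity_adjust(seg.log2_ratio, profile.purity) * ov
                total_w += ov
        if total_w == 0:
            calls[gene] = "neutral (no data)"
            continue
        mean_cn = weighted / total_w
        if mean_cn >= amp_cn:
            calls[gene] = "amplified"
        elif mean_cn <= del_cn:
            calls[gene] = "deleted"
        else:
            calls[gene] = "neutral"
    return calls
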