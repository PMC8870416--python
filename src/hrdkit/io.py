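"""Readers and writers for the text formats the pipeline touches.

Conventions
-----------
* Segments travel as SEG-style TSV with 1-based inclusive coordinates on disk
  and 0-based half-open coordinates in memory.
* SNP panels are TSV with one genotype column per control; gene panels are BED
  (0-based half-open per the BED standard); chromosome sizes are two-column
  TSV; clinical tables are CSV with months as the time unit.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import (
    GENOTYPES,
    GenomeModel,
    PatientClinicalRecord,
    Segment,
    SegmentProfile,
    SNPSite,
    VariantRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_SEG_COLUMNS = ["sample", "chromosome", "start", "end", "n_snps", "log2", "p_value", "baf"]

_GT_TO_CODE = {
    "0/0": "hom_ref", "0|0": "hom_ref", "AA": "hom_ref", "hom_ref": "hom_ref",
    "0/1": "het", "1/0": "het", "0|1": "het", "1|0": "het", "AB": "het", "het": "het",
    "1/1": "hom_alt", "1|1": "hom_alt", "BB": "hom_alt", "hom_alt": "hom_alt",
    "./.": "missing", ".": "missing", "NN": "missing", "missing": "missing", "": "missing",
}
_CODE_TO_GT = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def read_genome_sizes(path: PathLike, include_sex: bool = False) -> GenomeModel:
    """Load a two-column (chromosome, length) TSV into a :class:`GenomeModel`."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chromosome", "length"], comment="#")
    names = tuple(df["chromosome"].astype(str))
    lengths = dict(zip(names, df["length"].astype(int)))
    return GenomeModel(names=names, lengths=lengths, include_sex=include_sex)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_segments(
    path: PathLike,
    genome: GenomeModel,
    sample: Optional[str] = None,
    purity: float = 1.0,
) -> SegmentProfile:
    """Read a SEG-style TSV into a validated :class:`SegmentProfile`.

    The file is 1-based inclusive; memory is 0-based half-open. Files holding
    several samples require ``sample=`` to pick one.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chromosome", "start", "end", "log2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment file {path} missing columns: {sorted(missing)}")
    if "sample" in df.columns:
        samples = df["sample"].unique()
        if sample is not None:
            df = df[df["sample"] == sample]
            if df.empty:
                raise ValueError(f"sample {sample!r} not present in {path}")
        elif len(samples) > 1:
            raise ValueError(
                f"{path} holds {len(samples)} samples; pass sample= to select one"
            )
        else:
            sample = str(samples[0])
    if sample is None:
        sample = Path(path).stem
    segments = [
        Segment(
            chromosome=str(row.chromosome),
            start=int(row.start) - 1,  # 1-based inclusive -> 0-based half-open
            end=int(row.end),
            log2_ratio=float(row.log2),
            mean_baf=_opt_float(getattr(row, "baf", None)),
            n_snps=int(getattr(row, "n_snps", 0) or 0),
            p_value=_opt_float(getattr(row, "p_value", None)),
        )
        for row in df.itertuples(index=False)
    ]
    return SegmentProfile(sample_id=sample, genome=genome, segments=segments, purity=purity)


def write_segments(profiles: Union[SegmentProfile, Sequence[SegmentProfile]], path: PathLike) -> None:
    """Write one or more profiles as SEG-style TSV (1-based inclusive)."""
    if isinstance(profiles, SegmentProfile):
        profiles = [profiles]
    rows = []
    for prof in profiles:
        for seg in prof.segments:
            rows.append(
                {
                    "sample": prof.sample_id,
                    "chromosome": seg.chromosome,
                    "start": seg.start + 1,
                    "end": seg.end,
                    "n_snps": seg.n_snps,
                    "log2": seg.log2_ratio,
                    "p_value": seg.p_value,
                    "baf": seg.mean_baf,
                }
            )
    pd.DataFrame(rows, columns=_SEG_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_snp_table(path: PathLike, genome: GenomeModel, panel_size: int) -> list[SNPSite]:
    """Read the SNP backbone TSV: chromosome, position (1-based), one genotype
    column per control (``control_1`` ...), optional ``tumor_baf``."""
    df = pd.read_csv(path, sep="\t")
    gt_cols = [c for c in df.columns if c.startswith("control_")]
    if len(gt_cols) != panel_size:
        raise ValueError(
            f"expected {panel_size} control genotype columns, found {len(gt_cols)}"
        )
    sites = []
    for row in df.itertuples(index=False):
        genotypes = []
        for col in gt_cols:
            raw = str(getattr(row, col))
            if raw not in _GT_TO_CODE:
                raise ValueError(f"unknown genotype string {raw!r} in column {col}")
            genotypes.append(_GT_TO_CODE[raw])
        site = SNPSite(
            chromosome=str(row.chromosome),
            position=int(row.position) - 1,
            control_genotypes=tuple(genotypes),
            tumor_baf=_opt_float(getattr(row, "tumor_baf", None)),
        )
        genome.check_interval(site.chromosome, site.position, site.position + 1)
        sites.append(site)
    sites.sort(key=lambda s: (genome.order(s.chromosome), s.position))
    return sites


def write_snp_table(sites: Iterable[SNPSite], path: PathLike) -> None:
    rows = []
    for site in sites:
        row = {"chromosome": site.chromosome, "position": site.position + 1}
        for i, g in enumerate(site.control_genotypes, start=1):
            row[f"control_{i}"] = _CODE_TO_GT[g]
        row["tumor_baf"] = site.tumor_baf
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_clinical_table(path: PathLike) -> list[PatientClinicalRecord]:
    """Read the clinical CSV, validating every row; row-level errors are
    aggregated into a single exception naming the offending rows."""
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("clinical table %s is empty", path)
        return []
    records, errors = [], []
    for idx, row in df.iterrows():
        try:
            records.append(
                PatientClinicalRecord(
                    patient_id=str(row["patient_id"]),
                    tumor_type=str(row["tumor_type"]),
                    histology=str(row.get("histology", "")),
                    prior_lines=int(row["prior_lines"]),
                    best_response=str(row["best_response"]),
                    pfs_months=float(row["pfs_months"]),
                    pfs_event=bool(row["pfs_event"]),
                    os_months=float(row["os_months"]),
                    os_event=bool(row["os_event"]),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValueError("invalid clinical rows:\n" + "\n".join(errors))
    return records


def write_clinical_table(records: Iterable[PatientClinicalRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "tumor_type": r.tumor_type,
                "histology": r.histology,
                "prior_lines": r.prior_lines,
                "best_response": r.best_response,
                "pfs_months": r.pfs_months,
                "pfs_event": int(r.pfs_event),
                "os_months": r.os_months,
                "os_event": int(r.os_event),
            }
            for r in records
        ]
    ).to_csv(path, index=False, float_format="%.4f")


def read_variant_table(path: PathLike) -> list[VariantRecord]:
    """Read the curated variant TSV (post-annotation panel calls)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        sift = getattr(row, "sift", None)
        poly = getattr(row, "polyphen", None)
        records.append(
            VariantRecord(
                sample_id=str(row.sample_id),
                gene=str(row.gene),
                coverage=int(row.coverage),
                vaf=float(row.vaf),
                classification=str(row.classification),
                sift_call=None if pd.isna(sift) or sift in (None, ".") else str(sift),
                polyphen_call=None if pd.isna(poly) or poly in (None, ".") else str(poly),
                pathogenic_prediction=bool(getattr(row, "pathogenic_prediction", False)),
            )
        )
    return records


def write_variant_table(records: Iterable[VariantRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "gene": r.gene,
                "coverage": r.coverage,
                "vaf": r.vaf,
                "classification": r.classification,
                "sift": r.sift_call or ".",
                "polyphen": r.polyphen_call or ".",
                "pathogenic_prediction": int(r.pathogenic_prediction),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_bed(path: PathLike, genome: Optional[GenomeModel] = None) -> pd.DataFrame:
    """Read a BED file (0-based half-open) of named intervals, e.g. gene spans."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chromosome", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    if df.isna().any().any():
        raise ValueError(f"malformed BED file {path}: expected 4 columns chrom/start/end/name")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"malformed BED file {path}: start >= end")
    if genome is not None:
        for row in df.itertuples(index=False):
            genome.check_interval(str(row.chromosome), int(row.start), int(row.end))
    return df


def write_bed(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)
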