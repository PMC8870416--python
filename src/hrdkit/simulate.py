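"""Synthetic-cohort generator.

Emulates the data shapes the pipeline consumes: a homogeneous SNP backbone
genotyped in a small panel of normal controls, per-sample segmented
copy-number profiles whose event burden scales with a latent instability
level, purity-diluted log2/BAF signals under the two-component tumor/normal
mixture, a curated panel-variant table, and clinical outcomes (best response
and PFS/OS) linked to instability through logistic and exponential models.

The generator runs on a 1/10-scale autosomal genome with one SNP per 20 kb,
which keeps the backbone at roughly a tenth of a full-size targeted design
while preserving per-segment SNP counts large enough for LOH calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io as hio
from .genome import (
    GenomeModel,
    PatientClinicalRecord,
    Segment,
    SegmentProfile,
    SNPSite,
    VariantRecord,
    default_genome,
)

__all__ = ["SimulationConfig", "SNPBackbone", "Cohort", "simulate_profile", "simulate_cohort"]

#: Copy-number genotypes by event type: (major, minor) allele copies.
_EVENT_ALLELES = {"gain": (2, 1), "loss": (1, 0), "cnloh": (2, 0), "neutral": (1, 1)}

# HRR genes with observed alteration weights in a heavily pretreated
# gynecological cohort (BRCA1 the most frequent).
_HRR_MUT_GENES = ["BRCA1", "BRCA2", "ATM", "RAD54L", "ATR", "NBN", "SLX4", "WRN"]
_HRR_MUT_WEIGHTS = [3, 1, 2, 1, 1, 1, 1, 1]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort; defaults are the package's
    reference scenario."""

    seed: int = 0
    n_patients: int = 50
    genome_scale: float = 0.1
    snp_spacing: Optional[int] = 20_000  # None disables the SNP/LOH layer
    panel_size: int = 5
    control_het_prob: float = 0.4
    control_missing_prob: float = 0.0
    tumor_het_prob: float = 0.9  # at constitutively heterozygous sites
    # instability level theta ~ Uniform(0, 1); events ~ Poisson(l0 + l1*theta)
    lambda0: float = 2.0
    lambda1: float = 18.0
    event_length_median: float = 8e6
    event_length_sigma: float = 0.8  # sigma of log length
    event_length_max: float = 40e6
    event_min_gap: int = 100_000
    p_gain: float = 0.4
    p_loss: float = 0.4
    p_cnloh: float = 0.2
    purity_low: float = 0.3
    purity_high: float = 0.9
    baf_noise_sd: float = 0.03
    log2_noise_sd: float = 0.05
    # response: P(CR/PR) = expit(beta0 + beta1 * z), z = standardized event count
    beta0: float = -2.2
    beta1: float = 1.0
    ne_prob: float = 0.068
    # PFS: exponential with log hazard gamma0 - gamma1 * z
    gamma0: float = math.log(1.0 / 4.5)
    gamma1: float = 0.5
    censor_max_months: float = 24.0
    # OS: exponential, median os_median at z = 0
    os_median: float = 15.0
    os_gamma1: float = 0.3
    os_censor_max_months: float = 36.0
    # P(HRR mutation) = expit(hrr_mut_intercept + hrr_mut_slope * theta)
    hrr_mut_intercept: float = -2.5
    hrr_mut_slope: float = 2.0

    def __post_init__(self) -> None:
        probs = (self.p_gain, self.p_loss, self.p_cnloh)
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("event-type probabilities must be in [0,1] and sum to 1")
        if self.lambda0 < 0 or self.lambda1 < 0:
            raise ValueError("event rates must be non-negative")
        if not (0 < self.purity_low <= self.purity_high <= 1):
            raise ValueError("purity range must satisfy 0 < low <= high <= 1")


@dataclass
class SNPBackbone:
    """The cohort-level SNP design: positions and the control-panel genotypes
    shared by every tumor sample."""

    positions: dict[str, np.ndarray]  # chrom -> 0-based positions
    genotypes: dict[str, np.ndarray]  # chrom -> (n_sites, panel_size) int codes
    het_truth: dict[str, np.ndarray]  # chrom -> bool, >= 3 of panel het & none missing

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())


_CODE_NAMES = np.array(["hom_ref", "het", "hom_alt", "missing"])


def _simulate_backbone(cfg: SimulationConfig, genome: GenomeModel, rng: np.random.Generator) -> SNPBackbone:
    positions, genotypes, het_truth = {}, {}, {}
    p_het = cfg.control_het_prob
    p_miss = cfg.control_missing_prob
    p_hom = (1.0 - p_het - p_miss) / 2.0
    for chrom in genome.names:
        length = genome.lengths[chrom]
        pos = np.arange(cfg.snp_spacing // 2, length, cfg.snp_spacing, dtype=np.int64)
        gts = rng.choice(
            4, size=(len(pos), cfg.panel_size), p=[p_hom, p_het, p_hom, p_miss]
        ).astype(np.int8)
        n_het = (gts == 1).sum(axis=1)
        any_missing = (gts == 3).any(axis=1)
        positions[chrom] = pos
        genotypes[chrom] = gts
        het_truth[chrom] = (n_het >= 3) & ~any_missing
    return SNPBackbone(positions=positions, genotypes=genotypes, het_truth=het_truth)


def _place_events(
    cfg: SimulationConfig, genome: GenomeModel, k: int, rng: np.random.Generator
) -> list[dict]:
    """Place up to ``k`` non-overlapping events uniformly over the genome."""
    # error only when even perfect packing could not hold the request;
    # ordinary crowding is handled by skipping unplaceable events below
    expected_span = k * cfg.event_length_median
    if expected_span > 1.2 * genome.autosomal_length:
        raise ValueError(
            f"genome too small for {k} events of median "
            f"{cfg.event_length_median:.0f} bp; request fewer or shorter events"
        )
    chrom_names = list(genome.names)
    chrom_lengths = np.array([genome.lengths[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    events: list[dict] = []
    type_p = [cfg.p_gain, cfg.p_loss, cfg.p_cnloh]
    for _ in range(k):
        length = float(
            min(
                cfg.event_length_median * math.exp(rng.normal(0.0, cfg.event_length_sigma)),
                cfg.event_length_max,
            )
        )
        for _attempt in range(200):
            ci = rng.choice(len(chrom_names), p=chrom_p)
            chrom = chrom_names[ci]
            L = genome.lengths[chrom]
            if L <= length:
                continue
            start = int(rng.integers(0, int(L - length)))
            end = start + int(round(length))
            if end <= start:
                continue
            gap = cfg.event_min_gap
            if all(end + gap <= s or start >= e + gap for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                etype = ("gain", "loss", "cnloh")[rng.choice(3, p=type_p)]
                events.append({"chromosome": chrom, "start": start, "end": end, "type": etype})
                break
        # an unplaceable event is silently skipped; the realized count is truth
    order = genome.order
    events.sort(key=lambda e: (order(e["chromosome"]), e["start"]))
    return events


def _mixture_baf(a: int, b: int, purity: float) -> float:
    """Expected BAF of a het SNP with tumor allele copies (a, b) diluted by
    diploid normal cells at fraction 1 - purity."""
    return (purity * b + (1 - purity)) / (purity * (a + b) + 2 * (1 - purity))


def simulate_profile(
    cfg: SimulationConfig,
    theta: float,
    purity: float,
    rng: np.random.Generator,
    genome: GenomeModel,
    backbone: Optional[SNPBackbone] = None,
    sample_id: str = "S1",
) -> tuple[SegmentProfile, Optional[dict[str, np.ndarray]], dict]:
    """Simulate one tumor's segmented profile and per-SNP tumor BAF.

    Returns the profile, per-chromosome tumor-BAF arrays aligned to the
    backbone (None when the SNP layer is disabled), and the engineered truth.
    """
    k = int(rng.poisson(cfg.lambda0 + cfg.lambda1 * theta))
    events = _place_events(cfg, genome, k, rng)

    total_cn = {"gain": 3, "loss": 1, "cnloh": 2, "neutral": 2}
    segments: list[Segment] = []
    by_chrom: dict[str, list[dict]] = {c: [] for c in genome.names}
    for ev in events:
        by_chrom[ev["chromosome"]].append(ev)

    def _segment(chrom: str, start: int, end: int, etype: str) -> Segment:
        n = total_cn[etype]
        a, b = _EVENT_ALLELES[etype]
        log2 = math.log2((purity * n + 2 * (1 - purity)) / 2.0)
        log2 += float(rng.normal(0.0, cfg.log2_noise_sd)) if cfg.log2_noise_sd > 0 else 0.0
        m = _mixture_baf(a, b, purity)
        folded = 0.5 + abs(m - 0.5)
        if cfg.baf_noise_sd > 0:
            folded = float(np.clip(folded + rng.normal(0.0, cfg.baf_noise_sd), 0.0, 1.0))
        n_snps = max(1, (end - start) // (cfg.snp_spacing or 20_000))
        return Segment(
            chromosome=chrom, start=start, end=end, log2_ratio=log2,
            mean_baf=folded, n_snps=n_snps,
            p_value=1e-4 if etype != "neutral" else 0.5,
        )

    for chrom in genome.names:
        cursor = 0
        for ev in by_chrom[chrom]:
            if ev["start"] > cursor:
                segments.append(_segment(chrom, cursor, ev["start"], "neutral"))
            segments.append(_segment(chrom, ev["start"], ev["end"], ev["type"]))
            cursor = ev["end"]
        if cursor < genome.lengths[chrom]:
            segments.append(_segment(chrom, cursor, genome.lengths[chrom], "neutral"))

    profile = SegmentProfile(sample_id=sample_id, genome=genome, segments=segments, purity=purity)

    tumor_baf: Optional[dict[str, np.ndarray]] = None
    if backbone is not None:
        tumor_baf = {}
        for chrom in genome.names:
            pos = backbone.positions[chrom]
            n_pos = len(pos)
            alleles_a = np.ones(n_pos, dtype=np.int8)
            alleles_b = np.ones(n_pos, dtype=np.int8)
            for ev in by_chrom[chrom]:
                a, b = _EVENT_ALLELES[ev["type"]]
                inside = (pos >= ev["start"]) & (pos < ev["end"])
                alleles_a[inside], alleles_b[inside] = a, b
            het_p = np.where(backbone.het_truth[chrom], cfg.tumor_het_prob, 1 - cfg.tumor_het_prob)
            is_het = rng.random(n_pos) < het_p
            mean = np.where(
                is_het,
                (purity * alleles_b + (1 - purity))
                / (purity * (alleles_a + alleles_b) + 2 * (1 - purity)),
                np.where(rng.random(n_pos) < 0.5, 0.0, 1.0),
            )
            # the shifted allele is arbitrary: mirror het BAFs at random
            flip = is_het & (rng.random(n_pos) < 0.5)
            mean = np.where(flip, 1.0 - mean, mean)
            if cfg.baf_noise_sd > 0:
                mean = mean + rng.normal(0.0, cfg.baf_noise_sd, size=n_pos)
            tumor_baf[chrom] = np.clip(mean, 0.0, 1.0)

    truth = {
        "sample_id": sample_id,
        "theta": theta,
        "purity": purity,
        "events": events,
        "n_events_true": len(events),
        "n_loh_true": sum(ev["type"] in ("loss", "cnloh") for ev in events),
    }
    return profile, tumor_baf, truth


@dataclass
class Cohort:
    """An in-memory synthetic cohort plus its engineered truth."""

    config: SimulationConfig
    genome: GenomeModel
    backbone: Optional[SNPBackbone]
    profiles: list[SegmentProfile]
    tumor_baf: dict[str, Optional[dict[str, np.ndarray]]]  # sample -> chrom -> BAF
    variants: list[VariantRecord]
    clinical: list[PatientClinicalRecord]
    truth: pd.DataFrame

    def het_mask(self, min_het_controls: int = 3):
        """The panel-of-normals heterozygosity mask, built once per cohort."""
        from .loh import HetMask

        if self.backbone is None:
            raise ValueError("cohort was simulated without a SNP layer")
        gts = self.backbone.genotypes
        positions = {}
        for chrom, pos in self.backbone.positions.items():
            n_het = (gts[chrom] == 1).sum(axis=1)
            any_missing = (gts[chrom] == 3).any(axis=1)
            keep = (n_het >= min_het_controls) & ~any_missing
            if keep.any():
                positions[chrom] = pos[keep]
        return HetMask(positions=positions, min_het_controls=min_het_controls)

    def baf_arrays(self, sample_id: str) -> Optional[dict[str, tuple[np.ndarray, np.ndarray]]]:
        """Per-chromosome (positions, tumor BAF) pairs for fast LOH calling."""
        if self.backbone is None or self.tumor_baf[sample_id] is None:
            return None
        return {
            chrom: (self.backbone.positions[chrom], self.tumor_baf[sample_id][chrom])
            for chrom in self.genome.names
        }

    def snp_sites(self, sample_id: str) -> list[SNPSite]:
        """Materialize the SNP table (panel genotypes + tumor BAF) for one sample."""
        if self.backbone is None:
            return []
        baf = self.tumor_baf[sample_id]
        sites = []
        for chrom in self.genome.names:
            pos = self.backbone.positions[chrom]
            gts = self.backbone.genotypes[chrom]
            bafs = baf[chrom] if baf is not None else np.full(len(pos), np.nan)
            for i in range(len(pos)):
                sites.append(
                    SNPSite(
                        chromosome=chrom,
                        position=int(pos[i]),
                        control_genotypes=tuple(_CODE_NAMES[gts[i]]),
                        tumor_baf=float(bafs[i]),
                    )
                )
        return sites


def _simulate_variants(
    cfg: SimulationConfig, sample_id: str, theta: float, rng: np.random.Generator
) -> list[VariantRecord]:
    variants: list[VariantRecord] = []

    def _mk(gene: str, classification: str, coverage=None, vaf=None, **kw) -> VariantRecord:
        return VariantRecord(
            sample_id=sample_id,
            gene=gene,
            coverage=int(coverage if coverage is not None else rng.integers(120, 900)),
            vaf=float(vaf if vaf is not None else rng.uniform(0.10, 0.60)),
            classification=classification,
            **kw,
        )

    p_hrr = float(expit(cfg.hrr_mut_intercept + cfg.hrr_mut_slope * theta))
    if rng.random() < p_hrr:
        w = np.array(_HRR_MUT_WEIGHTS, dtype=float)
        gene = _HRR_MUT_GENES[rng.choice(len(_HRR_MUT_GENES), p=w / w.sum())]
        variants.append(_mk(gene, "P" if rng.random() < 0.7 else "LP"))
    if rng.random() < 0.55:
        variants.append(_mk("TP53", "P"))
    if rng.random() < 0.15:
        variants.append(_mk("PTEN", "P"))
    # decoys exercising the quality gates and the VUS rules
    if rng.random() < 0.3:
        gene = _HRR_MUT_GENES[int(rng.integers(len(_HRR_MUT_GENES)))]
        if rng.random() < 0.5:
            variants.append(_mk(gene, "LP", coverage=int(rng.integers(20, 99))))
        else:
            variants.append(_mk(gene, "LP", vaf=float(rng.uniform(0.005, 0.05))))
    if rng.random() < 0.2:
        gene = _HRR_MUT_GENES[int(rng.integers(len(_HRR_MUT_GENES)))]
        variants.append(
            _mk(gene, "VUS", sift_call="pathogenic", polyphen_call="benign")
        )
    return variants


def simulate_cohort(cfg: SimulationConfig, out_dir: Optional[Path] = None) -> Cohort:
    """Generate a full cohort; deterministic given ``cfg.seed``.

    With ``out_dir`` set, writes the text dialects :mod:`hrdkit.io` reads:
    ``segments.tsv``, ``snps/<sample>.tsv``, ``variants.tsv``,
    ``clinical.csv``, ``genome.tsv``, and the truth bundle ``truth.tsv``.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = default_genome(scale=cfg.genome_scale)
    backbone = (
        _simulate_backbone(cfg, genome, rng) if cfg.snp_spacing is not None else None
    )

    thetas = rng.uniform(0.0, 1.0, size=cfg.n_patients)
    purities = rng.uniform(cfg.purity_low, cfg.purity_high, size=cfg.n_patients)

    profiles, tumor_baf, variants, truth_rows = [], {}, [], []
    for i in range(cfg.n_patients):
        sid = f"P{i + 1:03d}"
        profile, baf, truth = simulate_profile(
            cfg, float(thetas[i]), float(purities[i]), rng, genome, backbone, sample_id=sid
        )
        profiles.append(profile)
        tumor_baf[sid] = baf
        variants.extend(_simulate_variants(cfg, sid, float(thetas[i]), rng))
        truth_rows.append(truth)

    # clinical outcomes linked to the engineered event burden
    k = np.array([t["n_events_true"] for t in truth_rows], dtype=float)
    sd = k.std(ddof=0)
    z = (k - k.mean()) / sd if sd > 0 else np.zeros_like(k)
    p_resp = expit(cfg.beta0 + cfg.beta1 * z)
    clinical: list[PatientClinicalRecord] = []
    for i, t in enumerate(truth_rows):
        responder = bool(rng.random() < p_resp[i])
        if responder:
            best = "CR" if rng.random() < 0.15 else "PR"
        else:
            best = "SD" if rng.random() < 0.65 else "PD"
        if rng.random() < cfg.ne_prob:
            best = "NE"
        pfs_rate = math.exp(cfg.gamma0 - cfg.gamma1 * z[i])
        latent_pfs = float(rng.exponential(1.0 / pfs_rate))
        c = float(rng.uniform(0.0, cfg.censor_max_months))
        os_rate = math.exp(math.log(1.0 / cfg.os_median) - cfg.os_gamma1 * z[i])
        latent_os = float(rng.exponential(1.0 / os_rate))
        c_os = float(rng.uniform(0.0, cfg.os_censor_max_months))
        u = rng.random()
        tumor_type = "ovarian" if u < 0.63 else ("endometrial" if u < 0.99 else "breast")
        histology = {"ovarian": "HGS", "endometrial": "endometrioid", "breast": "TNBC"}[tumor_type]
        clinical.append(
            PatientClinicalRecord(
                patient_id=t["sample_id"],
                tumor_type=tumor_type,
                histology=histology,
                prior_lines=int(1 + rng.poisson(1.8)),
                best_response=best,
                pfs_months=round(min(latent_pfs, c), 4),
                pfs_event=latent_pfs <= c,
                os_months=round(min(latent_os, c_os), 4),
                os_event=latent_os <= c_os,
            )
        )
        t["p_response_true"] = float(p_resp[i])
        t["latent_pfs"] = latent_pfs

    truth = pd.DataFrame(
        [
            {
                "sample_id": t["sample_id"],
                "theta": t["theta"],
                "purity": t["purity"],
                "n_events_true": t["n_events_true"],
                "n_loh_true": t["n_loh_true"],
                "p_response_true": t["p_response_true"],
                "latent_pfs": t["latent_pfs"],
            }
            for t in truth_rows
        ]
    ).set_index("sample_id")
    truth.attrs["events"] = {t["sample_id"]: t["events"] for t in truth_rows}

    cohort = Cohort(
        config=cfg, genome=genome, backbone=backbone, profiles=profiles,
        tumor_baf=tumor_baf, variants=variants, clinical=clinical, truth=truth,
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    hio.write_segments(cohort.profiles, out_dir / "segments.tsv")
    hio.write_variant_table(cohort.variants, out_dir / "variants.tsv")
    hio.write_clinical_table(cohort.clinical, out_dir / "clinical.csv")
    with open(out_dir / "genome.tsv", "w") as fh:
        for chrom in cohort.genome.names:
            fh.write(f"{chrom}\t{cohort.genome.lengths[chrom]}\n")
    pd.DataFrame(
        [
            {"sample": p.sample_id, "purity": p.purity}
            for p in cohort.profiles
        ]
    ).to_csv(out_dir / "purity.tsv", sep="\t", index=False, float_format="%.4f")
    cohort.truth.reset_index().to_csv(
        out_dir / "truth.tsv", sep="\t", index=False, float_format="%.6g"
    )
    if cohort.backbone is not None:
        snp_dir = out_dir / "snps"
        snp_dir.mkdir(exist_ok=True)
        for profile in cohort.profiles:
            hio.write_snp_table(
                cohort.snp_sites(profile.sample_id), snp_dir / f"{profile.sample_id}.tsv"
            )
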