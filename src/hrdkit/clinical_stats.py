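"""Trial-style clinical statistics: response groupings, exact binomial rates,
nonparametric group comparisons, Kaplan–Meier survival, and the GI-parameter
association scan.

Groupings follow RECIST-derived definitions: ORR (CR/PR vs SD/PD), CBR
(CR/PR/SD lasting more than 6 months vs the rest), and LTR (PFS at least twice
the cohort median).  Rates carry exact Clopper–Pearson intervals; two-group
comparisons use the Wilcoxon rank-sum test with Cohen's d as the effect size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseGrouping",
    "RateEstimate",
    "KMCurve",
    "AssociationResult",
    "group_patients",
    "response_rate",
    "wilcoxon_rank_sum",
    "cohens_d",
    "km_fit",
    "logrank",
    "association_scan",
]

CBR_MONTHS = 6.0  # strict: SD lasting exactly 6 months is CBR-negative
EXACT_MAX_N = 12  # exact rank-sum enumeration below this combined size


@dataclass
class ResponseGrouping:
    """A named binary grouping of patients; missing labels mark patients the
    grouping cannot classify (e.g. NE best response for ORR)."""

    name: str
    labels: pd.Series  # index: patient id; values: True/False/pd.NA

    @property
    def n_positive(self) -> int:
        return int((self.labels == True).sum())  # noqa: E712 (pd.NA-safe)

    @property
    def n_negative(self) -> int:
        return int((self.labels == False).sum())  # noqa: E712


@dataclass(frozen=True)
class RateEstimate:
    """A response rate with its exact (Clopper–Pearson) 95% CI, in percent."""

    numerator: int
    denominator: int
    rate: float
    ci_low: float
    ci_high: float


@dataclass
class KMCurve:
    """Product-limit survival estimate with its median and 95% CI (months)."""

    times: np.ndarray
    survival: np.ndarray
    median: float  # NaN when survival never reaches 0.5
    median_ci: tuple[float, float]
    n_at_risk: np.ndarray


@dataclass(frozen=True)
class AssociationResult:
    parameter: str
    grouping: str
    n_pos: int
    n_neg: int
    median_pos: float
    median_neg: float
    statistic: float
    p_value: float
    cohens_d: Optional[float]
    direction: int  # sign of (positive-group mean - negative-group mean)


def group_patients(
    records: Sequence,
    grouping: str,
    median_pfs: Optional[float] = None,
) -> ResponseGrouping:
    """Label each patient under ORR, CBR, or LTR.

    ORR: CR/PR positive, SD/PD negative, NE missing.  CBR: CR, PR, or SD with
    PFS strictly over 6 months positive; SD at or under 6 months or PD
    negative; NE missing.  LTR: PFS at least twice ``median_pfs`` (computed
    from the cohort's own KM fit when not pinned), inclusive at the boundary.
    """
    if grouping == "LTR" and median_pfs is None:
        km = km_fit([r.pfs_months for r in records], [r.pfs_event for r in records])
        if math.isnan(km.median):
            raise ValueError("LTR grouping needs a resolvable median PFS")
        median_pfs = km.median
    labels = {}
    for r in records:
        br = r.best_response
        if grouping == "ORR":
            labels[r.patient_id] = pd.NA if br == "NE" else br in ("CR", "PR")
        elif grouping == "CBR":
            if br == "NE":
                labels[r.patient_id] = pd.NA
            else:
                labels[r.patient_id] = br in ("CR", "PR") or (
                    br == "SD" and r.pfs_months > CBR_MONTHS
                )
        elif grouping == "LTR":
            labels[r.patient_id] = r.pfs_months >= 2.0 * median_pfs
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
    return ResponseGrouping(
        name=grouping, labels=pd.Series(labels, dtype="boolean", name=grouping)
    )


def response_rate(n_pos: int, n_total: int, alpha: float = 0.05) -> RateEstimate:
    """Exact binomial rate estimate, reported in percent."""
    if not (0 <= n_pos <= n_total) or n_total <= 0:
        raise ValueError(f"invalid counts {n_pos}/{n_total}")
    ci = stats.binomtest(n_pos, n_total).proportion_ci(
        confidence_level=1 - alpha, method="exact"
    )
    return RateEstimate(
        numerator=n_pos,
        denominator=n_total,
        rate=100.0 * n_pos / n_total,
        ci_low=100.0 * ci.low,
        ci_high=100.0 * ci.high,
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null distribution for small tie-free samples (combined n <= 12),
    otherwise the normal approximation with tie and continuity corrections.
    Returns (U statistic of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one non-missing value")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # degenerate: no rank information
        return float(len(x) * len(y) / 2.0), 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) + len(y) <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def cohens_d(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Standardized mean difference with the pooled (n1-1, n2-1)-weighted SD.

    Returns None (with a warning) when the pooled SD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("Cohen's d needs >= 2 values per group")
    pooled_var = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        logger.warning("pooled SD is zero; Cohen's d undefined")
        return None
    return float((np.mean(x) - np.mean(y)) / np.sqrt(pooled_var))


def km_fit(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan–Meier product-limit fit; the median is the earliest time where
    survival drops to 0.5 or below (NaN when never reached)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    # earliest time at which survival reaches 0.5 or below
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    grid = sf.index.to_numpy(dtype=float)
    below = grid[surv <= 0.5 + 1e-12]
    median = float(below.min()) if len(below) else float("nan")
    if math.isnan(median):
        ci = (float("nan"), float("nan"))
    else:
        med_ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])
        ci = (lo if math.isfinite(lo) else float("nan"), hi if math.isfinite(hi) else float("nan"))
    event_table = kmf.event_table
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=median,
        median_ci=ci,
        n_at_risk=event_table["at_risk"].to_numpy(dtype=float),
    )


def logrank(
    times_a: Sequence[float], events_a: Sequence[bool],
    times_b: Sequence[float], events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi-square statistic, p)."""
    res = _ll_logrank(
        np.asarray(times_a, dtype=float), np.asarray(times_b, dtype=float),
        event_observed_A=np.asarray(events_a, dtype=bool),
        event_observed_B=np.asarray(events_b, dtype=bool),
    )
    return float(res.test_statistic), float(res.p_value)


def association_scan(
    gi: pd.DataFrame,
    groupings: Iterable[ResponseGrouping],
    min_group: int = 2,
) -> pd.DataFrame:
    """Scan every (GI parameter, grouping) pair with a rank-sum test and
    Cohen's d; raw p values are reported alongside Benjamini–Hochberg
    adjusted ones.

    ``gi`` is a samples x parameters table; grouping labels are aligned on its
    index, and samples with missing labels drop out of that pair.  Pairs with
    fewer than ``min_group`` samples in either group are skipped with a log
    entry.
    """
    rows = []
    for grouping in groupings:
        labels = grouping.labels.reindex(gi.index)
        for param in gi.columns:
            values = gi[param]
            ok = labels.notna() & values.notna()
            pos = values[ok & (labels == True)]  # noqa: E712
            neg = values[ok & (labels == False)]  # noqa: E712
            if len(pos) < min_group or len(neg) < min_group:
                logger.info(
                    "skipping %s x %s: group sizes %d/%d below %d",
                    param, grouping.name, len(pos), len(neg), min_group,
                )
                continue
            stat, p = wilcoxon_rank_sum(pos, neg)
            try:
                d = cohens_d(pos, neg)
            except ValueError:
                d = None
            diff = float(np.mean(pos) - np.mean(neg))
            rows.append(
                {
                    "parameter": param,
                    "grouping": grouping.name,
                    "n_pos": len(pos),
                    "n_neg": len(neg),
                    "median_pos": float(np.median(pos)),
                    "median_neg": float(np.median(neg)),
                    "statistic": stat,
                    "p": p,
                    "cohens_d": d,
                    "direction": int(np.sign(diff)),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "parameter", "grouping", "n_pos", "n_neg", "median_pos", "median_neg",
            "statistic", "p", "cohens_d", "direction",
        ],
    )
    if not df.empty:
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df
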