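"""Response groupings, exact binomial rates, rank-sum/Cohen's d, KM/log-rank."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hrdkit.clinical_stats import (
    association_scan,
    cohens_d,
    group_patients,
    km_fit,
    logrank,
    response_rate,
    wilcoxon_rank_sum,
)
from conftest import make_patient


def exact_ranksum_p(x, y):
    """Independent oracle: full enumeration of the rank-sum distribution."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = [sum(combo) for combo in itertools.combinations(ranks, n1)]
    ws = np.array(ws)
    mean = ws.mean()
    p = np.mean(np.abs(ws - mean) >= abs(w_obs - mean) - 1e-12)
    return p


class TestGroupings:
    def test_orr_labels(self):
        recs = [make_patient("A", "PR", pfs=3.0), make_patient("B", "SD"),
                make_patient("C", "NE")]
        g = group_patients(recs, "ORR")
        assert g.labels["A"] == True and g.labels["B"] == False
        assert pd.isna(g.labels["C"])

    def test_cbr_six_month_boundary_is_strict(self):
        recs = [make_patient("A", "SD", pfs=6.0), make_patient("B", "SD", pfs=6.01),
                make_patient("C", "PR", pfs=2.0), make_patient("D", "PD", pfs=8.0)]
        g = group_patients(recs, "CBR")
        assert g.labels["A"] == False      # exactly 6 months: negative
        assert g.labels["B"] == True
        assert g.labels["C"] == True       # PR regardless of duration
        assert g.labels["D"] == False

    def test_ltr_threshold_inclusive(self):
        recs = [make_patient("A", "SD", pfs=9.08), make_patient("B", "SD", pfs=9.07)]
        g = group_patients(recs, "LTR", median_pfs=4.54)
        assert g.labels["A"] == True and g.labels["B"] == False

    def test_ltr_from_cohort_median(self):
        # uncensored PFS 1..8 -> KM median 4; threshold 8, inclusive
        recs = [make_patient(f"P{i}", "SD", pfs=float(i)) for i in range(1, 9)]
        g = group_patients(recs, "LTR")
        assert g.n_positive == 1 and g.labels["P8"] == True

    def test_labels_order_independent(self, trial_cohort):
        fwd = group_patients(trial_cohort, "ORR").labels
        rev = group_patients(list(reversed(trial_cohort)), "ORR").labels
        assert fwd.sort_index().equals(rev.sort_index())

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            group_patients([make_patient("A")], "DCR")


class TestResponseRate:
    def test_seven_of_73_is_9_6_percent(self):
        est = response_rate(7, 73)
        assert round(est.rate, 1) == 9.6
        assert est.ci_low < est.rate < est.ci_high

    def test_boundary_counts(self):
        assert response_rate(0, 10).ci_low == 0.0
        assert response_rate(10, 10).ci_high == 100.0

    def test_matches_beta_quantile_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(5, 120))
            k = int(rng.integers(0, n + 1))
            est = response_rate(k, n)
            low = 0.0 if k == 0 else stats.beta.ppf(0.025, k, n - k + 1)
            high = 1.0 if k == n else stats.beta.ppf(0.975, k + 1, n - k)
            assert est.ci_low == pytest.approx(100 * low, abs=1e-9)
            assert est.ci_high == pytest.approx(100 * high, abs=1e-9)

    def test_exact_interval_coverage(self):
        # the exact construction guarantees >= nominal coverage
        for n, p in [(20, 0.1), (50, 0.3), (73, 0.096)]:
            cover = 0.0
            for k in range(n + 1):
                est = response_rate(k, n)
                if est.ci_low <= 100 * p <= est.ci_high:
                    cover += stats.binom.pmf(k, n, p)
            assert cover >= 0.95

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            response_rate(5, 4)
        with pytest.raises(ValueError):
            response_rate(0, 0)


class TestRankSum:
    def test_fully_separated_triples(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_two_versus_one(self):
        _, p = wilcoxon_rank_sum([1, 2], [100])
        assert p == pytest.approx(2 / 3)

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 6))
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(exact_ranksum_p(x, y), abs=1e-9)

    def test_exact_and_asymptotic_agree_at_n6(self):
        # the continuity-corrected normal approximation deviates from the
        # exact null by at most 0.0155 over every tie-free n1=n2=6
        # configuration (full enumeration), so 0.016 is the sharp bound
        rng = np.random.default_rng(9)
        for _ in range(25):
            pooled = rng.choice(10_000, size=12, replace=False).astype(float)
            x, y = pooled[:6], pooled[6:]
            _, p_exact = wilcoxon_rank_sum(x, y)  # exact branch at n = 12
            p_approx = stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method="asymptotic").pvalue
            assert abs(p_exact - p_approx) <= 0.016

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCohensD:
    def test_known_value(self):
        assert cohens_d([2, 4], [0, 2]) == pytest.approx(2 / np.sqrt(2))

    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(1, 1, 10), rng.normal(0, 1, 12)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_zero_pooled_sd_returns_none(self, caplog):
        assert cohens_d([1.0, 1.0], [1.0, 1.0]) is None


class TestSurvival:
    def test_km_no_censoring_is_empirical_survivor(self):
        km = km_fit([1, 2, 3, 4], [True] * 4)
        lookup = dict(zip(km.times, km.survival))
        assert lookup[1.0] == pytest.approx(0.75)
        assert lookup[2.0] == pytest.approx(0.5)
        assert lookup[3.0] == pytest.approx(0.25)
        assert lookup[4.0] == pytest.approx(0.0)
        assert km.median == pytest.approx(2.0)

    def test_km_all_censored_median_undefined(self):
        km = km_fit([5, 6, 7], [False, False, False])
        assert np.isnan(km.median)
        assert (km.survival == 1.0).all()

    def test_logrank_identical_groups(self):
        t = [2, 4, 6, 8]
        e = [True, True, False, True]
        stat, p = logrank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_logrank_matches_hand_computed_table(self):
        # 6 vs 6 toy with censoring; oracle: direct observed-minus-expected
        # with the hypergeometric variance at each distinct event time
        ta, ea = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 1, 1, 1, 0, 1]
        tb, eb = [2.5, 3.5, 4.5, 5.5, 6.5, 7.5], [1, 0, 1, 1, 1, 0]
        stat, p = logrank(ta, ea, tb, eb)

        times = sorted(set([t for t, e in zip(ta, ea) if e] +
                           [t for t, e in zip(tb, eb) if e]))
        o_minus_e, var = 0.0, 0.0
        for t in times:
            n1 = sum(x >= t for x in ta)
            n2 = sum(x >= t for x in tb)
            d1 = sum(1 for x, e in zip(ta, ea) if x == t and e)
            d2 = sum(1 for x, e in zip(tb, eb) if x == t and e)
            n, d = n1 + n2, d1 + d2
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        expected = o_minus_e**2 / var
        assert stat == pytest.approx(expected, rel=1e-6)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-6)


class TestAssociationScan:
    def _gi(self, rng, n):
        return pd.DataFrame(
            {"param_a": rng.normal(size=n), "param_b": rng.normal(size=n)},
            index=[f"P{i}" for i in range(n)],
        )

    def test_loaded_parameter_found(self):
        rng = np.random.default_rng(12)
        gi = self._gi(rng, 40)
        labels = pd.Series([i < 20 for i in range(40)], index=gi.index, dtype="boolean")
        gi.loc[labels == True, "param_a"] += 3.0
        from hrdkit.clinical_stats import ResponseGrouping
        res = association_scan(gi, [ResponseGrouping("ORR", labels)])
        res = res.set_index("parameter")
        assert res.loc["param_a", "p"] < 0.001 < res.loc["param_b", "p"]
        assert res.loc["param_a", "direction"] == 1
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_degenerate_grouping_skipped(self, caplog):
        rng = np.random.default_rng(13)
        gi = self._gi(rng, 10)
        labels = pd.Series([True] * 10, index=gi.index, dtype="boolean")
        from hrdkit.clinical_stats import ResponseGrouping
        res = association_scan(gi, [ResponseGrouping("ORR", labels)])
        assert res.empty

    def test_missing_labels_drop_samples(self):
        rng = np.random.default_rng(14)
        gi = self._gi(rng, 10)
        labels = pd.Series([True] * 4 + [False] * 4 + [pd.NA] * 2,
                           index=gi.index, dtype="boolean")
        from hrdkit.clinical_stats import ResponseGrouping
        res = association_scan(gi, [ResponseGrouping("ORR", labels)])
        assert (res["n_pos"] == 4).all() and (res["n_neg"] == 4).all()
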