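"""GI parameter vector arithmetic and median/quartile categorization."""

import numpy as np
import pandas as pd
import pytest

from hrdkit.cn_events import CNEvent, CNEventSet, baf_borderline_filter
from hrdkit.genome import GenomeModel
from hrdkit.gi_features import PARAMETER_NAMES, categorize, compute_gi_vector
from hrdkit.loh import LOHSegment


def event(start_mb, len_mb, state, baf=None):
    return CNEvent("chr1", start_mb * 10**6, (start_mb + len_mb) * 10**6, state,
                   3.5 if state == "gain" else 1.0, mean_baf=baf)


def loh(start_mb, len_mb):
    return LOHSegment("chr1", start_mb * 10**6, (start_mb + len_mb) * 10**6, 30, 0.4)


MB = 10**6


class TestGIVector:
    def test_empty_inputs_all_zero(self, toy_genome):
        v = compute_gi_vector(CNEventSet("S1", []), CNEventSet("S1", []), [], toy_genome)
        assert list(v.index) == list(PARAMETER_NAMES)
        assert (v == 0).all()

    def test_worked_example_on_100mb_genome(self, toy_genome):
        # one 5 Mb gain + one 15 Mb loss, nothing BAF-filtered;
        # LOH tracts of 12 and 20 Mb
        events = CNEventSet("S1", [event(0, 5, "gain", baf=0.9),
                                   event(10, 15, "loss", baf=0.95)])
        filtered = baf_borderline_filter(events)
        assert len(filtered) == 2
        v = compute_gi_vector(events, filtered, [loh(30, 12), loh(50, 20)], toy_genome)
        assert v["n_events"] == 2
        assert v["mean_event_length"] == 10 * MB
        assert v["altered_length"] == 20 * MB
        assert v["pct_genome_altered"] == pytest.approx(20.0)
        assert v["n_gains"] == 1 and v["gain_length"] == 5 * MB
        assert v["pct_genome_gains"] == pytest.approx(5.0)
        assert v["n_losses"] == 1 and v["loss_length"] == 15 * MB
        assert v["pct_genome_losses"] == pytest.approx(15.0)
        assert v["loh_length"] == 32 * MB
        assert v["pct_genome_loh"] == pytest.approx(32.0)
        assert v["n_loh_gt10mb"] == 2 and v["loh_gt10mb_length"] == 32 * MB
        assert v["pct_genome_loh_gt10mb"] == pytest.approx(32.0)
        assert v["n_loh_gt15mb"] == 1 and v["loh_gt15mb_length"] == 20 * MB
        assert v["pct_genome_loh_gt15mb"] == pytest.approx(20.0)

    def test_baf_tier_drops_borderline_gain(self, toy_genome):
        events = CNEventSet("S1", [event(0, 5, "gain", baf=0.5),
                                   event(10, 15, "loss", baf=0.95)])
        filtered = baf_borderline_filter(events)
        v = compute_gi_vector(events, filtered, [], toy_genome)
        assert v["n_events_baf"] == 1
        assert v["mean_event_length_baf"] == 15 * MB
        assert v["altered_length_baf"] == 15 * MB
        assert v["pct_genome_altered_baf"] == pytest.approx(15.0)
        assert v["n_gains_baf"] == 0 and v["gain_length_baf"] == 0
        # unfiltered tier unchanged
        assert v["n_events"] == 2 and v["n_gains"] == 1

    def test_counts_decompose_and_percentages_bounded(self, toy_genome):
        rng = np.random.default_rng(3)
        for _ in range(25):
            events = _random_events(rng, toy_genome)
            filtered = baf_borderline_filter(events)
            v = compute_gi_vector(events, filtered, [], toy_genome)
            assert v["n_events"] == v["n_gains"] + v["n_losses"]
            assert v["n_events_baf"] <= v["n_events"]
            assert v["gain_length_baf"] <= v["gain_length"]
            pct = v[[c for c in v.index if c.startswith("pct_")]]
            assert ((pct >= 0) & (pct <= 100)).all()

    def test_scale_invariance_of_percentages(self):
        g1 = GenomeModel(names=("chr1",), lengths={"chr1": 100 * MB})
        g2 = GenomeModel(names=("chr1",), lengths={"chr1": 200 * MB})
        e1 = CNEventSet("S1", [event(0, 5, "gain"), event(10, 15, "loss")])
        e2 = CNEventSet("S1", [event(0, 10, "gain"), event(20, 30, "loss")])
        v1 = compute_gi_vector(e1, e1, [loh(30, 20)], g1)
        v2 = compute_gi_vector(e2, e2, [loh(60, 40)], g2)
        for c in v1.index:
            if c.startswith(("pct_", "n_")) and "gt1" not in c:
                assert v1[c] == pytest.approx(v2[c]), c

    def test_brute_force_per_basepair_tally(self, small_genome):
        rng = np.random.default_rng(11)
        for _ in range(20):
            events = _random_events(rng, small_genome, max_len=50_000)
            filtered = baf_borderline_filter(events)
            v = compute_gi_vector(events, filtered, [], small_genome)
            # oracle: paint every basepair
            total = small_genome.autosomal_length
            masks = {}
            for name in ("all", "gain", "loss"):
                masks[name] = {c: np.zeros(small_genome.lengths[c], dtype=bool)
                               for c in small_genome.names}
            for e in events:
                masks["all"][e.chromosome][e.start:e.end] = True
                masks[e.state][e.chromosome][e.start:e.end] = True
            altered = sum(m.sum() for m in masks["all"].values())
            gains = sum(m.sum() for m in masks["gain"].values())
            losses = sum(m.sum() for m in masks["loss"].values())
            assert v["altered_length"] == altered
            assert v["gain_length"] == gains
            assert v["loss_length"] == losses
            assert v["pct_genome_altered"] == pytest.approx(100 * altered / total)

    def test_sample_mismatch_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="different samples"):
            compute_gi_vector(CNEventSet("A", []), CNEventSet("B", []), [], toy_genome)


def _random_events(rng, genome, max_len=None):
    events = []
    for chrom in genome.names:
        length = genome.lengths[chrom]
        max_len = max_len or length // 10
        cursor = 0
        while cursor < length - max_len:
            start = cursor + int(rng.integers(1, max_len))
            end = min(start + int(rng.integers(1, max_len)), length)
            if end <= start:
                break
            if rng.random() < 0.5:
                events.append(CNEvent(chrom, start, end,
                                      "gain" if rng.random() < 0.5 else "loss",
                                      3.0, mean_baf=float(rng.uniform(0, 1))))
            cursor = end
    return CNEventSet("S1", events)


class TestCategorize:
    def test_median_split(self):
        out = categorize(pd.Series([1.0, 2, 3, 4]), "median")
        assert out.cuts == (2.5,)
        assert list(out.labels) == ["low", "low", "high", "high"]

    def test_ties_at_cut_go_low(self):
        out = categorize(pd.Series([1.0, 2, 2, 3]), "median")
        assert list(out.labels) == ["low", "low", "low", "high"]

    def test_degenerate_all_equal(self, caplog):
        out = categorize(pd.Series([5.0, 5, 5]), "median")
        assert list(out.labels) == ["low", "low", "low"]

    def test_quartiles_of_1_to_8(self):
        out = categorize(pd.Series(np.arange(1.0, 9)), "quartile")
        assert out.cuts == pytest.approx((2.75, 4.5, 6.25))
        assert list(out.labels) == ["q1", "q1", "q2", "q2", "q3", "q3", "q4", "q4"]

    def test_missing_values_keep_missing_label(self):
        out = categorize(pd.Series([1.0, np.nan, 3, 4]), "median")
        assert out.labels.isna().tolist() == [False, True, False, False]

    def test_insufficient_values_rejected(self):
        with pytest.raises(ValueError):
            categorize(pd.Series([1.0]), "median")
        with pytest.raises(ValueError):
            categorize(pd.Series([1.0, 2, 3]), "quartile")

    def test_median_group_sizes_balanced_up_to_ties(self):
        rng = np.random.default_rng(5)
        values = pd.Series(rng.normal(size=101))  # continuous, no ties
        out = categorize(values, "median")
        n_low = (out.labels == "low").sum()
        n_high = (out.labels == "high").sum()
        assert abs(n_low - n_high) <= 1
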