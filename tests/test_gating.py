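import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meioflow import (
    ClassLabel,
    EventTable,
    GateVariant,
    ThresholdSet,
    apply_quality_filter,
    classify_event,
    classify_events,
    default_thresholds,
    tabulate_counts,
)
from meioflow.errors import MissingChannelError
from oracles import brute_force_quality, brute_force_tally

ALL_CHANNELS = ["FITC.A", "PE.CF594.A", "FSC.H", "FSC.A", "SSC.H", "BV605.A", "BV510.A"]


def _random_table(rng, n=1000, channels=ALL_CHANNELS):
    cols = {
        "FITC.A": rng.uniform(0, 12_000, n),
        "PE.CF594.A": rng.uniform(0, 12_000, n),
        "FSC.H": rng.uniform(0, 260_000, n),
        "FSC.A": rng.uniform(0, 260_000, n),
        "SSC.H": rng.uniform(0, 5_000, n),
        "BV605.A": rng.uniform(0, 3_000, n),
        "BV510.A": rng.uniform(0, 3_000, n),
    }
    return EventTable("rand", channels, np.column_stack([cols[c] for c in channels]))


class TestDefaultThresholds:
    def test_fluorescence_cuts_shared_by_both_variants(self):
        a = default_thresholds(GateVariant.RFP_GFP_ONLY)
        b = default_thresholds(GateVariant.QUALITY_RFP_GFP)
        assert a.fluorescence == b.fluorescence
        assert a.fluorescence["FITC.A"] == (560.0, 10_000.0)
        assert a.fluorescence["PE.CF594.A"] == (1_000.0, 10_000.0)

    def test_only_quality_variant_has_quality_block(self):
        assert default_thresholds(GateVariant.RFP_GFP_ONLY).quality == {}
        q = default_thresholds(GateVariant.QUALITY_RFP_GFP).quality
        assert q["FSC.H"] == (55_000.0, None)
        assert q["FSC.A"] == (None, 200_000.0)
        assert q["SSC.H"] == (450.0, 3_500.0)
        assert q["BV605.A"] == (800.0, None)
        assert q["BV510.A"] == (800.0, None)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSet(fluorescence={"FITC.A": (10_000.0, 560.0),
                                       "PE.CF594.A": (1_000.0, 10_000.0)})


class TestClassify:
    thresholds = default_thresholds(GateVariant.RFP_GFP_ONLY)

    @pytest.mark.parametrize(
        "fitc,pe,expected",
        [
            (2_000.0, 500.0, ClassLabel.GFP),
            (200.0, 5_000.0, ClassLabel.RFP),
            (2_000.0, 5_000.0, ClassLabel.GFP_RFP),
            (100.0, 100.0, ClassLabel.WT),
            (560.0, 1_000.0, ClassLabel.WT),        # ties fall negative
            (10_000.0, 10_000.0, ClassLabel.WT),    # cap boundary
            (20_000.0, 5_000.0, ClassLabel.RFP),    # saturated GFP falls out
            (20_000.0, 20_000.0, ClassLabel.WT),    # doubly saturated -> WT
        ],
    )
    def test_single_event_examples(self, fitc, pe, expected):
        label = classify_event({"FITC.A": fitc, "PE.CF594.A": pe}, self.thresholds)
        assert label is expected

    def test_missing_fluorescence_channel(self):
        with pytest.raises(MissingChannelError):
            classify_event({"FITC.A": 100.0}, self.thresholds)

    def test_partition_is_exhaustive(self, rng):
        """Every event gets exactly one label; counts are conserved."""
        table = _random_table(rng, 5_000)
        labels = classify_events(table, self.thresholds)
        assert len(labels) == 5_000
        counts = tabulate_counts(table, self.thresholds)
        assert counts.n_total == 5_000


class TestTabulate:
    def test_empty_table(self):
        table = EventTable("e", ["FITC.A", "PE.CF594.A"], np.empty((0, 2)))
        counts = tabulate_counts(table, default_thresholds(GateVariant.RFP_GFP_ONLY))
        assert (counts.y1, counts.y2, counts.y3) == (0, 0, 0)

    def test_four_example_events(self, small_table):
        counts = tabulate_counts(small_table, default_thresholds(GateVariant.RFP_GFP_ONLY))
        assert (counts.y1, counts.y2, counts.y3) == (1, 2, 1)

    def test_matches_brute_force_oracle(self, rng):
        table = _random_table(rng, 10_000)
        counts = tabulate_counts(table, default_thresholds(GateVariant.RFP_GFP_ONLY))
        assert (counts.y1, counts.y2, counts.y3) == brute_force_tally(table.events, table.channels)


class TestQualityFilter:
    thresholds = default_thresholds(GateVariant.QUALITY_RFP_GFP)

    def test_good_event_retained_and_low_ssc_removed(self):
        events = np.array([
            [1_000.0, 1_000.0, 60_000.0, 100_000.0, 1_000.0, 900.0, 900.0],
            [1_000.0, 1_000.0, 60_000.0, 100_000.0, 0.0, 900.0, 900.0],
        ])
        table = EventTable("q", ALL_CHANNELS, events)
        kept = apply_quality_filter(table, self.thresholds)
        assert len(kept) == 1
        assert kept.events[0, 4] == 1_000.0

    def test_no_quality_bounds_is_identity(self, rng):
        table = _random_table(rng, 100)
        kept = apply_quality_filter(table, default_thresholds(GateVariant.RFP_GFP_ONLY))
        assert kept is table

    def test_matches_brute_force_oracle(self, rng):
        table = _random_table(rng, 1_000)
        kept = apply_quality_filter(table, self.thresholds)
        assert len(kept) == brute_force_quality(table.events, table.channels).sum()

    def test_missing_quality_channel_named(self, rng):
        table = _random_table(rng, 10, channels=["FITC.A", "PE.CF594.A", "FSC.H"])
        with pytest.raises(MissingChannelError, match="FSC.A"):
            apply_quality_filter(table, self.thresholds)

    def test_variant_containment(self, rng):
        """Quality-filtered totals never exceed the unfiltered totals."""
        table = _random_table(rng, 2_000)
        n_qual = tabulate_counts(apply_quality_filter(table, self.thresholds),
                                 self.thresholds).n_total
        n_all = tabulate_counts(table, default_thresholds(GateVariant.RFP_GFP_ONLY)).n_total
        assert n_qual <= n_all


@settings(max_examples=30, deadline=None, derandomize=True)
@given(cut=st.floats(min_value=100.0, max_value=9_000.0))
def test_raising_gfp_cut_never_increases_y2(cut):
    """Monotonicity: a higher GFP positive-cut can only shrink category 2."""
    rng = np.random.default_rng(7)
    table = EventTable(
        "m", ["FITC.A", "PE.CF594.A"],
        np.column_stack([rng.uniform(0, 12_000, 2_000), rng.uniform(0, 12_000, 2_000)]),
    )
    base = ThresholdSet(fluorescence={"FITC.A": (cut, 10_000.0),
                                      "PE.CF594.A": (1_000.0, 10_000.0)})
    higher = ThresholdSet(fluorescence={"FITC.A": (cut + 500.0, 10_000.0),
                                        "PE.CF594.A": (1_000.0, 10_000.0)})
    assert tabulate_counts(table, higher).y2 <= tabulate_counts(table, base).y2
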