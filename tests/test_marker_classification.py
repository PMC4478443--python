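import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trnapore.band_segmentation import BandConfig, segment_event
from trnapore.event_detection import DetectionParams, detect_events, select_long_events
from trnapore.marker_classification import (
    ClassifiedEvent,
    ClassifyConfig,
    apportion_percentages,
    classify_event,
    fraction_pct,
    select_complete_translocations,
    tabulate_categories,
)
from trnapore.synthetic_squiggle import (
    CATEGORIES,
    SimConfig,
    event_bounds,
    make_category_event,
    simulate_trace,
)

from _helpers import make_segments
from _oracles import oracle_classify, random_segment_sequence


def _classify(specs):
    segs = make_segments(specs)
    duration = sum(s.duration_s for s in segs)
    return classify_event(segs, duration, ClassifyConfig())


class TestWorkedRulePatterns:
    def test_leading_and_trailing(self):
        specs = [
            ("MARKER_HIGH", 3e-3, 35.0),
            ("LOW", 20e-3, 22.0),
            ("MARKER_HIGH", 2.5e-3, 34.5),
        ]
        assert _classify(specs) == "LEADING_AND_TRAILING"

    def test_leading_only(self):
        specs = [("MARKER_HIGH", 3e-3, 35.0), ("LOW", 20e-3, 22.0)]
        assert _classify(specs) == "LEADING_ONLY"

    def test_trailing_only(self):
        specs = [("LOW", 20e-3, 22.0), ("MARKER_HIGH", 2.5e-3, 34.5)]
        assert _classify(specs) == "TRAILING_ONLY"

    def test_three_markers_is_other(self):
        specs = [
            ("MARKER_HIGH", 3e-3, 35.0),
            ("LOW", 20e-3, 22.0),
            ("MARKER_HIGH", 2.5e-3, 34.5),
            ("MID", 5e-3, 30.0),
            ("MARKER_HIGH", 2.5e-3, 35.5),
        ]
        assert _classify(specs) == "OTHER"

    def test_two_markers_without_low_is_other(self):
        specs = [
            ("MARKER_HIGH", 3e-3, 35.0),
            ("MID", 30e-3, 30.0),
            ("MARKER_HIGH", 2.5e-3, 34.5),
        ]
        assert _classify(specs) == "OTHER"

    def test_trailing_marker_far_from_end_is_other(self):
        # the second marker must be proximal to event termination
        specs = [
            ("MARKER_HIGH", 3e-3, 35.0),
            ("LOW", 20e-3, 22.0),
            ("MARKER_HIGH", 2.5e-3, 34.5),
            ("MID", 2.0, 30.0),
        ]
        assert _classify(specs) == "OTHER"

    def test_mid_segments_tolerated_anywhere(self):
        specs = [
            ("MID", 5e-3, 30.0),
            ("MARKER_HIGH", 3e-3, 35.0),
            ("MID", 8e-3, 31.0),
            ("LOW", 20e-3, 22.0),
            ("MID", 4e-3, 29.0),
            ("MARKER_HIGH", 2.5e-3, 34.5),
        ]
        assert _classify(specs) == "LEADING_AND_TRAILING"


@settings(max_examples=300, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_classifier_agrees_with_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    segs = make_segments(random_segment_sequence(rng))
    duration = sum(s.duration_s for s in segs)
    got = classify_event(segs, duration, ClassifyConfig())
    expected = oracle_classify([(s.band, s.duration_s, s.mean_pA) for s in segs])
    assert got == expected


def test_classification_is_pure_function_of_segments():
    specs = [("MARKER_HIGH", 3e-3, 35.0), ("LOW", 20e-3, 22.0)]
    segs = make_segments(specs)
    duration = sum(s.duration_s for s in segs)
    cfg = ClassifyConfig()
    assert classify_event(segs, duration, cfg) == classify_event(segs, duration, cfg)


def test_segments_must_tile_the_event():
    from _helpers import event_from_levels

    ev = event_from_levels([(30.0, 10e-3)])
    half = make_segments([("MID", 5e-3, 30.0)])
    with pytest.raises(ValueError, match="tile"):
        classify_event(half, ev, ClassifyConfig())


class TestSelectCompleteTranslocations:
    def _classified(self, specs):
        segs = make_segments(specs)
        duration = sum(s.duration_s for s in segs)
        cat = classify_event(segs, duration, ClassifyConfig())
        return ClassifiedEvent(event=None, segments=segs, category=cat)

    def test_two_marker_event_included(self):
        ce = self._classified(
            [
                ("MARKER_HIGH", 3e-3, 35.0),
                ("LOW", 20e-3, 22.0),
                ("MARKER_HIGH", 2.5e-3, 34.5),
            ]
        )
        assert select_complete_translocations([ce]) == [ce]

    def test_three_marker_event_excluded(self):
        ce = self._classified(
            [
                ("MARKER_HIGH", 3e-3, 35.0),
                ("LOW", 20e-3, 22.0),
                ("MARKER_HIGH", 2.5e-3, 34.5),
                ("MID", 5e-3, 30.0),
                ("MARKER_HIGH", 2.5e-3, 35.5),
            ]
        )
        assert select_complete_translocations([ce]) == []

    def test_planted_cohort_count_recovered(self, rng):
        cats = (
            ["LEADING_AND_TRAILING"] * 8
            + ["LEADING_ONLY"] * 6
            + ["TRAILING_ONLY"] * 2
            + ["OTHER"] * 4
        )
        templates = [make_category_event(c, rng) for c in cats]
        trace, manifest = simulate_trace(
            SimConfig(seed=77, event_rate=2.0), templates
        )
        events = select_long_events(detect_events(trace, DetectionParams()))
        classified = [
            ClassifiedEvent(
                event=ev,
                segments=(segs := segment_event(ev, BandConfig())),
                category=classify_event(segs, ev, ClassifyConfig()),
            )
            for ev in events
        ]
        completes = select_complete_translocations(classified)
        assert len(completes) == 8
        # recovered categories match the plant
        bounds = event_bounds(manifest)
        correct = 0
        for ce in classified:
            hits = bounds[
                (bounds.start_sample < ce.event.end)
                & (bounds.end_sample > ce.event.start)
            ]
            correct += ce.category == hits.iloc[0].truth_category
        assert correct >= len(classified) - 1


class TestTabulation:
    def test_counts_and_percentages(self):
        cats = (
            ["LEADING_AND_TRAILING"] * 3
            + ["LEADING_ONLY"] * 5
            + ["TRAILING_ONLY"] * 1
            + ["OTHER"] * 1
        )
        table = tabulate_categories(cats)
        assert table.total == 10
        assert table.counts["LEADING_ONLY"] == 5
        assert sum(table.counts.values()) == table.total
        assert sum(table.percentages.values()) == pytest.approx(100.0)

    def test_single_category_is_100_percent(self):
        table = tabulate_categories(["OTHER"] * 7)
        assert table.percentages["OTHER"] == 100.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            tabulate_categories([])

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            tabulate_categories(["WAT"])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=6).filter(lambda c: sum(c) > 0))
    def test_hamilton_percentages_sum_to_100_and_stay_close_to_exact(self, counts):
        pcts = apportion_percentages(counts)
        assert sum(pcts) == pytest.approx(100.0, abs=1e-9)
        total = sum(counts)
        for c, p in zip(counts, pcts):
            assert abs(p - 100.0 * c / total) <= 0.1 + 1e-9

    def test_fraction_pct_plain_rounding(self):
        assert fraction_pct(1, 3) == 33.3
        assert fraction_pct(2, 3) == 66.7
        with pytest.raises(ValueError):
            fraction_pct(1, 0)
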