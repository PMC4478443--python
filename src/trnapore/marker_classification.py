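"""Marker-rule classification of long blockade events.

Long (>1 s) events are assigned one of four categories from the abasic
marker states they contain:

* ``LEADING_AND_TRAILING`` — exactly two qualifying high-current marker
  segments with a qualifying low-current segment between them and the
  trailing marker proximal to event termination (the signature of a
  complete 5'-to-3' translocation);
* ``LEADING_ONLY`` — exactly one marker, with the low segment(s) after it;
* ``TRAILING_ONLY`` — exactly one marker, with the low segment(s) before it;
* ``OTHER`` — everything else (no markers, more than two markers, or a
  marker pattern without the required low segment).

A qualifying marker segment has mean current in 33.5-36.5 pA and duration
>= 2 ms; a qualifying low segment has mean current < 26.5 pA and duration
>= 10 ms. "Proximal to termination" is quantified as the trailing marker
ending within the final 10% of the event or within 50 ms of its end,
whichever window is larger. MID segments are tolerated anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .band_segmentation import BandSegment
from .event_detection import BlockadeEvent
from .synthetic_squiggle import (
    CATEGORIES,
    LEADING_AND_TRAILING,
    LEADING_ONLY,
    LOW,
    MARKER_HIGH,
    OTHER,
    TRAILING_ONLY,
)

__all__ = [
    "ClassifyConfig",
    "ClassifiedEvent",
    "CategoryTable",
    "classify_event",
    "select_complete_translocations",
    "tabulate_categories",
    "apportion_percentages",
    "fraction_pct",
]


@dataclass
class ClassifyConfig:
    """Qualification thresholds and the proximity rule for marker rules."""

    marker_band_pA: tuple[float, float] = (33.5, 36.5)
    low_band_max_pA: float = 26.5
    marker_min_s: float = 2e-3
    low_min_s: float = 1e-2
    proximal_fraction: float = 0.1
    proximal_min_s: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.proximal_fraction <= 1:
            raise ValueError("proximal_fraction must be in (0, 1]")


@dataclass
class ClassifiedEvent:
    """An event together with its band segments and assigned category."""

    event: BlockadeEvent
    segments: list[BandSegment]
    category: str
    event_id: int = -1
    truth_class: str = ""


def _qualified(segments: list[BandSegment], cfg: ClassifyConfig):
    lo_m, hi_m = cfg.marker_band_pA
    markers = [
        s
        for s in segments
        if s.band == MARKER_HIGH
        and lo_m <= s.mean_pA <= hi_m
        and s.duration_s >= cfg.marker_min_s
    ]
    lows = [
        s
        for s in segments
        if s.band == LOW
        and s.mean_pA < cfg.low_band_max_pA
        and s.duration_s >= cfg.low_min_s
    ]
    return markers, lows


def classify_event(
    segments: list[BandSegment],
    event: BlockadeEvent | float,
    cfg: ClassifyConfig | None = None,
) -> str:
    """Assign a marker category to one event from its band segments.

    ``event`` may be the :class:`BlockadeEvent` itself or its duration in
    seconds. The segments must tile the event (checked to within one
    sample when a BlockadeEvent is given).
    """
    cfg = cfg or ClassifyConfig()
    duration = getattr(event, "duration_s", None)
    if duration is None:
        duration = float(event)
    else:
        covered = sum(s.duration_s for s in segments)
        if abs(covered - duration) * event.sample_rate > 1.5:
            raise ValueError(
                f"segments do not tile the event: cover {covered:.6f} s "
                f"of {duration:.6f} s"
            )
    markers, lows = _qualified(segments, cfg)

    if len(markers) == 2:
        first, second = markers
        window = max(cfg.proximal_fraction * duration, cfg.proximal_min_s)
        end_s = sum(s.duration_s for s in segments)
        trailing_proximal = (end_s - _seg_end_s(second, segments)) <= window
        low_between = any(
            s.start >= first.end and s.end <= second.start for s in lows
        )
        if low_between and trailing_proximal:
            return LEADING_AND_TRAILING
        return OTHER
    if len(markers) == 1 and lows:
        marker = markers[0]
        if all(s.start >= marker.end for s in lows):
            return LEADING_ONLY
        if all(s.end <= marker.start for s in lows):
            return TRAILING_ONLY
        return OTHER
    return OTHER


def _seg_end_s(seg: BandSegment, segments: list[BandSegment]) -> float:
    """End time of *seg* in seconds from the event start."""
    rate = (seg.end - seg.start) / seg.duration_s if seg.duration_s else 1.0
    return seg.end / rate


def select_complete_translocations(
    classified: list[ClassifiedEvent],
) -> list[ClassifiedEvent]:
    """Events containing exactly two abasic-dependent marker regions.

    Keeps events classified ``LEADING_AND_TRAILING`` whose segment list
    carries exactly two qualifying MARKER_HIGH segments — the complete
    5'-to-3' translocation signature used for region I-III analysis.
    """
    out = []
    cfg = ClassifyConfig()
    for ce in classified:
        markers, _ = _qualified(ce.segments, cfg)
        if ce.category == LEADING_AND_TRAILING and len(markers) == 2:
            out.append(ce)
    return out


@dataclass
class CategoryTable:
    """Counts and one-decimal percentages per category, summing to 100.0."""

    counts: dict = field(default_factory=dict)
    percentages: dict = field(default_factory=dict)
    total: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [self.counts[c] for c in CATEGORIES],
                "percent": [self.percentages[c] for c in CATEGORIES],
            }
        )


def apportion_percentages(counts: list[int], decimals: int = 1) -> list[float]:
    """Percentages by largest-remainder (Hamilton) rounding.

    Each share is floored at the requested precision and the leftover
    tenths are assigned to the largest fractional remainders (earlier
    entry wins ties), so the printed percentages always sum to exactly
    100 at that precision.
    """
    total = sum(counts)
    if total <= 0:
        raise ValueError("cannot compute percentages of an empty tabulation")
    scale = 10**decimals
    exact = [100.0 * scale * c / total for c in counts]
    floors = [int(v) for v in exact]
    leftover = round(100 * scale) - sum(floors)
    remainders = sorted(
        range(len(counts)), key=lambda i: (-(exact[i] - floors[i]), i)
    )
    for i in remainders[:leftover]:
        floors[i] += 1
    return [f / scale for f in floors]


def fraction_pct(count: int, total: int, decimals: int = 1) -> float:
    """A single count/total share as a percentage, round-half at *decimals*."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def tabulate_categories(categories: list[str]) -> CategoryTable:
    """Tabulate event categories into counts and percentages.

    Raises on an empty list (a tabulation of nothing is meaningless).
    """
    if not categories:
        raise ValueError("no events to tabulate")
    unknown = set(categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    counts = {c: 0 for c in CATEGORIES}
    for c in categories:
        counts[c] += 1
    pcts = apportion_percentages([counts[c] for c in CATEGORIES])
    return CategoryTable(
        counts=counts,
        percentages=dict(zip(CATEGORIES, pcts)),
        total=len(categories),
    )
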