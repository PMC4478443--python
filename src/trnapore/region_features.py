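"""Region I-III feature extraction from complete translocation events.

A complete translocation event contains exactly two abasic marker
segments. The event is partitioned into three regions:

* region I — event start through the end of the leading marker (adapter
  capture signal plus the 5' abasic marker);
* region II — the intervening span between the markers (the RNA-dependent
  portion of the signal);
* region III — start of the trailing marker through event end (the 3'
  abasic marker and exit).

Regions I-III therefore tile the event exactly. Each region is summarised
by its duration (seconds) and arithmetic mean current (pA) — the feature
pair used downstream for tRNA discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .band_segmentation import BandSegment
from .event_detection import BlockadeEvent
from .marker_classification import ClassifyConfig, _qualified

__all__ = ["RegionFeatures", "extract_regions", "features_table", "REGIONS"]

REGIONS = ("I", "II", "III")


@dataclass
class RegionFeatures:
    """Duration and mean current for regions I, II, III of one event."""

    dur_I: float
    mean_I: float
    dur_II: float
    mean_II: float
    dur_III: float
    mean_III: float
    event_id: int = -1
    class_label: str = ""

    def duration(self, region: str) -> float:
        return getattr(self, f"dur_{region}")

    def mean(self, region: str) -> float:
        return getattr(self, f"mean_{region}")


def extract_regions(
    event: BlockadeEvent,
    segments: list[BandSegment],
    event_id: int = -1,
    class_label: str = "",
    cfg: ClassifyConfig | None = None,
) -> RegionFeatures:
    """Split a complete translocation event into regions I-III.

    Raises
    ------
    ValueError
        If the segment list does not contain exactly two qualifying
        marker segments, or if the inter-marker region II is empty.
    """
    cfg = cfg or ClassifyConfig()
    markers, _ = _qualified(segments, cfg)
    if len(markers) != 2:
        raise ValueError(
            f"complete translocation required: expected exactly 2 marker "
            f"segments, found {len(markers)}"
        )
    first, second = markers
    b1, b2 = first.end, second.start
    if b2 <= b1:
        raise ValueError("empty region II: markers are adjacent or overlap")
    x = event.samples
    n = x.size
    fs = event.sample_rate
    spans = {"I": (0, b1), "II": (b1, b2), "III": (b2, n)}
    values = {}
    for region, (s, e) in spans.items():
        if e <= s:
            raise ValueError(f"region {region} is empty")
        values[f"dur_{region}"] = (e - s) / fs
        values[f"mean_{region}"] = float(np.mean(x[s:e]))
    return RegionFeatures(event_id=event_id, class_label=class_label, **values)


def features_table(features: list[RegionFeatures]) -> pd.DataFrame:
    """Feature table with one row per complete translocation event."""
    rows = [
        {
            "event_id": f.event_id,
            "class_label": f.class_label,
            "dur_I": f.dur_I,
            "mean_I": f.mean_I,
            "dur_II": f.dur_II,
            "mean_II": f.mean_II,
            "dur_III": f.dur_III,
            "mean_III": f.mean_III,
        }
        for f in features
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "class_label",
            "dur_I",
            "mean_I",
            "dur_II",
            "mean_II",
            "dur_III",
            "mean_III",
        ],
    )
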