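"""Decomposition of blockade events into current-band segments.

Within a blockade event three bands matter for the marker rules: the
abasic-marker high band (33.5-36.5 pA), the low RNA band (<26.5 pA) and
everything in between (MID). Each sample is provisionally labelled from a
moving-average level (the band rules apply to segment means, not raw
samples), with 0.5 pA hysteresis at the band edges to suppress chatter;
run boundaries are then refined back onto the raw signal, runs shorter
than their band's minimum duration (markers >=2 ms, low >=10 ms) are
relabelled MID, and any surviving MARKER_HIGH/LOW segment whose raw mean
falls outside its band is demoted to MID. The resulting segments tile the
event exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .event_detection import BlockadeEvent
from .synthetic_squiggle import LOW, MARKER_HIGH, MID

__all__ = ["BandConfig", "BandSegment", "segment_event", "segments_table"]


@dataclass
class BandConfig:
    """Band thresholds and minimum durations for segmenting events."""

    marker_band_pA: tuple[float, float] = (33.5, 36.5)
    low_band_max_pA: float = 26.5
    marker_min_s: float = 2e-3
    low_min_s: float = 1e-2
    mid_min_s: float = 1e-3
    smoothing_window_s: float = 5e-4
    hysteresis_pA: float = 0.5

    def __post_init__(self) -> None:
        if not self.low_band_max_pA < self.marker_band_pA[0]:
            raise ValueError("low band upper bound must lie below the marker band")
        if not (self.marker_min_s > 0 and self.low_min_s > 0):
            raise ValueError("band minimum durations must be > 0")
        if not self.smoothing_window_s >= 0:
            raise ValueError("smoothing_window_s must be >= 0")


@dataclass
class BandSegment:
    """A maximal run of samples assigned to one band within an event."""

    band: str
    start: int  # sample index within the event, half-open
    end: int
    mean_pA: float
    duration_s: float


def _base_labels(smoothed: np.ndarray, cfg: BandConfig) -> np.ndarray:
    """Per-sample band codes (0=MID, 1=MARKER_HIGH, 2=LOW), no hysteresis."""
    lo_m, hi_m = cfg.marker_band_pA
    codes = np.zeros(smoothed.size, dtype=np.int8)
    codes[(smoothed >= lo_m) & (smoothed <= hi_m)] = 1
    codes[smoothed < cfg.low_band_max_pA] = 2
    return codes


def _runs(codes: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal codes as (start, end, code), half-open."""
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [codes.size]))
    return [(int(s), int(e), int(codes[s])) for s, e in zip(starts, ends)]


def _apply_hysteresis(
    runs: list[tuple[int, int, int]], smoothed: np.ndarray, cfg: BandConfig
) -> list[tuple[int, int, int]]:
    """Absorb runs that do not escape the current band's hysteresis zone.

    Leaving MARKER_HIGH requires the smoothed level to move more than
    ``hysteresis_pA`` beyond a band edge; likewise for LOW. Entry into a
    band from MID uses the plain band thresholds.
    """
    if not runs:
        return runs
    h = cfg.hysteresis_pA
    lo_m, hi_m = cfg.marker_band_pA
    out = [list(runs[0])]
    for start, end, code in runs[1:]:
        cur = out[-1][2]
        absorb = False
        if cur == 1 and code != 1:
            seg = smoothed[start:end]
            if not np.any((seg < lo_m - h) | (seg > hi_m + h)):
                absorb = True
        elif cur == 2 and code != 2:
            seg = smoothed[start:end]
            if not np.any(seg > cfg.low_band_max_pA + h):
                absorb = True
        if absorb or code == cur:
            out[-1][1] = end
        else:
            out.append([start, end, code])
    return [(s, e, c) for s, e, c in out]


def _refine_boundaries(
    runs: list[tuple[int, int, int]], x: np.ndarray, window: int
) -> list[tuple[int, int, int]]:
    """Snap run boundaries from the smoothed signal onto the raw signal.

    Around each boundary the first raw sample closer to the following
    run's mean than to the preceding run's mean is taken as the new
    boundary; on noise-free piecewise-constant input this recovers the
    exact transition sample.
    """
    if len(runs) < 2:
        return runs
    means = [float(np.mean(x[s:e])) for s, e, _ in runs]
    new_bounds = [0]
    half = max(1, window)
    for i in range(len(runs) - 1):
        b = runs[i][1]
        lo = max(new_bounds[-1] + 1, b - half)
        hi = min(x.size - 1, b + half)
        seg = x[lo:hi]
        closer = np.abs(seg - means[i + 1]) < np.abs(seg - means[i])
        idx = np.flatnonzero(closer)
        new_b = lo + int(idx[0]) if idx.size else b
        new_b = min(max(new_b, new_bounds[-1] + 1), x.size - 1)
        new_bounds.append(new_b)
    new_bounds.append(x.size)
    return [
        (new_bounds[i], new_bounds[i + 1], runs[i][2]) for i in range(len(runs))
    ]


def _coalesce(runs: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    out: list[list[int]] = []
    for s, e, c in runs:
        if out and out[-1][2] == c:
            out[-1][1] = e
        else:
            out.append([s, e, c])
    return [(s, e, c) for s, e, c in out]


def segment_event(event: BlockadeEvent, cfg: BandConfig | None = None) -> list[BandSegment]:
    """Split an event's samples into maximal band segments.

    The segments tile the event exactly: adjacent segments carry distinct
    bands, every MARKER_HIGH segment has its raw mean inside the marker
    band and duration >= ``marker_min_s``, every LOW segment has its raw
    mean below the low bound and duration >= ``low_min_s``. An event may
    legitimately come back as a single MID segment.
    """
    cfg = cfg or BandConfig()
    x = event.samples
    if x.size == 0:
        raise ValueError("cannot segment an empty event")
    fs = event.sample_rate
    window = max(1, round(cfg.smoothing_window_s * fs))
    smoothed = uniform_filter1d(x, size=window, mode="nearest") if window > 1 else x

    runs = _runs(_base_labels(smoothed, cfg))
    runs = _apply_hysteresis(runs, smoothed, cfg)
    runs = _refine_boundaries(runs, x, window)

    min_samples = {1: round(cfg.marker_min_s * fs), 2: round(cfg.low_min_s * fs)}
    # relabel sub-minimum marker/low runs as MID, then re-merge
    runs = [
        (s, e, 0 if c in min_samples and (e - s) < min_samples[c] else c)
        for s, e, c in runs
    ]
    runs = _coalesce(runs)

    # a brief MID excursion between two band runs is noise flicker or a
    # transition sliver, not a genuine inter-state dwell: merge it
    # (shortest first) into the neighbour with the closer mean, earlier
    # neighbour on ties; MID runs at the event edges are kept
    mid_min = round(cfg.mid_min_s * fs)
    runs = [list(r) for r in runs]
    while True:
        candidates = [
            i
            for i in range(1, len(runs) - 1)
            if runs[i][2] == 0 and (runs[i][1] - runs[i][0]) < mid_min
        ]
        if not candidates:
            break
        i = min(candidates, key=lambda i: (runs[i][1] - runs[i][0], i))
        s, e, _ = runs[i]
        mean = float(np.mean(x[s:e]))
        prev_mean = float(np.mean(x[runs[i - 1][0] : runs[i - 1][1]]))
        next_mean = float(np.mean(x[runs[i + 1][0] : runs[i + 1][1]]))
        if abs(mean - prev_mean) <= abs(mean - next_mean):
            runs[i - 1][1] = e
        else:
            runs[i + 1][0] = s
        del runs[i]
        runs = [list(r) for r in _coalesce([tuple(r) for r in runs])]
    runs = _coalesce([tuple(r) for r in runs])
    # re-snap boundaries now that slivers are resolved
    runs = _refine_boundaries(runs, x, window)

    # demote marker/low runs whose raw mean violates the band definition
    lo_m, hi_m = cfg.marker_band_pA
    demoted = []
    for s, e, c in runs:
        mean = float(np.mean(x[s:e]))
        if c == 1 and not (lo_m <= mean <= hi_m):
            c = 0
        elif c == 2 and not mean < cfg.low_band_max_pA:
            c = 0
        demoted.append((s, e, c))
    runs = _coalesce(demoted)

    band_name = {0: MID, 1: MARKER_HIGH, 2: LOW}
    return [
        BandSegment(
            band=band_name[c],
            start=s,
            end=e,
            mean_pA=float(np.mean(x[s:e])),
            duration_s=(e - s) / fs,
        )
        for s, e, c in runs
    ]


def segments_table(
    segments_per_event: dict[int, list[BandSegment]], sample_rate: float
) -> pd.DataFrame:
    """Flatten per-event segment lists into a tab-separated-ready table."""
    rows = []
    for event_id, segments in segments_per_event.items():
        for seg in segments:
            rows.append(
                {
                    "event_id": event_id,
                    "band": seg.band,
                    "start_s": seg.start / sample_rate,
                    "duration_s": seg.duration_s,
                    "mean_pA": seg.mean_pA,
                }
            )
    return pd.DataFrame(
        rows, columns=["event_id", "band", "start_s", "duration_s", "mean_pA"]
    )
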