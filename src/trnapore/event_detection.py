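"""Detection of self-terminating blockade events in ionic-current traces.

An event opens when the current drops below the entry cutoff (45 or 55 pA)
after the open-channel level (68.0-72.5 pA) has been established, and
closes at the last upward cutoff crossing before the current re-enters
the open-channel band (so both boundaries are timed by the same
threshold; the open-band re-entry itself confirms self-termination). Events
shorter than the minimum duration (>0.1 ms) are discarded, as are events
in which the current goes negative (voltage-reversal ejections). Events
cut off by the end of the trace are flagged as not self-terminated.

Because the analog anti-aliasing filter of the acquisition chain delays
every threshold crossing by its (flat) group delay, detected boundaries
are corrected by that constant when the trace metadata records the analog
filter cutoff; this keeps boundaries within a few samples of the physical
event edges. The correction can be disabled or overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import filtering
from .signal_io import Trace

__all__ = [
    "DetectionParams",
    "BlockadeEvent",
    "NoOpenChannelError",
    "detect_events",
    "select_long_events",
]


class NoOpenChannelError(RuntimeError):
    """The trace never establishes an open-channel baseline."""


@dataclass
class DetectionParams:
    """Threshold criteria for blockade-event detection.

    ``delay_correction_s``: seconds to subtract from detected boundaries;
    ``None`` (default) derives the correction from the trace metadata keys
    ``analog_filter_cutoff``/``analog_filter_order`` when present, else 0.
    Set to 0.0 to disable.
    """

    open_range_pA: tuple[float, float] = (68.0, 72.5)
    entry_cutoff_pA: float = 55.0
    min_duration_s: float = 1e-4
    reject_negative: bool = True
    open_established_s: float = 1e-3
    delay_correction_s: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.open_range_pA
        if not lo < hi:
            raise ValueError("open_range_pA interval is empty")
        if not self.entry_cutoff_pA < lo:
            raise ValueError(
                f"entry cutoff {self.entry_cutoff_pA} pA must lie below the "
                f"open-channel range lower bound {lo} pA"
            )
        if not self.min_duration_s > 0:
            raise ValueError("min_duration_s must be > 0")
        if not self.open_established_s > 0:
            raise ValueError("open_established_s must be > 0")


@dataclass
class BlockadeEvent:
    """A contiguous blockade of the pore, with half-open sample bounds."""

    start: int
    end: int
    sample_rate: float
    samples: np.ndarray
    self_terminated: bool

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.sample_rate

    @property
    def mean_pA(self) -> float:
        return float(np.mean(self.samples))

    @property
    def min_pA(self) -> float:
        return float(np.min(self.samples))


def _delay_samples(trace: Trace, params: DetectionParams) -> int:
    if params.delay_correction_s is not None:
        return round(params.delay_correction_s * trace.sample_rate)
    cutoff = trace.metadata.get("analog_filter_cutoff")
    if not cutoff:
        return 0
    order = int(trace.metadata.get("analog_filter_order", 4))
    return round(
        filtering.group_delay_samples(float(cutoff), order, trace.sample_rate)
    )


def detect_events(trace: Trace, params: DetectionParams | None = None) -> list[BlockadeEvent]:
    """Find blockade events in *trace* by threshold criteria.

    The open-channel baseline is considered established once the trailing
    ``open_established_s`` moving average lies inside the open range; this
    debounces event onset against noise and enforces a minimum open-channel
    validation between consecutive events.

    Raises
    ------
    NoOpenChannelError
        If the moving-average current never enters the open range.
    """
    params = params or DetectionParams()
    x = trace.samples
    n = x.size
    if n == 0:
        raise NoOpenChannelError("empty trace: no open channel")
    lo, hi = params.open_range_pA
    win = max(1, round(params.open_established_s * trace.sample_rate))
    # trailing moving average: value at i summarises x[i-win+1 .. i]
    avg = uniform_filter1d(x, size=win, mode="nearest", origin=-(win // 2))
    established = (avg >= lo) & (avg <= hi)
    est_idx = np.flatnonzero(established)
    if est_idx.size == 0:
        raise NoOpenChannelError(
            f"no open channel: moving average never enters [{lo}, {hi}] pA"
        )
    below_idx = np.flatnonzero(x < params.entry_cutoff_pA)
    inopen_idx = np.flatnonzero((x >= lo) & (x <= hi))

    delay = _delay_samples(trace, params)
    raw: list[tuple[int, int, bool]] = []
    pos = 0
    while True:
        j = np.searchsorted(est_idx, pos)
        if j == est_idx.size:
            break
        open_at = est_idx[j]
        k = np.searchsorted(below_idx, open_at + 1)
        if k == below_idx.size:
            break
        start = below_idx[k]
        m = np.searchsorted(inopen_idx, start + 1)
        if m == inopen_idx.size:
            raw.append((start, n, False))
            break
        reentry = inopen_idx[m]
        # the event ends at the last upward cutoff crossing before the
        # confirmed open-channel re-entry; dips back below the cutoff on
        # the way up are within-event fluctuations
        j = np.searchsorted(below_idx, reentry) - 1
        end = int(below_idx[j]) + 1
        raw.append((start, end, True))
        pos = reentry

    events: list[BlockadeEvent] = []
    prev_end = 0
    for start, end, self_term in raw:
        s = max(start - delay, prev_end, 0)
        e = max(end - delay if self_term else end, s + 1)
        e = min(e, n)
        prev_end = e
        duration = (e - s) / trace.sample_rate
        if duration < params.min_duration_s:
            continue
        seg = x[s:e]
        if params.reject_negative and np.any(seg < 0):
            continue
        events.append(
            BlockadeEvent(
                start=s,
                end=e,
                sample_rate=trace.sample_rate,
                samples=seg,
                self_terminated=self_term,
            )
        )
    return events


def select_long_events(
    events: list[BlockadeEvent], min_s: float = 1.0
) -> list[BlockadeEvent]:
    """Self-terminating events longer than ``min_s`` seconds (default >1 s)."""
    return [e for e in events if e.self_terminated and e.duration_s > min_s]
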