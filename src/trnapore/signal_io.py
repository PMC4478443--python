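"""Reading and writing ionic-current traces and tabular pipeline artifacts.

Two interchange formats are supported for traces:

* columnar text — two tab-separated columns ``time_s`` and ``current_pA``
  preceded by ``#``-prefixed header lines carrying the sampling rate and
  free-form metadata;
* an HDF5 container — a single ``current_pA`` dataset with ``sample_rate``
  and metadata stored as attributes.

Event, segment, feature and manifest tables are plain tab-separated files
with a header row, read and written through pandas.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "TraceParseError",
    "read_trace",
    "write_trace",
    "write_events",
    "read_events",
    "write_table",
    "read_table",
    "EVENT_COLUMNS",
]

#: Column order of the per-event table produced by the detection stage.
EVENT_COLUMNS = [
    "event_id",
    "start_s",
    "duration_s",
    "mean_pA",
    "self_terminated",
    "category",
]

_TEXT_EXTENSIONS = {".txt", ".tsv", ".dat", ".csv"}
_HDF5_EXTENSIONS = {".h5", ".hdf5"}


class TraceParseError(ValueError):
    """Raised when a trace file cannot be parsed; names the offending line."""


@dataclass
class Trace:
    """A uniformly sampled ionic-current record.

    Parameters
    ----------
    samples : ndarray
        Current values in picoamperes.
    sample_rate : float
        Digitisation rate in Hz (samples per second).
    metadata : dict
        Free-form key/value metadata (e.g. ``voltage_mV``, ``substrate``,
        ``analog_filter_cutoff``). Preserved across round-trips.
    """

    samples: np.ndarray
    sample_rate: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def time(self) -> np.ndarray:
        """Sample times in seconds (0-based)."""
        return np.arange(self.samples.size) / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "Trace":
        """A copy of this trace with ``samples`` replaced, metadata shared."""
        return Trace(samples, self.sample_rate, dict(self.metadata))


def _resolve_format(path: str, format_hint: str | None) -> str:
    if format_hint is not None:
        if format_hint not in ("text", "hdf5"):
            raise ValueError(f"unknown trace format {format_hint!r}")
        return format_hint
    ext = os.path.splitext(str(path))[1].lower()
    if ext in _HDF5_EXTENSIONS:
        return "hdf5"
    return "text"


def write_trace(trace: Trace, path: str, format_hint: str | None = None) -> None:
    """Write *trace* to *path* in columnar text or the HDF5 container.

    The format is taken from ``format_hint`` ("text" or "hdf5") or inferred
    from the file extension (``.h5``/``.hdf5`` select HDF5).
    """
    fmt = _resolve_format(path, format_hint)
    if fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("current_pA", data=trace.samples)
            ds.attrs["sample_rate"] = float(trace.sample_rate)
            for key, value in trace.metadata.items():
                ds.attrs[str(key)] = value
        return
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz: {trace.sample_rate!r}\n")
        for key, value in trace.metadata.items():
            fh.write(f"# {key}: {value!r}\n")
        fh.write("time_s\tcurrent_pA\n")
        t = trace.time()
        for ti, ci in zip(t, trace.samples):
            fh.write(f"{ti:.9f}\t{ci:.17g}\n")


def _parse_metadata_value(text: str):
    text = text.strip()
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            pass
    if len(text) >= 2 and text[0] == text[-1] and text[0] in "'\"":
        return text[1:-1]
    return text


def read_trace(path: str, format_hint: str | None = None) -> Trace:
    """Read a trace written by :func:`write_trace`.

    Raises
    ------
    TraceParseError
        On malformed text input (names the 1-based line number) or when the
        sampling rate is missing.
    FileNotFoundError
        If *path* does not exist.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format_hint)
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            if "current_pA" not in fh:
                raise TraceParseError(f"{path}: missing 'current_pA' dataset")
            ds = fh["current_pA"]
            attrs = dict(ds.attrs)
            if "sample_rate" not in attrs:
                raise TraceParseError(f"{path}: missing sample_rate attribute")
            rate = float(attrs.pop("sample_rate"))
            meta = {
                k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in attrs.items()
            }
            return Trace(ds[...], rate, meta)

    rate = None
    metadata: dict = {}
    samples: list[float] = []
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip()
                    if key == "sample_rate_hz":
                        try:
                            rate = float(value)
                        except ValueError:
                            raise TraceParseError(
                                f"{path}:{lineno}: bad sample rate {value.strip()!r}"
                            ) from None
                    else:
                        metadata[key] = _parse_metadata_value(value)
                continue
            if not saw_header and line.startswith("time_s"):
                saw_header = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TraceParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                samples.append(float(parts[1]))
            except ValueError:
                raise TraceParseError(
                    f"{path}:{lineno}: non-numeric current value {parts[1]!r}"
                ) from None
    if rate is None:
        raise TraceParseError(f"{path}: missing '# sample_rate_hz:' header")
    return Trace(np.asarray(samples), rate, metadata)


def write_events(events: Iterable, path: str, categories=None) -> None:
    """Write a per-event table (one row per blockade event) to *path*.

    ``events`` may be an iterable of ``BlockadeEvent`` or a DataFrame that
    already has :data:`EVENT_COLUMNS`. ``categories`` optionally supplies a
    category label per event (same order).
    """
    if isinstance(events, pd.DataFrame):
        df = events.loc[:, EVENT_COLUMNS]
    else:
        events = list(events)
        cats = list(categories) if categories is not None else [""] * len(events)
        rows = []
        for i, (ev, cat) in enumerate(zip(events, cats)):
            rows.append(
                {
                    "event_id": i,
                    "start_s": ev.start / ev.sample_rate,
                    "duration_s": ev.duration_s,
                    "mean_pA": ev.mean_pA,
                    "self_terminated": bool(ev.self_terminated),
                    "category": cat or "",
                }
            )
        df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str) -> pd.DataFrame:
    """Read a per-event table written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: event table missing columns {missing}")
    if "category" in df.columns:
        df["category"] = df["category"].fillna("")
    return df


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a generic tab-separated table with a header row."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    """Read a tab-separated table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
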