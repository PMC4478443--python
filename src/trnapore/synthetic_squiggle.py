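"""Synthetic nanopore squiggle generator with planted ground truth.

Emulates the signal phenomenology of alpha-hemolysin recordings of
adapter-ligated RNA: an open-channel level in 68.0-72.5 pA, self-terminating
blockade events rendered as piecewise-constant state sequences, abasic-marker
high-current states (33.5-36.5 pA), low-current RNA states (<26.5 pA),
additive Gaussian noise at the digitiser rate, and a causal low-pass Bessel
stage standing in for the instrument's 5 kHz analog filter. Every planted
event and state is returned in a manifest with exact half-open sample
boundaries, so downstream detection/segmentation/classification stages can
be scored against ground truth.

Blockade dwell times follow log-normal populations parameterised in log10
seconds, matching the semi-log presentation of nanopore dwell data; the
module ships the printed population means/SEMs for the substrates studied
(adapter alone, adapted tRNA with and without Mg2+, adapted RNA hairpin with
and without the phi29 DNAP brake).

A feature-level generator (:func:`make_two_class_cohort`) produces labelled
region I-III feature tables for two tRNA classes whose region II (the
RNA-dependent, inter-marker span) distributions differ while the
adapter-dependent regions I/III are shared — the structure the
discrimination stage is designed to exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import filtering
from .signal_io import Trace

__all__ = [
    "MARKER_HIGH",
    "LOW",
    "MID",
    "ADAPTER",
    "CATEGORIES",
    "LEADING_AND_TRAILING",
    "LEADING_ONLY",
    "TRAILING_ONLY",
    "OTHER",
    "SimConfig",
    "StateSpec",
    "PlantedEvent",
    "DwellModel",
    "RegionModel",
    "DWELL_MODELS",
    "DEFAULT_REGION_MODELS",
    "sample_dwell",
    "simulate_trace",
    "make_category_event",
    "make_blockade_event",
    "make_two_class_cohort",
    "event_bounds",
]

# state / band labels
MARKER_HIGH = "MARKER_HIGH"
LOW = "LOW"
MID = "MID"
ADAPTER = "ADAPTER"

# event truth categories (leading/trailing abasic-marker combinations)
LEADING_AND_TRAILING = "LEADING_AND_TRAILING"
LEADING_ONLY = "LEADING_ONLY"
TRAILING_ONLY = "TRAILING_ONLY"
OTHER = "OTHER"
CATEGORIES = (LEADING_AND_TRAILING, LEADING_ONLY, TRAILING_ONLY, OTHER)

MARKER_BAND = (33.5, 36.5)
LOW_BAND_MAX = 26.5


@dataclass
class SimConfig:
    """Operating parameters of the simulated recording.

    ``noise_sd_pA`` is the white-noise standard deviation injected at the
    digitiser rate, before the analog-filter emulation; the default (3.0)
    yields a post-filter RMS of about 1 pA at 100 kHz / 5 kHz, typical of
    alpha-hemolysin recordings.
    """

    sample_rate: float = 100_000.0
    open_channel_pA: tuple[float, float] = (68.0, 72.5)
    noise_sd_pA: float = 3.0
    analog_filter_cutoff: float = 5000.0
    analog_filter_order: int = 4
    seed: int = 0
    event_rate: float = 1.0  # events per second of trace
    min_gap_s: float = 0.01  # open-channel floor between events

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        if self.noise_sd_pA < 0:
            raise ValueError("noise_sd_pA must be >= 0")
        lo, hi = self.open_channel_pA
        if not lo < hi:
            raise ValueError("open_channel_pA interval is empty")
        if not self.event_rate > 0:
            raise ValueError("event_rate must be > 0")


@dataclass
class StateSpec:
    """One piecewise-constant sub-state of a blockade event."""

    label: str
    level_pA: float
    dwell_s: float

    def __post_init__(self) -> None:
        if self.label not in (MARKER_HIGH, LOW, MID, ADAPTER):
            raise ValueError(f"unknown state label {self.label!r}")
        if not self.dwell_s > 0:
            raise ValueError("state dwell_s must be > 0")
        if self.label == MARKER_HIGH and not (
            MARKER_BAND[0] <= self.level_pA <= MARKER_BAND[1]
        ):
            raise ValueError(
                f"MARKER_HIGH level {self.level_pA} pA outside {MARKER_BAND}"
            )
        if self.label == LOW and not self.level_pA < LOW_BAND_MAX:
            raise ValueError(f"LOW level {self.level_pA} pA not below {LOW_BAND_MAX}")


@dataclass
class PlantedEvent:
    """A blockade event template plus, after placement, its trace location."""

    states: list[StateSpec]
    start_index: int | None = None
    truth_category: str = ""
    truth_class: str = ""

    @property
    def total_duration_s(self) -> float:
        return sum(s.dwell_s for s in self.states)

    def n_samples(self, sample_rate: float) -> int:
        return sum(max(1, round(s.dwell_s * sample_rate)) for s in self.states)


@dataclass
class DwellModel:
    """Log-normal dwell-time population, parameterised in log10 seconds.

    ``log10_sem`` is the standard error of the population's log10 mean as
    reported for a reference sample of ``n_reference`` events; the
    population spread is therefore ``log10_sem * sqrt(n_reference)``.
    """

    log10_mean: float
    log10_sem: float
    n_reference: int = 200

    def __post_init__(self) -> None:
        if self.log10_sem < 0:
            raise ValueError("log10_sem must be >= 0")
        if self.n_reference < 1:
            raise ValueError("n_reference must be >= 1")

    @property
    def log10_sd(self) -> float:
        return self.log10_sem * math.sqrt(self.n_reference)

    @classmethod
    def from_sd(cls, log10_mean: float, log10_sd: float) -> "DwellModel":
        """Construct directly from a population log10 standard deviation."""
        return cls(log10_mean, log10_sd, n_reference=1)


#: Printed dwell-time populations (log10 mean +/- SEM over ~200 events).
DWELL_MODELS: dict[str, DwellModel] = {
    "adapter_alone": DwellModel(-3.9, 0.04),
    "adapted_trna_fmet": DwellModel(-2.6, 0.06),
    "adapted_trna_fmet_mg": DwellModel(-1.4, 0.1),
    "adapted_hairpin": DwellModel(-3.2, 0.02),
    "adapted_hairpin_dnap_short": DwellModel(-2.9, 0.09),
    "adapted_hairpin_dnap_braked": DwellModel(0.43, 0.03),
}


def sample_dwell(model: DwellModel, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` dwell times (seconds) from a log-normal dwell model.

    ``seed`` may be an int or a ``numpy.random.Generator``. Zero spread
    returns exactly ``10**log10_mean`` for every draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draws = rng.normal(model.log10_mean, model.log10_sd, size=n)
    return np.power(10.0, draws)


# ---------------------------------------------------------------------------
# event templates


def _marker_state(rng: np.random.Generator, dwell_s: float) -> StateSpec:
    # keep planted levels off the band edges so segment means stay in band
    return StateSpec(MARKER_HIGH, rng.uniform(34.3, 35.9), dwell_s)


def _low_state(rng: np.random.Generator, dwell_s: float) -> StateSpec:
    return StateSpec(LOW, rng.uniform(18.0, 24.0), dwell_s)


def _mid_state(rng: np.random.Generator, dwell_s: float, level=None) -> StateSpec:
    level = rng.uniform(28.0, 32.5) if level is None else level
    return StateSpec(MID, level, dwell_s)


def _adapter_state(rng: np.random.Generator, dwell_s: float) -> StateSpec:
    return StateSpec(ADAPTER, rng.uniform(28.0, 32.5), dwell_s)


def make_category_event(
    category: str,
    rng: np.random.Generator,
    total_duration_s: float | None = None,
    truth_class: str = "",
    mid_level: float | None = None,
) -> PlantedEvent:
    """Build a long blockade-event template of a given marker category.

    Sub-state dwell times within an event are free parameters of the
    generator (only the marker minimums are constrained by the band rules):
    the leading (5') marker is long (~30-80 ms), the trailing (3') marker
    short (~3-8 ms), and the qualifying low-current RNA state >=15 ms. The
    event total defaults to 1.1-1.8 s so that every template passes the
    >1 s long-event selection.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if total_duration_s is None:
        total_duration_s = rng.uniform(1.1, 1.8)

    lead = 10.0 ** rng.uniform(-1.5, -1.1)
    trail = 10.0 ** rng.uniform(-2.5, -2.1)
    low = 10.0 ** rng.uniform(-1.7, -1.3)
    adapter = 10.0 ** rng.uniform(-2.0, -1.6)

    if category == LEADING_AND_TRAILING:
        fixed = adapter + lead + low + trail
        filler = total_duration_s - fixed
        states = [
            _adapter_state(rng, adapter),
            _marker_state(rng, lead),
            _mid_state(rng, 0.45 * filler, mid_level),
            _low_state(rng, low),
            _mid_state(rng, 0.55 * filler, mid_level),
            _marker_state(rng, trail),
        ]
    elif category == LEADING_ONLY:
        fixed = adapter + lead + low
        filler = total_duration_s - fixed
        states = [
            _adapter_state(rng, adapter),
            _marker_state(rng, lead),
            _mid_state(rng, 0.45 * filler, mid_level),
            _low_state(rng, low),
            _mid_state(rng, 0.55 * filler, mid_level),
        ]
    elif category == TRAILING_ONLY:
        fixed = adapter + low + trail
        filler = total_duration_s - fixed
        states = [
            _adapter_state(rng, adapter),
            _mid_state(rng, 0.45 * filler, mid_level),
            _low_state(rng, low),
            _mid_state(rng, 0.55 * filler, mid_level),
            _marker_state(rng, trail),
        ]
    else:  # OTHER: either no marker at all, or more than two markers
        if rng.random() < 0.5:
            fixed = adapter + low
            filler = total_duration_s - fixed
            states = [
                _adapter_state(rng, adapter),
                _mid_state(rng, 0.5 * filler, mid_level),
                _low_state(rng, low),
                _mid_state(rng, 0.5 * filler, mid_level),
            ]
        else:
            extra = 10.0 ** rng.uniform(-2.3, -2.0)
            fixed = adapter + lead + low + trail + extra
            filler = total_duration_s - fixed
            states = [
                _adapter_state(rng, adapter),
                _marker_state(rng, lead),
                _mid_state(rng, 0.3 * filler, mid_level),
                _low_state(rng, low),
                _mid_state(rng, 0.3 * filler, mid_level),
                _marker_state(rng, extra),
                _mid_state(rng, 0.4 * filler, mid_level),
                _marker_state(rng, trail),
            ]
    if filler <= 0.02:
        raise ValueError(
            f"total_duration_s={total_duration_s} too short for category {category}"
        )
    return PlantedEvent(states=states, truth_category=category, truth_class=truth_class)


def make_blockade_event(
    level_pA: float,
    duration_s: float,
    truth_category: str = "",
    truth_class: str = "",
) -> PlantedEvent:
    """A single-state blockade template (simple rectangular dip)."""
    label = LOW if level_pA < LOW_BAND_MAX else (
        MARKER_HIGH if MARKER_BAND[0] <= level_pA <= MARKER_BAND[1] else MID
    )
    return PlantedEvent(
        states=[StateSpec(label, level_pA, duration_s)],
        truth_category=truth_category,
        truth_class=truth_class,
    )


# ---------------------------------------------------------------------------
# trace rendering


def simulate_trace(
    config: SimConfig,
    events: Sequence[PlantedEvent],
    duration_s: float | None = None,
) -> tuple[Trace, pd.DataFrame]:
    """Render planted events into a noisy, filter-emulated trace.

    Events with ``start_index`` set are honoured (and checked for overlap);
    events without are placed left-to-right with exponential inter-event
    gaps at ``config.event_rate`` (floored at ``config.min_gap_s``). The
    trace holds the open-channel level between events; 10% open-channel
    padding is appended (or ``duration_s`` is honoured if given — too short
    a request is rejected).

    Returns
    -------
    (Trace, DataFrame)
        The trace (metadata records the open level and analog-filter
        emulation) and a manifest with one row per planted state:
        ``event_id, start_sample, end_sample, state_index, state,
        level_pA, truth_category, truth_class`` — all indices half-open
        on the unfiltered, noise-free plant.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    open_level = rng.uniform(*config.open_channel_pA)

    placed: list[tuple[int, PlantedEvent]] = []
    pos = 0
    explicit = [e for e in events if e.start_index is not None]
    if explicit and len(explicit) != len(events):
        raise ValueError("either all or none of the events may carry start_index")
    if explicit:
        for ev in sorted(events, key=lambda e: e.start_index):
            placed.append((int(ev.start_index), ev))
        for (s0, e0), (s1, e1) in zip(placed, placed[1:]):
            if s0 + e0.n_samples(fs) > s1:
                raise ValueError(
                    f"planted events overlap near samples {s0}..{s1}"
                )
        pos = placed[-1][0] + placed[-1][1].n_samples(fs) if placed else 0
    else:
        for ev in events:
            gap = max(config.min_gap_s, rng.exponential(1.0 / config.event_rate))
            pos += round(gap * fs)
            placed.append((pos, ev))
            pos += ev.n_samples(fs)

    min_len = math.ceil(pos * 1.1) + round(0.01 * fs)
    if duration_s is None:
        n_total = min_len
    else:
        n_total = round(duration_s * fs)
        if n_total < pos + round(config.min_gap_s * fs):
            raise ValueError(
                f"requested trace of {duration_s} s is too short for the "
                f"planted events (need >= {pos / fs:.3f} s)"
            )

    x = np.full(n_total, open_level)
    rows = []
    for event_id, (start, ev) in enumerate(placed):
        cursor = start
        for state_index, st in enumerate(ev.states):
            n = max(1, round(st.dwell_s * fs))
            x[cursor : cursor + n] = st.level_pA
            rows.append(
                {
                    "event_id": event_id,
                    "start_sample": cursor,
                    "end_sample": cursor + n,
                    "state_index": state_index,
                    "state": st.label,
                    "level_pA": st.level_pA,
                    "truth_category": ev.truth_category,
                    "truth_class": ev.truth_class,
                }
            )
            cursor += n
    manifest = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "start_sample",
            "end_sample",
            "state_index",
            "state",
            "level_pA",
            "truth_category",
            "truth_class",
        ],
    )

    if config.noise_sd_pA > 0:
        x = x + rng.normal(0.0, config.noise_sd_pA, size=n_total)

    metadata = {
        "open_level_pA": float(open_level),
        "substrate": "synthetic",
    }
    trace = Trace(x, fs, metadata)
    if config.analog_filter_cutoff:
        trace = filtering.bessel_lowpass(
            trace,
            cutoff_hz=config.analog_filter_cutoff,
            order=config.analog_filter_order,
            zero_phase=False,
        )
        trace.metadata["analog_filter_cutoff"] = float(config.analog_filter_cutoff)
        trace.metadata["analog_filter_order"] = int(config.analog_filter_order)
    return trace, manifest


def event_bounds(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-event [start, end) sample bounds and truth labels from a manifest."""
    grouped = manifest.groupby("event_id")
    out = pd.DataFrame(
        {
            "start_sample": grouped["start_sample"].min(),
            "end_sample": grouped["end_sample"].max(),
            "truth_category": grouped["truth_category"].first(),
            "truth_class": grouped["truth_class"].first(),
        }
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# feature-level two-class cohorts


@dataclass
class RegionModel:
    """Per-region feature distribution: dwell model + Gaussian mean current."""

    dwell: DwellModel
    mean_pA: float
    sd_pA: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_pA < 0:
            raise ValueError("sd_pA must be >= 0")


#: Default calibration of the two-class cohort: adapter-dependent regions
#: I and III are identical across classes; the RNA-dependent region II
#: differs in both dwell (0.25 log10 s apart) and mean current (3 pA apart),
#: i.e. roughly 1 and 2 pooled SDs respectively.
DEFAULT_REGION_MODELS: dict[str, object] = {
    "I": RegionModel(DwellModel.from_sd(-1.1, 0.15), 33.0, 1.0),
    "II": (
        RegionModel(DwellModel.from_sd(0.30, 0.25), 26.0, 1.5),
        RegionModel(DwellModel.from_sd(0.55, 0.25), 29.0, 1.5),
    ),
    "III": RegionModel(DwellModel.from_sd(-2.2, 0.2), 35.0, 0.8),
}


def make_two_class_cohort(
    n_per_class: int = 80,
    region_models: dict | None = None,
    class_labels: tuple[str, str] = ("fMet", "Lys"),
    seed=0,
) -> pd.DataFrame:
    """Labelled region I-III feature table for a two-class experiment.

    ``region_models`` maps region name ("I", "II", "III") to either a single
    :class:`RegionModel` (shared by both classes — the default for the
    adapter-dependent regions I and III) or a pair of models (one per class,
    as for the RNA-dependent region II).

    Returns a DataFrame with one row per event: ``event_id, class_label,
    dur_I, mean_I, dur_II, mean_II, dur_III, mean_III``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    models = dict(DEFAULT_REGION_MODELS if region_models is None else region_models)
    for region in ("I", "II", "III"):
        if region not in models:
            raise ValueError(f"region_models missing region {region!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rows = []
    event_id = 0
    for class_idx, label in enumerate(class_labels):
        row_block = {"class_label": [label] * n_per_class}
        for region in ("I", "II", "III"):
            model = models[region]
            if isinstance(model, (tuple, list)):
                model = model[class_idx]
            durations = sample_dwell(model.dwell, n_per_class, rng)
            currents = rng.normal(model.mean_pA, model.sd_pA, size=n_per_class)
            row_block[f"dur_{region}"] = durations
            row_block[f"mean_{region}"] = currents
        block = pd.DataFrame(row_block)
        block.insert(0, "event_id", np.arange(event_id, event_id + n_per_class))
        event_id += n_per_class
        rows.append(block)
    return pd.concat(rows, ignore_index=True)
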