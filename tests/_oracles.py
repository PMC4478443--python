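"""Independent brute-force oracles used to cross-check the pipeline.

The classification oracle evaluates the marker rules directly on plain
(band, duration, mean) tuples, footnote by footnote, without sharing any
code with the production classifier.
"""

from __future__ import annotations

import numpy as np

MARKER_BAND = (33.5, 36.5)
LOW_MAX = 26.5
MARKER_MIN_S = 2e-3
LOW_MIN_S = 1e-2


def oracle_classify(
    segs: list[tuple[str, float, float]],
    proximal_fraction: float = 0.1,
    proximal_min_s: float = 0.05,
) -> str:
    """Classify a band sequence given as [(band, duration_s, mean_pA), ...].

    Enumerates the rule predicates directly: a qualifying marker is a
    MARKER_HIGH stretch with mean in 33.5-36.5 pA lasting >= 2 ms; a
    qualifying low is a LOW stretch with mean < 26.5 pA lasting >= 10 ms.
    """
    event_duration = sum(d for _, d, _ in segs)
    # positions (start, end) in seconds of every segment
    starts = np.concatenate(([0.0], np.cumsum([d for _, d, _ in segs])[:-1]))
    qual = []
    for (band, dur, mean), start in zip(segs, starts):
        is_marker = (
            band == "MARKER_HIGH"
            and MARKER_BAND[0] <= mean <= MARKER_BAND[1]
            and dur >= MARKER_MIN_S
        )
        is_low = band == "LOW" and mean < LOW_MAX and dur >= LOW_MIN_S
        qual.append((is_marker, is_low, start, start + dur))

    marker_spans = [(s, e) for m, l, s, e in qual if m]
    low_spans = [(s, e) for m, l, s, e in qual if l]

    if len(marker_spans) == 2:
        (s1, e1), (s2, e2) = marker_spans
        window = max(proximal_fraction * event_duration, proximal_min_s)
        proximal = (event_duration - e2) <= window + 1e-12
        low_between = any(ls >= e1 - 1e-12 and le <= s2 + 1e-12 for ls, le in low_spans)
        if proximal and low_between:
            return "LEADING_AND_TRAILING"
        return "OTHER"
    if len(marker_spans) == 1 and low_spans:
        ms, me = marker_spans[0]
        if all(ls >= me - 1e-12 for ls, le in low_spans):
            return "LEADING_ONLY"
        if all(le <= ms + 1e-12 for ls, le in low_spans):
            return "TRAILING_ONLY"
    return "OTHER"


def oracle_segment_labels(x: np.ndarray, sample_rate: float):
    """Brute-force band scan of a noise-free piecewise-constant event.

    Labels every raw sample by the band thresholds, takes maximal runs,
    relabels runs shorter than their band minimum as MID, and merges
    adjacent equal-band runs. Returns [(band, start, end), ...].
    """
    labels = []
    for v in x:
        if MARKER_BAND[0] <= v <= MARKER_BAND[1]:
            labels.append("MARKER_HIGH")
        elif v < LOW_MAX:
            labels.append("LOW")
        else:
            labels.append("MID")
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([labels[start], start, i])
            start = i
    min_n = {
        "MARKER_HIGH": round(MARKER_MIN_S * sample_rate),
        "LOW": round(LOW_MIN_S * sample_rate),
    }
    for run in runs:
        band, s, e = run
        if band in min_n and (e - s) < min_n[band]:
            run[0] = "MID"
    merged = []
    for band, s, e in runs:
        if merged and merged[-1][0] == band:
            merged[-1][2] = e
        else:
            merged.append([band, s, e])
    return [(band, s, e) for band, s, e in merged]


def random_segment_sequence(rng: np.random.Generator):
    """A random band sequence exercising the qualification edge cases.

    Durations and means straddle the qualification thresholds so that
    sub-minimum and out-of-band segments occur frequently.
    """
    n = int(rng.integers(1, 7))
    bands = []
    prev = None
    for _ in range(n):
        choices = [b for b in ("MARKER_HIGH", "LOW", "MID") if b != prev]
        prev = choices[int(rng.integers(len(choices)))]
        bands.append(prev)
    segs = []
    for band in bands:
        if band == "MARKER_HIGH":
            dur = float(rng.choice([1e-3, 2e-3, 3e-3, 8e-3, 0.05]))
            mean = float(rng.uniform(32.5, 37.5))
        elif band == "LOW":
            dur = float(rng.choice([5e-3, 1e-2, 2e-2, 0.1]))
            mean = float(rng.uniform(24.0, 28.0))
        else:
            dur = float(10 ** rng.uniform(-3, -0.3))
            mean = float(rng.uniform(27.0, 33.0))
        segs.append((band, dur, mean))
    return segs
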