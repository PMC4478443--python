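"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np

from trnapore.band_segmentation import BandSegment
from trnapore.event_detection import BlockadeEvent

FS = 100_000.0


def make_segments(specs, fs: float = FS) -> list[BandSegment]:
    """BandSegments from [(band, duration_s, mean_pA), ...], tiled from 0."""
    out = []
    cursor = 0
    for band, dur, mean in specs:
        n = max(1, round(dur * fs))
        out.append(
            BandSegment(
                band=band,
                start=cursor,
                end=cursor + n,
                mean_pA=float(mean),
                duration_s=n / fs,
            )
        )
        cursor += n
    return out


def event_from_levels(specs, fs: float = FS, noise_sd: float = 0.0, seed=0) -> BlockadeEvent:
    """A BlockadeEvent rendered directly from (level_pA, duration_s) pairs."""
    rng = np.random.default_rng(seed)
    parts = []
    for level, dur in specs:
        n = max(1, round(dur * fs))
        block = np.full(n, float(level))
        if noise_sd:
            block = block + rng.normal(0, noise_sd, n)
        parts.append(block)
    samples = np.concatenate(parts)
    return BlockadeEvent(
        start=0,
        end=samples.size,
        sample_rate=fs,
        samples=samples,
        self_terminated=True,
    )
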