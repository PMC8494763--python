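"""Shared fixtures and independent brute-force oracles.

The naive helpers here deliberately re-derive runs and measures by scanning
one frame at a time in pure Python; they stay independent of the vectorised
implementation they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from facegaze import GazeStream, SyntheticConfig, sample_cohort


def naive_runs(
    hits,
    valid,
    segment=None,
    min_instance_frames: int = 1,
):
    """Per-frame scan for gaze runs with truncate-onset segment handling.

    Returns a list of (onset_frame, truncated_length) for runs whose onset
    lies inside the segment; lengths are cut at the segment's right edge.
    The minimum-instance filter applies to the full (untruncated) run.
    """
    hits = list(hits)
    valid = list(valid)
    n = len(hits)
    a, b = (0, n) if segment is None else segment
    full = []  # (onset, end) of maximal ON-valid blocks
    onset = None
    for i in range(n):
        active = bool(hits[i]) and bool(valid[i])
        if active and onset is None:
            onset = i
        elif not active and onset is not None:
            full.append((onset, i))
            onset = None
    if onset is not None:
        full.append((onset, n))
    out = []
    for s, e in full:
        if e - s < min_instance_frames:
            continue
        if a <= s < b:
            out.append((s, min(e, b) - s))
    return out


def naive_measures(hits, valid, frame_interval_s, segment=None):
    """Brute-force duration/frequency/dwell for a segment (no filters)."""
    n = len(hits)
    a, b = (0, n) if segment is None else segment
    n_valid = sum(1 for i in range(a, b) if valid[i])
    if n_valid == 0:
        return None
    minutes = n_valid * frame_interval_s / 60.0
    on = sum(1 for i in range(a, b) if hits[i] and valid[i])
    on_s = on * frame_interval_s
    inst = len(naive_runs(hits, valid, (a, b)))
    return {
        "duration_per_min": on_s / minutes,
        "frequency_per_min": inst / minutes,
        "mean_dwell_s": on_s / inst if inst else math.nan,
        "n_instances": inst,
        "minutes": minutes,
    }


def random_stream(rng: np.random.Generator, max_len: int = 5000) -> GazeStream:
    n = int(rng.integers(1, max_len + 1))
    p_on = rng.uniform(0.05, 0.95)
    p_valid = rng.uniform(0.5, 1.0)
    return GazeStream(
        consultation_id="R",
        physician_id="P",
        hits=rng.random(n) < p_on,
        valid=rng.random(n) < p_valid,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared read-only across tests."""
    config = SyntheticConfig()
    streams, cohort = sample_cohort(config, seed=7)
    return config, streams, cohort
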