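"""Gaze runs and the three face-gaze measures.

A *run* (one gaze instance) is a maximal block of consecutive ON frames that
are all valid; an OFF frame or an invalid frame interrupts it.  From the
runs of a stream, or of any segment of it, three measures are derived:

* duration per minute — seconds of face gaze per analysed minute,
* frequency per minute — number of gaze instances per analysed minute,
* mean dwell time — seconds of face gaze per instance.

The identity ``duration = frequency x dwell`` holds exactly on every segment
with at least one instance, because all three come from the same ON-second
total and instance count.

Segment boundaries use the *truncate-onset* policy: a run crossing a
boundary contributes its in-segment seconds to each side's duration, but is
counted as an instance only in the segment containing its onset.  This
conserves total duration across any partition and counts each instance
exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    BoundsError,
    DegenerateSegmentError,
    DegenerateStreamError,
)
from .stream import GazeStream

__all__ = [
    "GazeRun",
    "GazeMeasures",
    "DecileProfile",
    "extract_runs",
    "compute_measures",
    "decile_profile",
    "decile_table",
    "MEASURE_NAMES",
]

MEASURE_NAMES = ("duration", "frequency", "dwell")
N_DECILES = 10


@dataclass(frozen=True)
class GazeRun:
    """One uninterrupted face-gaze instance (possibly boundary-truncated)."""

    onset_frame: int
    length_frames: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.length_frames < 1:
            raise ValueError("a gaze run spans at least one frame")


@dataclass(frozen=True)
class GazeMeasures:
    """The duration / frequency / dwell triplet for a stream or segment.

    ``mean_dwell_s`` is NaN when the segment contains no gaze instance;
    it is never coded as zero, which would break the measure identity.
    """

    duration_per_min: float
    frequency_per_min: float
    mean_dwell_s: float
    n_instances: int
    minutes: float

    def as_dict(self) -> dict[str, float]:
        return {
            "duration_per_min": self.duration_per_min,
            "frequency_per_min": self.frequency_per_min,
            "mean_dwell_s": self.mean_dwell_s,
            "n_instances": self.n_instances,
            "minutes": self.minutes,
        }

    def value(self, measure_name: str) -> float:
        return {
            "duration": self.duration_per_min,
            "frequency": self.frequency_per_min,
            "dwell": self.mean_dwell_s,
        }[measure_name]


@dataclass(frozen=True)
class DecileProfile:
    """Per-consultation 10-bin time course of one measure.

    Bins partition the *valid* frames (not wall-clock frames), so gap-masked
    stretches do not distort the time base.
    """

    consultation_id: str
    measure_name: str
    values: np.ndarray
    bin_minutes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "bin_minutes", np.asarray(self.bin_minutes, dtype=float)
        )
        if self.values.shape != (N_DECILES,) or self.bin_minutes.shape != (N_DECILES,):
            raise ValueError("a decile profile has exactly 10 bins")
        if not (self.bin_minutes > 0).all():
            raise ValueError("every decile bin must have positive duration")
        if self.measure_name not in MEASURE_NAMES:
            raise ValueError(f"unknown measure {self.measure_name!r}")


# ---------------------------------------------------------------------------
# run index: computed once per stream, queried per segment


class _RunIndex:
    """Vectorised run decomposition of one stream.

    ``onsets``/``on_counts`` describe each run (in frame order); ``retained``
    applies the minimum-instance-length filter; ``active_pos`` lists the
    frame index of every ON-valid frame belonging to a retained-or-not run,
    with ``active_run`` giving its run id.
    """

    def __init__(
        self,
        stream: GazeStream,
        min_instance_frames: int = 1,
        bridge_invalid_frames: int = 0,
    ):
        if min_instance_frames < 1:
            raise ValueError("min_instance_frames must be >= 1")
        if bridge_invalid_frames < 0:
            raise ValueError("bridge_invalid_frames must be >= 0")
        self.stream = stream
        self.dt = stream.frame_interval_s
        valid = stream.valid
        active = stream.hits & valid
        self.valid_cs = np.concatenate(([0], np.cumsum(valid)))

        a = active.astype(np.int8)
        d = np.diff(a)
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if a.size and a[0]:
            starts = np.concatenate(([0], starts))
        if a.size and a[-1]:
            ends = np.concatenate((ends, [a.size]))
        block_len = ends - starts

        if starts.size and bridge_invalid_frames > 0:
            gap_len = starts[1:] - ends[:-1]
            # gap bridged only when short enough and containing no valid frame
            gap_valid = self.valid_cs[starts[1:]] - self.valid_cs[ends[:-1]]
            merge = (gap_len <= bridge_invalid_frames) & (gap_valid == 0)
            block_run = np.concatenate(([0], np.cumsum(~merge)))
        else:
            block_run = np.arange(starts.size)

        n_runs = int(block_run[-1]) + 1 if starts.size else 0
        self.n_runs = n_runs
        if n_runs:
            first_block = np.searchsorted(block_run, np.arange(n_runs))
            self.onsets = starts[first_block]
            self.on_counts = np.bincount(block_run, weights=block_len).astype(
                np.int64
            )
        else:
            self.onsets = np.empty(0, dtype=np.int64)
            self.on_counts = np.empty(0, dtype=np.int64)
        self.retained = self.on_counts >= min_instance_frames

        # per-active-frame run labels, aligned with ascending frame position
        if starts.size:
            self.active_pos = np.flatnonzero(active)
            self.active_run = np.repeat(block_run, block_len)
        else:
            self.active_pos = np.empty(0, dtype=np.int64)
            self.active_run = np.empty(0, dtype=np.int64)

    # -- segment queries ---------------------------------------------------

    def _check_segment(self, segment: tuple[int, int] | None) -> tuple[int, int]:
        n = self.stream.n_frames
        if segment is None:
            return 0, n
        a, b = int(segment[0]), int(segment[1])
        if not (0 <= a < b <= n):
            raise BoundsError(
                f"segment [{a}, {b}) out of bounds or empty for stream of "
                f"{n} frames"
            )
        return a, b

    def segment_runs(self, segment: tuple[int, int] | None) -> list[GazeRun]:
        """Retained runs with onset inside the segment, right-truncated."""
        a, b = self._check_segment(segment)
        lo = np.searchsorted(self.active_pos, a)
        hi = np.searchsorted(self.active_pos, b)
        in_seg_counts = np.bincount(
            self.active_run[lo:hi], minlength=self.n_runs
        )
        rid_lo = np.searchsorted(self.onsets, a)
        rid_hi = np.searchsorted(self.onsets, b)
        runs = []
        for rid in range(rid_lo, rid_hi):
            if not self.retained[rid]:
                continue
            length = int(in_seg_counts[rid])
            if length == 0:  # onset inside but all its ON frames outside: impossible
                continue
            runs.append(
                GazeRun(
                    onset_frame=int(self.onsets[rid]),
                    length_frames=length,
                    duration_s=length * self.dt,
                )
            )
        return runs

    def segment_measures(self, segment: tuple[int, int] | None) -> GazeMeasures:
        a, b = self._check_segment(segment)
        n_valid = int(self.valid_cs[b] - self.valid_cs[a])
        if n_valid == 0:
            raise DegenerateSegmentError(
                f"segment [{a}, {b}) of stream "
                f"{self.stream.consultation_id!r} contains no valid frames"
            )
        minutes = n_valid * self.dt / 60.0

        lo = np.searchsorted(self.active_pos, a)
        hi = np.searchsorted(self.active_pos, b)
        if self.retained.all():
            on_frames = hi - lo
        else:
            on_frames = int(np.count_nonzero(self.retained[self.active_run[lo:hi]]))
        on_seconds = on_frames * self.dt

        rid_lo = np.searchsorted(self.onsets, a)
        rid_hi = np.searchsorted(self.onsets, b)
        n_instances = int(np.count_nonzero(self.retained[rid_lo:rid_hi]))

        return GazeMeasures(
            duration_per_min=on_seconds / minutes,
            frequency_per_min=n_instances / minutes,
            mean_dwell_s=on_seconds / n_instances if n_instances else math.nan,
            n_instances=n_instances,
            minutes=minutes,
        )


# ---------------------------------------------------------------------------
# public operations


def extract_runs(
    stream: GazeStream,
    segment: tuple[int, int] | None = None,
    boundary_policy: str = "truncate_onset",
    min_instance_frames: int = 1,
    bridge_invalid_frames: int = 0,
) -> list[GazeRun]:
    """Return the gaze instances of a stream segment.

    ``segment`` is a half-open frame interval ``(start, end)``; ``None``
    means the whole stream.  Under the (only) ``truncate_onset`` policy a run
    is attributed to the segment containing its onset and its duration is
    truncated at the segment's right edge.
    """
    if boundary_policy != "truncate_onset":
        raise ValueError(f"unknown boundary policy {boundary_policy!r}")
    idx = _RunIndex(stream, min_instance_frames, bridge_invalid_frames)
    return idx.segment_runs(segment)


def compute_measures(
    stream: GazeStream,
    segment: tuple[int, int] | None = None,
    min_instance_frames: int = 1,
    bridge_invalid_frames: int = 0,
) -> GazeMeasures:
    """Compute duration/min, frequency/min and mean dwell for a segment."""
    idx = _RunIndex(stream, min_instance_frames, bridge_invalid_frames)
    return idx.segment_measures(segment)


def _decile_frame_boundaries(stream: GazeStream) -> np.ndarray:
    """Frame-index boundaries of the 10 valid-frame deciles (length 11)."""
    n_valid = stream.n_valid
    if n_valid < N_DECILES:
        raise DegenerateStreamError(
            f"stream {stream.consultation_id!r} has {n_valid} valid frames; "
            f"at least {N_DECILES} are needed for a decile profile"
        )
    vpos = np.flatnonzero(stream.valid)
    ordinals = (np.arange(N_DECILES + 1) * n_valid) // N_DECILES
    bounds = np.empty(N_DECILES + 1, dtype=np.int64)
    bounds[:-1] = vpos[ordinals[:-1]]
    bounds[-1] = stream.n_frames
    return bounds


def decile_profile(
    stream: GazeStream,
    measure_name: str,
    min_instance_frames: int = 1,
    bridge_invalid_frames: int = 0,
) -> DecileProfile:
    """Profile one measure over the 10 deciles of a consultation's time.

    Deciles are contiguous bins of the valid-frame sequence, with boundaries
    at ``floor(d * N / 10)`` over valid-frame ordinal positions.
    """
    if measure_name not in MEASURE_NAMES:
        raise ValueError(f"unknown measure {measure_name!r}")
    idx = _RunIndex(stream, min_instance_frames, bridge_invalid_frames)
    bounds = _decile_frame_boundaries(stream)
    values = np.empty(N_DECILES)
    minutes = np.empty(N_DECILES)
    for d in range(N_DECILES):
        m = idx.segment_measures((int(bounds[d]), int(bounds[d + 1])))
        values[d] = m.value(measure_name)
        minutes[d] = m.minutes
    return DecileProfile(
        consultation_id=stream.consultation_id,
        measure_name=measure_name,
        values=values,
        bin_minutes=minutes,
    )


def decile_table(
    streams: Sequence[GazeStream] | GazeStream,
    min_instance_frames: int = 1,
    bridge_invalid_frames: int = 0,
) -> pd.DataFrame:
    """Tidy per-decile table of all three measures for one or many streams.

    Columns: consultation_id, decile (1–10), duration, frequency, dwell,
    minutes.
    """
    if isinstance(streams, GazeStream):
        streams = [streams]
    rows = []
    for stream in streams:
        idx = _RunIndex(stream, min_instance_frames, bridge_invalid_frames)
        bounds = _decile_frame_boundaries(stream)
        for d in range(N_DECILES):
            m = idx.segment_measures((int(bounds[d]), int(bounds[d + 1])))
            rows.append(
                {
                    "consultation_id": stream.consultation_id,
                    "decile": d + 1,
                    "duration": m.duration_per_min,
                    "frequency": m.frequency_per_min,
                    "dwell": m.mean_dwell_s,
                    "minutes": m.minutes,
                }
            )
    return pd.DataFrame(rows)


def measures_table(
    streams: Sequence[GazeStream],
    min_instance_frames: int = 1,
    bridge_invalid_frames: int = 0,
) -> pd.DataFrame:
    """Whole-consultation measures for a collection of streams."""
    rows = []
    for stream in streams:
        m = compute_measures(
            stream,
            min_instance_frames=min_instance_frames,
            bridge_invalid_frames=bridge_invalid_frames,
        )
        rows.append(
            {
                "consultation_id": stream.consultation_id,
                "physician_id": stream.physician_id,
                **m.as_dict(),
            }
        )
    return pd.DataFrame(rows)
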