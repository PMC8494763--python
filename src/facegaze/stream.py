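"""Frame-coded gaze streams.

A consultation is represented as a sequence of fixed-length video frames
(40 ms by default).  Each frame carries a binary face-gaze hit — the gaze
point fell inside the face area-of-interest (ON) or not (OFF) — plus a
validity flag.  Invalid frames (physical-examination gaps, tracker dropouts)
are removed from the time base entirely: they contribute to neither the
numerator nor the denominator of any rate, and they interrupt gaze runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import BoundsError, StreamValidationError

DEFAULT_FRAME_INTERVAL_S = 0.04

__all__ = ["GazeStream", "mask_gap", "DEFAULT_FRAME_INTERVAL_S"]


@dataclass
class GazeStream:
    """Binary face-gaze hit stream for one consultation.

    Parameters
    ----------
    consultation_id, physician_id
        Opaque identifiers linking the stream to cohort metadata.
    hits
        Boolean array, one element per frame; True = gaze on the face AOI.
    valid
        Boolean array of the same length; False = frame excluded from all
        measures (gap-masked or lost).
    frame_interval_s
        Seconds per frame; 0.04 s for 25 fps scene video.
    """

    consultation_id: str
    physician_id: str
    hits: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        hits = np.asarray(self.hits)
        if hits.ndim != 1 or hits.size == 0:
            raise StreamValidationError(
                f"stream {self.consultation_id!r}: hits must be a non-empty "
                f"1-d sequence, got shape {hits.shape}"
            )
        if hits.dtype != np.bool_:
            vals = np.unique(hits)
            if not np.isin(vals, (0, 1)).all():
                raise StreamValidationError(
                    f"stream {self.consultation_id!r}: hit values must be 0/1, "
                    f"found {vals[~np.isin(vals, (0, 1))][:5]!r}"
                )
            hits = hits.astype(bool)
        self.hits = hits

        if self.valid is None:
            valid = np.ones(hits.size, dtype=bool)
        else:
            valid = np.asarray(self.valid).astype(bool)
        if valid.shape != hits.shape:
            raise StreamValidationError(
                f"stream {self.consultation_id!r}: valid mask length "
                f"{valid.size} != hits length {hits.size}"
            )
        self.valid = valid

        if not (float(self.frame_interval_s) > 0):
            raise StreamValidationError(
                f"frame_interval_s must be positive, got {self.frame_interval_s}"
            )
        self.frame_interval_s = float(self.frame_interval_s)

    # -- basic bookkeeping -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(self.hits.size)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def minutes(self) -> float:
        """Analysed (valid) duration in minutes."""
        return self.n_valid * self.frame_interval_s / 60.0

    def __len__(self) -> int:
        return self.n_frames

    def copy(self) -> "GazeStream":
        return replace(self, hits=self.hits.copy(), valid=self.valid.copy())

    # -- gap masking -------------------------------------------------------

    def mask_gap(self, start_frame: int, end_frame: int) -> "GazeStream":
        """Return a copy with frames [start_frame, end_frame) marked invalid.

        Used to excise physical-examination gaps or data loss; masked frames
        leave both the numerator and the denominator of every rate.
        """
        if not (0 <= start_frame < end_frame <= self.n_frames):
            raise BoundsError(
                f"gap [{start_frame}, {end_frame}) out of bounds or empty for "
                f"stream of {self.n_frames} frames"
            )
        out = self.copy()
        out.valid[start_frame:end_frame] = False
        return out


def mask_gap(stream: GazeStream, start_frame: int, end_frame: int) -> GazeStream:
    """Functional form of :meth:`GazeStream.mask_gap`."""
    return stream.mask_gap(start_frame, end_frame)
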