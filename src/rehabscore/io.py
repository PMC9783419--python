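"""Readers and writers for the package's text interchange formats.

Recordings travel as CSV with a ``time_s`` column followed by one column
per channel; battery configurations, models and reports are JSON. Every
file the package writes can be read back by the package.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .recording import MotionRecording

__all__ = ["RecordingFormatError", "read_recording", "write_recording"]

TIME_COLUMN = "time_s"
_TIME_TOLERANCE_S = 1e-6
_FLOAT_FORMAT = "%.12g"  # 12 significant digits: round-trips cleanly


class RecordingFormatError(ValueError):
    """Raised when a recording CSV cannot be parsed."""


def write_recording(recording: MotionRecording, path: str | Path) -> None:
    """Write a recording to CSV (time_s column + one column per channel)."""
    frame = pd.DataFrame({TIME_COLUMN: recording.times, **recording.channels})
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_recording(
    path: str | Path,
    movement_id: str | None = None,
    side: str = "right",
    subject_id: str | None = None,
) -> MotionRecording:
    """Read a recording CSV, validating the uniform time base.

    The sampling rate is recovered from the (uniform) time step; a step
    deviating by more than 1 microsecond raises a format error naming the
    first offending row.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise RecordingFormatError(f"{path}: file is empty") from exc
    except (pd.errors.ParserError, ValueError) as exc:
        raise RecordingFormatError(f"{path}: {exc}") from exc
    if TIME_COLUMN not in frame.columns:
        raise RecordingFormatError(
            f"{path}: missing required {TIME_COLUMN!r} header column"
        )
    channels = [c for c in frame.columns if c != TIME_COLUMN]
    if not channels:
        raise RecordingFormatError(f"{path}: no channel columns")
    if len(frame) < 2:
        raise RecordingFormatError(f"{path}: need at least 2 samples")
    times = frame[TIME_COLUMN].to_numpy(dtype=float)
    steps = np.diff(times)
    dt = steps[0]
    if dt <= 0:
        raise RecordingFormatError(f"{path}: non-increasing time at row 2")
    bad = np.flatnonzero(np.abs(steps - dt) > _TIME_TOLERANCE_S)
    if bad.size:
        # +2: 1-based data rows after the header
        raise RecordingFormatError(
            f"{path}: non-uniform time step at row {int(bad[0]) + 2} "
            f"(step {steps[bad[0]]:.9f} s, expected {dt:.9f} s)"
        )
    return MotionRecording(
        movement_id=movement_id if movement_id is not None else path.stem,
        sampling_rate=1.0 / dt,
        channels={c: frame[c].to_numpy(dtype=float) for c in channels},
        side=side,
        subject_id=subject_id,
    )
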