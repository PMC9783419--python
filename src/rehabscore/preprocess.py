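"""Signal preprocessing: sliding filtering and effective-movement extraction.

Raw wearable recordings are smoothed with a centered moving-average filter
and the portions where the subject is actually moving ("effective movement
cycles") are extracted by thresholding the smoothed angular-speed magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import ANGULAR_VELOCITY, MotionRecording, channel_kind

__all__ = [
    "Segment",
    "moving_average_filter",
    "filter_channel",
    "extract_movement_cycles",
    "DEFAULT_FILTER_WINDOW",
]

# ~0.17 s at 30 Hz: short enough to keep movement morphology
DEFAULT_FILTER_WINDOW = 5


@dataclass(frozen=True)
class Segment:
    """Half-open sample range [start_index, end_index), 0-based."""

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_index < self.end_index):
            raise ValueError("segment requires 0 <= start < end")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    def duration(self, sampling_rate: float) -> float:
        return self.n_samples / sampling_rate


def filter_channel(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of a 1-D signal.

    Near the boundaries the window shrinks to the available samples (no
    zero padding), so constants are fixed points and edges are not
    attenuated. Length is preserved; the filter is linear.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd sample count")
    values = np.asarray(values, dtype=float)
    if window > values.size:
        raise ValueError("window exceeds signal length")
    if window == 1:
        return values.copy()
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


def moving_average_filter(
    recording: MotionRecording, window: int = DEFAULT_FILTER_WINDOW
) -> MotionRecording:
    """Apply the centered moving-average filter to every channel."""
    return recording.with_channels(
        {name: filter_channel(values, window) for name, values in recording}
    )


def _angular_speed(recording: MotionRecording) -> np.ndarray:
    vel = [
        values
        for name, values in recording
        if channel_kind(name) == ANGULAR_VELOCITY
    ]
    if not vel:
        raise ValueError(
            f"recording {recording.movement_id!r} has no angular-velocity channel"
        )
    return np.sqrt(np.sum(np.square(vel), axis=0))


def extract_movement_cycles(
    recording: MotionRecording,
    threshold_fraction: float = 0.1,
    min_duration: float = 0.5,
    merge_gap: float = 0.3,
    smooth_window: int = DEFAULT_FILTER_WINDOW,
) -> list[Segment]:
    """Find effective movement cycles from the angular-speed magnitude.

    The combined angular speed (Euclidean magnitude over all angular-velocity
    channels) is smoothed; samples where it strictly exceeds
    ``threshold_fraction * max`` are active. Active runs separated by gaps
    shorter than ``merge_gap`` seconds are merged, then runs shorter than
    ``min_duration`` seconds are dropped. Segments come back in time order
    and never overlap. A recording with no movement at all (flat zero
    angular speed) yields an empty list.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    speed = _angular_speed(recording)
    speed = filter_channel(speed, min(smooth_window, _largest_odd(speed.size)))
    peak = float(speed.max())
    if peak <= 0.0:
        return []
    active = speed > threshold_fraction * peak
    runs = _runs(active)
    rate = recording.sampling_rate
    max_gap = int(round(merge_gap * rate))
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] < max_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    min_samples = max(2, int(round(min_duration * rate)))
    return [
        Segment(start, end) for start, end in merged if end - start >= min_samples
    ]


def _largest_odd(n: int) -> int:
    return n if n % 2 == 1 else n - 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean vector."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))
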