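"""Container for a uniformly sampled multi-channel motion recording.

A recording is what one wearable sensor set produces for a single movement
attempt: joint angle (deg), angular velocity (deg/s), linear acceleration
(m/s^2) and, for hand tasks, per-finger flexion fractions, all sampled on a
shared uniform clock (30 Hz for the target hardware).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "MotionRecording",
    "channel_kind",
    "ANGLE",
    "ANGULAR_VELOCITY",
    "ACCELERATION",
    "FLEX",
]

# canonical channel-name prefixes; classification drives tremor/noise scaling
ANGLE = "angle"
ANGULAR_VELOCITY = "angular_velocity"
ACCELERATION = "acceleration"
FLEX = "flex"


def channel_kind(name: str) -> str:
    """Classify a channel name into angle / angular_velocity / acceleration / flex."""
    if name.startswith(ANGULAR_VELOCITY):
        return ANGULAR_VELOCITY
    if name.startswith(ANGLE):
        return ANGLE
    if name.startswith(ACCELERATION):
        return ACCELERATION
    if name.startswith(FLEX):
        return FLEX
    raise ValueError(f"unrecognised channel name {name!r}")


@dataclass
class MotionRecording:
    """One movement attempt: named channels on a shared uniform time base.

    Parameters
    ----------
    movement_id:
        Identifier of the assessment task this attempt belongs to.
    sampling_rate:
        Samples per second (Hz); must be positive.
    channels:
        Ordered mapping channel name -> 1-D sample vector. All vectors must
        have the same length (>= 2 samples).
    side:
        Which body side was instrumented ("left" or "right").
    subject_id:
        Optional subject identifier.
    """

    movement_id: str
    sampling_rate: float
    channels: dict[str, np.ndarray]
    side: str = "right"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channels:
            raise ValueError("recording must have at least one channel")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        clean: dict[str, np.ndarray] = {}
        n = None
        for name, values in self.channels.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"channel {name!r} must be 1-D")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError("all channels must have equal length")
            clean[name] = arr
        assert n is not None
        if n < 2:
            raise ValueError("channels must hold at least 2 samples")
        self.channels = clean

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        """Span of the time axis in seconds ((n-1) / rate)."""
        return (self.n_samples - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self.channels.items())

    def slice(self, start: int, end: int) -> "MotionRecording":
        """Return a new recording restricted to samples [start, end)."""
        if not (0 <= start < end <= self.n_samples):
            raise ValueError("invalid slice bounds")
        if end - start < 2:
            raise ValueError("slice must keep at least 2 samples")
        return replace(
            self, channels={k: v[start:end].copy() for k, v in self.channels.items()}
        )

    def with_channels(self, channels: Mapping[str, np.ndarray]) -> "MotionRecording":
        return replace(self, channels=dict(channels))

    def copy(self) -> "MotionRecording":
        return replace(self, channels={k: v.copy() for k, v in self.channels.items()})
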