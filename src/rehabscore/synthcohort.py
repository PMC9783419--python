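"""Synthetic cohort generation: templates, impaired recordings, FMA labels.

This module emulates the study conditions end-to-end so the scoring and
mapping pipeline can be exercised without any recorded patient data:

* movement *templates* — the clinician's standard execution of each task —
  are smooth raised-cosine joint excursions with analytically consistent
  angular-velocity and acceleration channels;
* patient recordings are templates degraded by a latent severity in [0, 1]
  (0 = healthy, 1 = no voluntary movement): amplitude attenuation, time
  dilation (impaired movements are slower), a tremor sinusoid and additive
  sensor noise;
* physician Fugl-Meyer item scores (33 upper-limb + 17 lower-limb motor
  items, each 0/1/2) come from a latent-trait model with rater noise;
* per-assessment durations are drawn from the reported system/physician
  timing distributions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .battery import BatteryConfig, default_battery
from .recording import (
    ACCELERATION,
    ANGLE,
    ANGULAR_VELOCITY,
    FLEX,
    MotionRecording,
    channel_kind,
)

__all__ = [
    "SeverityProfile",
    "CohortSample",
    "generate_template",
    "degrade_motion",
    "simulate_physician_fma",
    "generate_cohort",
    "N_UPPER_ITEMS",
    "N_LOWER_ITEMS",
]

N_UPPER_ITEMS = 33  # FMA upper-limb motor items (max 66)
N_LOWER_ITEMS = 17  # FMA lower-limb motor items (max 34)

DEFAULT_SAMPLING_RATE = 30.0  # Hz, wearable hardware rate

# Reported assessment durations (minutes). The system figure includes a
# fixed 1-minute preparation overhead (donning devices, opening software),
# so measurement-only draws use the mean minus that overhead.
SYSTEM_TIME_MEAN = 13.82
SYSTEM_TIME_SD = 6.61
PHYSICIAN_TIME_MEAN = 21.26
PHYSICIAN_TIME_SD = 7.79
PREPARATION_MIN = 1.0
MIN_DURATION_MIN = 3.0  # left-truncation of simulated durations

# acceleration lever arm (m): converts angular acceleration to the linear
# acceleration a distally mounted IMU would see
LEVER_ARM_RANGE = (0.20, 0.40)
AMPLITUDE_RANGE_DEG = (30.0, 90.0)
FLEX_RANGE = (0.5, 0.9)

# per-channel-kind scale applied to tremor and noise so the perturbation is
# commensurate with each channel's units (flex is a 0-1 fraction)
_UNIT_SCALE = {ANGLE: 1.0, ANGULAR_VELOCITY: 1.0, ACCELERATION: 0.1, FLEX: 0.01}


@dataclass(frozen=True)
class SeverityProfile:
    """How a latent impairment severity maps onto the sensor signals.

    severity: 0 = healthy, 1 = no voluntary movement.
    amplitude_attenuation: fraction of amplitude lost at full severity.
    speed_factor: time-dilation factor (>= 1; impaired movement is slower).
    tremor_amplitude: tremor sinusoid amplitude on angle channels (deg).
    tremor_frequency: tremor frequency (Hz).
    noise_sd: additive Gaussian sensor noise SD (angle-channel units).
    rater_sd: physician rater noise SD on the unit latent-function scale.
    """

    severity: float
    amplitude_attenuation: float = 0.8
    speed_factor: float = 1.0
    tremor_amplitude: float = 0.0
    tremor_frequency: float = 5.0
    noise_sd: float = 0.0
    rater_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.speed_factor < 1.0:
            raise ValueError("speed_factor must be >= 1")
        for name in ("tremor_amplitude", "noise_sd", "rater_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.amplitude_attenuation <= 1.0:
            raise ValueError("amplitude_attenuation must lie in [0, 1]")

    @classmethod
    def from_severity(
        cls,
        severity: float,
        amplitude_attenuation: float = 0.8,
        tremor_amplitude_max: float = 2.0,
        tremor_frequency: float = 5.0,
        noise_sd: float = 0.5,
        rater_sd: float = 0.1,
    ) -> "SeverityProfile":
        """Default severity->signal map.

        Dilation grows linearly to 2x and tremor to `tremor_amplitude_max`
        degrees at full severity, so a severity-0 profile with zero noise
        leaves a template untouched.
        """
        return cls(
            severity=severity,
            amplitude_attenuation=amplitude_attenuation,
            speed_factor=1.0 + severity,
            tremor_amplitude=tremor_amplitude_max * severity,
            tremor_frequency=tremor_frequency,
            noise_sd=noise_sd,
            rater_sd=rater_sd,
        )


@dataclass
class CohortSample:
    """One simulated subject: recordings, physician labels, durations."""

    subject_id: str
    recordings: dict[str, MotionRecording]
    fma_items_upper: np.ndarray
    fma_items_lower: np.ndarray
    physician_time: float  # minutes
    system_time: float  # minutes, measurement only (preparation excluded)
    true_severity: float

    def __post_init__(self) -> None:
        self.fma_items_upper = np.asarray(self.fma_items_upper, dtype=int)
        self.fma_items_lower = np.asarray(self.fma_items_lower, dtype=int)
        if self.fma_items_upper.size != N_UPPER_ITEMS:
            raise ValueError(f"expected {N_UPPER_ITEMS} upper-limb items")
        if self.fma_items_lower.size != N_LOWER_ITEMS:
            raise ValueError(f"expected {N_LOWER_ITEMS} lower-limb items")
        for items in (self.fma_items_upper, self.fma_items_lower):
            if not np.isin(items, (0, 1, 2)).all():
                raise ValueError("FMA items must be 0, 1 or 2")
        if self.physician_time <= 0 or self.system_time <= 0:
            raise ValueError("assessment times must be positive")
        if not 0.0 <= self.true_severity <= 1.0:
            raise ValueError("true_severity must lie in [0, 1]")

    @property
    def upper_total(self) -> int:
        return int(self.fma_items_upper.sum())

    @property
    def lower_total(self) -> int:
        return int(self.fma_items_lower.sum())

    @property
    def total(self) -> int:
        return self.upper_total + self.lower_total


def _movement_rng(movement_id: str, seed: int) -> np.random.Generator:
    # stable per-movement stream: same (movement_id, seed) -> same template
    return np.random.default_rng([seed, zlib.crc32(movement_id.encode())])


def generate_template(
    movement_id: str,
    duration: float = 4.0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    seed: int = 0,
    channels: tuple[str, ...] | None = None,
) -> MotionRecording:
    """Generate the clinician's standard execution of one movement task.

    The joint angle follows one raised-cosine cycle
    ``theta(t) = A/2 * (1 - cos(2 pi t / T))`` (starts and ends at rest),
    with the angular-velocity and acceleration channels its exact analytic
    derivatives; hand tasks add five raised-cosine finger-flexion channels.
    Deterministic given (movement_id, seed).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if channels is None:
        channels = ("angle_deg", "angular_velocity_dps", "acceleration_mps2")
    rng = _movement_rng(movement_id, seed)
    amplitude = rng.uniform(*AMPLITUDE_RANGE_DEG)
    lever = rng.uniform(*LEVER_ARM_RANGE)
    flex_amps = rng.uniform(*FLEX_RANGE, size=5)

    n = int(round(duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    omega = 2.0 * np.pi / duration  # rad/s of the movement cycle
    phase = omega * t

    out: dict[str, np.ndarray] = {}
    for name in channels:
        kind = channel_kind(name)
        if kind == ANGLE:
            out[name] = amplitude / 2.0 * (1.0 - np.cos(phase))
        elif kind == ANGULAR_VELOCITY:
            out[name] = amplitude / 2.0 * omega * np.sin(phase)
        elif kind == ACCELERATION:
            amp_rad = np.deg2rad(amplitude)
            out[name] = lever * amp_rad / 2.0 * omega**2 * np.cos(phase)
        elif kind == FLEX:
            idx = int(name.rsplit("_", 1)[1]) - 1
            out[name] = flex_amps[idx % 5] / 2.0 * (1.0 - np.cos(phase))
    return MotionRecording(
        movement_id=movement_id, sampling_rate=sampling_rate, channels=out
    )


def degrade_motion(
    template: MotionRecording, profile: SeverityProfile, seed: int = 0
) -> MotionRecording:
    """Degrade a template according to an impairment profile.

    Amplitude (about each channel's initial value) is scaled by
    ``1 - amplitude_attenuation * severity``; the time axis is dilated by
    ``speed_factor``; a tremor sinusoid and Gaussian sensor noise are added,
    each scaled to the channel's units. A severity-0 profile with unit
    speed_factor, zero tremor and zero noise returns the template unchanged.
    """
    if not template.channels:
        raise ValueError("template must be non-empty")
    rng = np.random.default_rng(seed)
    rate = template.sampling_rate
    n = template.n_samples
    amp_factor = 1.0 - profile.amplitude_attenuation * profile.severity

    dilation = profile.speed_factor
    if dilation == 1.0:
        t_new = template.times
        n_new = n
    else:
        n_new = int(round((n - 1) * dilation)) + 1
        t_new = np.arange(n_new) / rate
    t_template = template.times

    two_pi_f = 2.0 * np.pi * profile.tremor_frequency
    out: dict[str, np.ndarray] = {}
    for name, values in template:
        kind = channel_kind(name)
        base = values[0]
        if amp_factor == 1.0:  # keep the severity-0 identity bit-exact
            scaled = values
        else:
            scaled = base + amp_factor * (values - base)
        if dilation == 1.0:
            warped = scaled
        else:
            warped = np.interp(t_new / dilation, t_template, scaled)
            # a dilated movement is executed more slowly: rate channels
            # shrink by the dilation (velocity) or its square (acceleration)
            if kind == ANGULAR_VELOCITY:
                warped = warped / dilation
            elif kind == ACCELERATION:
                warped = warped / dilation**2
        unit = _UNIT_SCALE[kind]
        if profile.tremor_amplitude > 0:
            if kind == ANGULAR_VELOCITY:
                tremor = (
                    profile.tremor_amplitude * two_pi_f * np.cos(two_pi_f * t_new)
                )
            else:
                tremor = (
                    profile.tremor_amplitude * unit * np.sin(two_pi_f * t_new)
                )
            warped = warped + tremor
        if profile.noise_sd > 0:
            warped = warped + rng.normal(0.0, profile.noise_sd * unit, n_new)
        out[name] = warped
    return MotionRecording(
        movement_id=template.movement_id,
        sampling_rate=rate,
        channels=out,
        side=template.side,
        subject_id=template.subject_id,
    )


def simulate_physician_fma(
    severity: float, rater_sd: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a physician's per-item FMA motor scores.

    Each item's latent function is ``(1 - severity)`` plus Gaussian rater
    noise; the 0/1/2 item score is thresholded at 1/3 and 2/3 (equal
    a-priori bands on the unit latent scale). Returns (33 upper items,
    17 lower items).
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if rater_sd < 0:
        raise ValueError("rater_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = N_UPPER_ITEMS + N_LOWER_ITEMS
    latent = (1.0 - severity) + rng.normal(0.0, rater_sd, n)
    items = np.where(latent >= 2.0 / 3.0, 2, np.where(latent >= 1.0 / 3.0, 1, 0))
    return items[:N_UPPER_ITEMS], items[N_UPPER_ITEMS:]


def generate_cohort(
    n: int,
    seed: int = 0,
    config: BatteryConfig | None = None,
    noise_sd: float = 0.5,
    rater_sd: float = 0.1,
    template_seed: int | None = None,
) -> list[CohortSample]:
    """Generate a cohort of simulated subjects.

    Severities are uniform on [0, 1]; every subject performs each battery
    movement once (the shared templates are generated from
    ``template_seed``, defaulting to ``seed``); physician FMA items come
    from the latent-trait rater model; assessment durations come from the
    reported timing distributions, left-truncated at 3 minutes. Fully
    reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    config = config if config is not None else default_battery()
    if len(config) == 0:
        raise ValueError("battery must contain at least one movement")
    if template_seed is None:
        template_seed = seed
    templates = {
        m.movement_id: generate_template(
            m.movement_id,
            duration=m.duration_s,
            sampling_rate=DEFAULT_SAMPLING_RATE,
            seed=template_seed,
            channels=m.channels,
        )
        for m in config
    }
    rng = np.random.default_rng(seed)
    samples: list[CohortSample] = []
    for k in range(n):
        severity = float(rng.uniform())
        profile = SeverityProfile.from_severity(
            severity, noise_sd=noise_sd, rater_sd=rater_sd
        )
        recordings = {
            mid: degrade_motion(tpl, profile, seed=int(rng.integers(2**31)))
            for mid, tpl in templates.items()
        }
        upper, lower = simulate_physician_fma(
            severity, rater_sd=rater_sd, seed=int(rng.integers(2**31))
        )
        system_time = max(
            MIN_DURATION_MIN,
            float(rng.normal(SYSTEM_TIME_MEAN - PREPARATION_MIN, SYSTEM_TIME_SD)),
        )
        physician_time = max(
            MIN_DURATION_MIN,
            float(rng.normal(PHYSICIAN_TIME_MEAN, PHYSICIAN_TIME_SD)),
        )
        samples.append(
            CohortSample(
                subject_id=f"S{k + 1:03d}",
                recordings=recordings,
                fma_items_upper=upper,
                fma_items_lower=lower,
                physician_time=physician_time,
                system_time=system_time,
                true_severity=severity,
            )
        )
    return samples
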