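"""Movement-battery configuration.

The assessment battery is the ordered list of movement tasks a subject
performs; the default battery holds 32 tasks (20 upper-limb, 12 lower-limb)
spanning flexor/extensor synergies, isolated joint movements, wrist
stability, finger function and coordination items, mirroring the structure
of the Fugl-Meyer motor sections. Finger tasks carry five glove flex
channels in addition to the IMU channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["MovementSpec", "BatteryConfig", "default_battery"]

BATTERY_FORMAT_VERSION = "1"

IMU_CHANNELS = ["angle_deg", "angular_velocity_dps", "acceleration_mps2"]
FLEX_CHANNELS = [f"flex_{i}" for i in range(1, 6)]


@dataclass(frozen=True)
class MovementSpec:
    movement_id: str
    limb: str  # "upper" | "lower"
    channels: tuple[str, ...]
    duration_s: float

    def __post_init__(self) -> None:
        if self.limb not in ("upper", "lower"):
            raise ValueError(f"limb must be 'upper' or 'lower', got {self.limb!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not self.channels:
            raise ValueError("movement must define at least one channel")


@dataclass
class BatteryConfig:
    """Ordered battery of assessment movements."""

    movements: list[MovementSpec]
    version: str = BATTERY_FORMAT_VERSION

    def __post_init__(self) -> None:
        ids = [m.movement_id for m in self.movements]
        if len(ids) != len(set(ids)):
            raise ValueError("movement_ids must be unique")
        if not self.movements:
            raise ValueError("battery must contain at least one movement")

    def __len__(self) -> int:
        return len(self.movements)

    def __iter__(self):
        return iter(self.movements)

    @property
    def movement_ids(self) -> list[str]:
        return [m.movement_id for m in self.movements]

    def limb_indices(self, limb: str) -> list[int]:
        """Positions (battery order) of the movements tagged with `limb`."""
        if limb not in ("upper", "lower"):
            raise ValueError("limb must be 'upper' or 'lower'")
        return [i for i, m in enumerate(self.movements) if m.limb == limb]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "movements": [
                {
                    "movement_id": m.movement_id,
                    "limb": m.limb,
                    "channels": list(m.channels),
                    "duration_s": m.duration_s,
                }
                for m in self.movements
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BatteryConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed battery file {path}: {exc}") from exc
        version = payload.get("version")
        if version != BATTERY_FORMAT_VERSION:
            raise ValueError(f"unsupported battery file version {version!r}")
        movements = [
            MovementSpec(
                movement_id=m["movement_id"],
                limb=m["limb"],
                channels=tuple(m["channels"]),
                duration_s=float(m["duration_s"]),
            )
            for m in payload["movements"]
        ]
        return cls(movements=movements, version=version)


def _imu(movement_id: str, limb: str, duration_s: float) -> MovementSpec:
    return MovementSpec(movement_id, limb, tuple(IMU_CHANNELS), duration_s)


def _hand(movement_id: str, duration_s: float) -> MovementSpec:
    return MovementSpec(
        movement_id, "upper", tuple(IMU_CHANNELS + FLEX_CHANNELS), duration_s
    )


def default_battery() -> BatteryConfig:
    """The 32-task default battery: 20 upper-limb and 12 lower-limb movements."""
    upper = [
        # flexor-synergy joint movements
        _imu("u01_shoulder_flexion", "upper", 4.0),
        _imu("u02_shoulder_abduction", "upper", 4.0),
        _imu("u03_shoulder_external_rotation", "upper", 3.5),
        _imu("u04_elbow_flexion", "upper", 3.0),
        _imu("u05_forearm_supination", "upper", 3.0),
        _imu("u06_shoulder_shrug", "upper", 3.0),
        # extensor-synergy joint movements
        _imu("u07_elbow_extension", "upper", 3.0),
        _imu("u08_shoulder_adduction", "upper", 4.0),
        _imu("u09_forearm_pronation", "upper", 3.0),
        # mixed-synergy joint movements
        _imu("u10_hand_to_lumbar_spine", "upper", 4.0),
        _imu("u11_shoulder_flexion_90", "upper", 4.0),
        _imu("u12_pronation_supination_elbow_90", "upper", 3.5),
        # out-of-synergy movements
        _imu("u13_shoulder_abduction_90", "upper", 4.0),
        _imu("u14_shoulder_flexion_180", "upper", 4.5),
        # wrist stability
        _imu("u15_wrist_flexion_extension", "upper", 3.0),
        # finger function (glove flex channels)
        _hand("u16_finger_mass_flexion", 3.0),
        _hand("u17_finger_mass_extension", 3.0),
        _hand("u18_hook_grasp", 3.5),
        _hand("u19_lateral_pinch", 3.0),
        _hand("u20_cylinder_grip", 3.5),
    ]
    lower = [
        # flexor-synergy joint movements
        _imu("l01_hip_flexion", "lower", 4.0),
        _imu("l02_knee_flexion", "lower", 3.5),
        _imu("l03_ankle_dorsiflexion", "lower", 3.0),
        # extensor-synergy joint movements
        _imu("l04_hip_extension", "lower", 4.0),
        _imu("l05_knee_extension", "lower", 3.5),
        _imu("l06_ankle_plantarflexion", "lower", 3.0),
        _imu("l07_hip_adduction", "lower", 3.5),
        # mixed-synergy joint movements
        _imu("l08_knee_flexion_sitting", "lower", 3.5),
        _imu("l09_ankle_dorsiflexion_sitting", "lower", 3.0),
        # out-of-synergy movements
        _imu("l10_knee_flexion_standing", "lower", 4.0),
        _imu("l11_hip_abduction_standing", "lower", 4.0),
        # coordination / speed
        _imu("l12_heel_to_shin", "lower", 4.5),
    ]
    return BatteryConfig(movements=upper + lower)
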