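"""Movement scoring: per-feature DTW distances fused by entropy weights.

For each movement task a *template* holds the clinician's reference
recording, the per-feature "no movement" distance X_max (DTW between the
reference channel and a constant sequence pinned at its starting value) and
a weight vector delta obtained by the entropy weight method. A patient
attempt is scored per feature by the DTW distance X_i to the reference
channel, normalized to [0, 1] by X_i / X_max (X_min = 0 by construction,
clipped at 1), and fused into

    deviation_score = 100 * sum_i delta_i * clip(X_i / X_max_i, 0, 1)

so 0 means a perfect reproduction of the template and 100 means no movement
at all. Because higher Fugl-Meyer totals mean better function, the
complement ``quality_score = 100 - deviation_score`` is the movement score
fed to the mapping model; both orientations are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .battery import BatteryConfig, default_battery
from .dtw import dtw_distance
from .preprocess import extract_movement_cycles, moving_average_filter
from .recording import MotionRecording
from .synthcohort import CohortSample, generate_template

__all__ = [
    "MovementTemplate",
    "MovementScore",
    "entropy_weights",
    "compute_x_max",
    "build_template",
    "build_battery_templates",
    "feature_distances",
    "score_from_distances",
    "score_movement",
    "calibrate_weights",
    "score_cohort",
]


@dataclass
class MovementTemplate:
    """Reference recording plus per-feature X_max and entropy weights."""

    movement_id: str
    reference: MotionRecording
    feature_list: list[str]
    x_max: np.ndarray  # per-feature no-movement DTW distance, > 0
    weights: np.ndarray  # delta_i, non-negative, sums to 1

    def __post_init__(self) -> None:
        self.x_max = np.asarray(self.x_max, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        m = len(self.feature_list)
        if self.x_max.shape != (m,) or self.weights.shape != (m,):
            raise ValueError("x_max and weights must align with feature_list")
        if not (self.x_max > 0).all():
            raise ValueError("every feature must have x_max > 0")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        missing = [f for f in self.feature_list if f not in self.reference.channels]
        if missing:
            raise ValueError(f"reference lacks feature channels {missing}")


@dataclass(frozen=True)
class MovementScore:
    """Per-feature DTW distances and the fused 0-100 scores."""

    movement_id: str
    feature_distances: np.ndarray
    normalized_deviations: np.ndarray
    deviation_score: float  # 100 = no movement at all
    quality_score: float  # 100 = perfect template reproduction

    def __post_init__(self) -> None:
        if not (0.0 <= self.deviation_score <= 100.0):
            raise ValueError("deviation_score must lie in [0, 100]")
        if abs(self.deviation_score + self.quality_score - 100.0) > 1e-9:
            raise ValueError("scores must be complementary")


def entropy_weights(calibration_matrix) -> np.ndarray:
    """Entropy-weight-method feature weights from a calibration matrix.

    Rows are samples (n >= 2), columns are features with non-negative
    entries (here: normalized DTW deviations). Column shares
    p_ij = x_ij / sum_i x_ij (uniform for an all-zero column) give the
    normalized Shannon entropy e_j = -(1/ln n) sum_i p_ij ln p_ij
    (0 ln 0 := 0); weights are the normalized divergences
    delta_j = (1 - e_j) / sum_k (1 - e_k). If every column has e_j = 1
    (no feature carries information) the weights are uniform.
    """
    X = np.asarray(calibration_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("calibration matrix must be 2-D")
    n, m = X.shape
    if n < 2:
        raise ValueError("entropy weights need at least 2 samples")
    if m < 1:
        raise ValueError("entropy weights need at least 1 feature")
    if (X < 0).any() or not np.isfinite(X).all():
        raise ValueError("entries must be finite and non-negative")
    sums = X.sum(axis=0)
    P = np.where(sums > 0, X / np.where(sums > 0, sums, 1.0), 1.0 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    divergence = 1.0 - e
    divergence = np.clip(divergence, 0.0, None)  # guard tiny negative rounding
    total = divergence.sum()
    if total <= 1e-12:
        return np.full(m, 1.0 / m)
    return divergence / total


def compute_x_max(reference_channel) -> float:
    """DTW distance between a reference channel and total absence of movement.

    "No movement at all" is a constant sequence of the same length pinned at
    the channel's initial value.
    """
    ref = np.asarray(reference_channel, dtype=float)
    if ref.size == 0:
        raise ValueError("reference channel must be non-empty")
    still = np.full_like(ref, ref[0])
    return dtw_distance(ref, still).distance


def build_template(
    movement_id: str,
    duration: float = 4.0,
    sampling_rate: float = 30.0,
    seed: int = 0,
    channels: tuple[str, ...] | None = None,
    preprocess: bool = True,
) -> MovementTemplate:
    """Build a movement template with uniform (uncalibrated) weights.

    The stored reference is the clinician recording put through the same
    preprocessing as patient data (moving-average filter + effective-cycle
    extraction), so an attempt identical to the clinician's scores exactly
    0 deviation.
    """
    reference = generate_template(
        movement_id,
        duration=duration,
        sampling_rate=sampling_rate,
        seed=seed,
        channels=channels,
    )
    if preprocess:
        reference = moving_average_filter(reference)
        segments = extract_movement_cycles(reference)
        if segments:
            reference = reference.slice(segments[0].start_index, segments[0].end_index)
    features = reference.channel_names
    x_max = np.array([compute_x_max(reference.channels[f]) for f in features])
    weights = np.full(len(features), 1.0 / len(features))
    return MovementTemplate(
        movement_id=movement_id,
        reference=reference,
        feature_list=features,
        x_max=x_max,
        weights=weights,
    )


def build_battery_templates(
    config: BatteryConfig | None = None, seed: int = 0, sampling_rate: float = 30.0
) -> dict[str, MovementTemplate]:
    """One template per battery movement, keyed by movement_id."""
    config = config if config is not None else default_battery()
    return {
        m.movement_id: build_template(
            m.movement_id,
            duration=m.duration_s,
            sampling_rate=sampling_rate,
            seed=seed,
            channels=m.channels,
        )
        for m in config
    }


def feature_distances(
    recording: MotionRecording,
    template: MovementTemplate,
    preprocess: bool = True,
    filter_window: int = 5,
) -> np.ndarray:
    """Per-feature DTW distances between an attempt and the template.

    The recording is smoothed and its effective movement cycles extracted;
    each feature's distance is the DTW distance between the cycle's channel
    and the reference channel. With several cycles (repeated attempts) the
    per-feature median distance is used — robust to one aborted repetition;
    with none (no effective movement) the whole recording is compared.
    """
    missing = [f for f in template.feature_list if f not in recording.channels]
    if missing:
        raise ValueError(f"recording lacks feature channels {missing}")
    if preprocess:
        recording = moving_average_filter(recording, filter_window)
        segments = extract_movement_cycles(recording)
    else:
        segments = []
    if not segments:
        parts = [recording]
    else:
        parts = [recording.slice(s.start_index, s.end_index) for s in segments]
    dist = np.empty((len(parts), len(template.feature_list)))
    for p, part in enumerate(parts):
        for f, feature in enumerate(template.feature_list):
            dist[p, f] = dtw_distance(
                part.channels[feature], template.reference.channels[feature]
            ).distance
    return np.median(dist, axis=0)


def score_from_distances(
    distances: np.ndarray, template: MovementTemplate
) -> MovementScore:
    """Fuse per-feature DTW distances into the 0-100 movement scores."""
    distances = np.asarray(distances, dtype=float)
    if distances.shape != template.x_max.shape:
        raise ValueError("distances must align with the template features")
    normalized = np.clip(distances / template.x_max, 0.0, 1.0)
    deviation = float(100.0 * np.dot(template.weights, normalized))
    deviation = min(max(deviation, 0.0), 100.0)
    return MovementScore(
        movement_id=template.movement_id,
        feature_distances=distances,
        normalized_deviations=normalized,
        deviation_score=deviation,
        quality_score=100.0 - deviation,
    )


def score_movement(
    recording: MotionRecording,
    template: MovementTemplate,
    preprocess: bool = True,
) -> MovementScore:
    """Score one movement attempt against its template."""
    return score_from_distances(
        feature_distances(recording, template, preprocess=preprocess), template
    )


def calibrate_weights(
    template: MovementTemplate, distance_rows: np.ndarray
) -> MovementTemplate:
    """Refit a template's entropy weights from cohort distances.

    ``distance_rows`` is (n subjects, n features) of raw DTW distances for
    this movement; they are normalized by the template's X_max before the
    entropy calculation.
    """
    rows = np.asarray(distance_rows, dtype=float)
    normalized = np.clip(rows / template.x_max, 0.0, 1.0)
    return replace(template, weights=entropy_weights(normalized))


def score_cohort(
    samples: list[CohortSample],
    templates: dict[str, MovementTemplate],
    calibrate: bool = True,
) -> tuple[pd.DataFrame, dict[str, MovementTemplate]]:
    """Score every subject on every movement, optionally calibrating weights.

    Distances are computed once per (subject, movement, feature); if
    ``calibrate`` is set, each movement's entropy weights are fitted on the
    cohort's normalized-deviation matrix before the scores are formed.

    Returns
    -------
    (scores, templates)
        ``scores`` is a DataFrame of quality scores (rows = subjects in
        cohort order, columns = movement_ids in template order);
        ``templates`` are the (possibly recalibrated) templates.
    """
    if not samples:
        raise ValueError("cohort must be non-empty")
    distances = {
        mid: np.stack(
            [
                feature_distances(sample.recordings[mid], tpl)
                for sample in samples
            ]
        )
        for mid, tpl in templates.items()
    }
    if calibrate and len(samples) >= 2:
        templates = {
            mid: calibrate_weights(tpl, distances[mid])
            for mid, tpl in templates.items()
        }
    scores = pd.DataFrame(
        {
            mid: [
                score_from_distances(distances[mid][i], templates[mid]).quality_score
                for i in range(len(samples))
            ]
            for mid in templates
        },
        index=[s.subject_id for s in samples],
    )
    return scores, templates
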