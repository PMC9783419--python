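"""Mapping movement scores to Fugl-Meyer totals with support vector regression.

A movement-score 0/1/2 FMA item correspondence would be far too coarse, so
the 32 per-movement quality scores are mapped to aggregate FMA totals by an
RBF-kernel support vector regression trained against the physician's
labels. Three independent models are fitted: total (0-100, all movements),
upper-limb (0-66, upper-limb movements only) and lower-limb (0-34,
lower-limb movements only). Hyperparameters come from a seeded 5-fold
cross-validated grid search over a small fixed grid, keeping training
deterministic.

Models persist as transparent JSON (scaler parameters, kernel parameters,
support vectors and dual coefficients); prediction is computed in-package
from the RBF kernel expansion, so a saved model round-trips exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .battery import BatteryConfig, default_battery
from .synthcohort import CohortSample

__all__ = [
    "AssessmentRecord",
    "FmaMappingModel",
    "ModelFormatError",
    "records_from_cohort",
    "train_mapping",
    "predict_fma",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = "1"

OUTPUT_RANGES = {"total": (0.0, 100.0), "upper": (0.0, 66.0), "lower": (0.0, 34.0)}

# fixed hyperparameter grid; gamma is expressed as multiples of the scale
# heuristic 1/(n_features * var) computed on the standardized features
C_GRID = (1.0, 10.0, 100.0)
GAMMA_FACTORS = (0.1, 1.0, 10.0)
EPSILON_GRID = (0.5, 1.0, 2.0)  # FMA points


class ModelFormatError(ValueError):
    """Raised when a persisted model file cannot be parsed."""


@dataclass
class AssessmentRecord:
    """One subject's movement scores plus optional labels and predictions."""

    subject_id: str
    movement_scores: np.ndarray  # quality scores, battery order
    physician_upper: float | None = None
    physician_lower: float | None = None
    physician_total: float | None = None
    system_upper: float | None = None
    system_lower: float | None = None
    system_total: float | None = None

    def __post_init__(self) -> None:
        self.movement_scores = np.asarray(self.movement_scores, dtype=float)
        if self.movement_scores.ndim != 1:
            raise ValueError("movement_scores must be a vector")
        labels = (self.physician_upper, self.physician_lower, self.physician_total)
        ranges = (66.0, 34.0, 100.0)
        for value, hi in zip(labels, ranges):
            if value is not None and not (0.0 <= value <= hi):
                raise ValueError(f"label {value} outside [0, {hi}]")
        if all(v is not None for v in labels):
            if abs(self.physician_total - self.physician_upper - self.physician_lower) > 1e-9:
                raise ValueError("physician_total must equal upper + lower")

    def label(self, target: str) -> float | None:
        return getattr(self, f"physician_{target}")


def records_from_cohort(
    samples: list[CohortSample],
    scores: pd.DataFrame,
    config: BatteryConfig | None = None,
) -> list[AssessmentRecord]:
    """Assemble labeled assessment records from a scored cohort."""
    config = config if config is not None else default_battery()
    order = config.movement_ids
    records = []
    for sample in samples:
        row = scores.loc[sample.subject_id, order].to_numpy(dtype=float)
        records.append(
            AssessmentRecord(
                subject_id=sample.subject_id,
                movement_scores=row,
                physician_upper=float(sample.upper_total),
                physician_lower=float(sample.lower_total),
                physician_total=float(sample.total),
            )
        )
    return records


@dataclass
class FmaMappingModel:
    """A trained scores -> FMA-total regression, serializable to JSON."""

    target: str  # total | upper | lower
    feature_indices: list[int]  # battery positions used as inputs
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    gamma: float
    C: float
    epsilon: float
    support_vectors: np.ndarray  # (n_sv, d), standardized feature space
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float
    output_range: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scaler_mean = np.asarray(self.scaler_mean, dtype=float)
        self.scaler_scale = np.asarray(self.scaler_scale, dtype=float)
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coef = np.asarray(self.dual_coef, dtype=float)

    @property
    def n_features(self) -> int:
        return len(self.feature_indices)

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Raw (unclamped) SVR output for rows of battery-order scores."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] == self.n_features:
            sub = X
        else:
            sub = X[:, self.feature_indices]
        Z = (sub - self.scaler_mean) / self.scaler_scale
        if self.support_vectors.size == 0:
            return np.full(Z.shape[0], self.intercept)
        sq = (
            np.sum(Z**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.clip(sq, 0.0, None))
        return K @ self.dual_coef + self.intercept


def _feature_indices(target: str, config: BatteryConfig) -> list[int]:
    if target == "total":
        return list(range(len(config)))
    return config.limb_indices(target)


def train_mapping(
    records: list[AssessmentRecord],
    target: str = "total",
    seed: int = 0,
    config: BatteryConfig | None = None,
) -> FmaMappingModel:
    """Train the SVR mapping for one target (total, upper or lower).

    Requires >= 10 labeled records. Features are standardized; C, gamma and
    epsilon are selected by 5-fold cross-validated grid search with a
    seeded, shuffled fold split, so training is deterministic given
    (records, seed).
    """
    if target not in OUTPUT_RANGES:
        raise ValueError("target must be 'total', 'upper' or 'lower'")
    config = config if config is not None else default_battery()
    labeled = [r for r in records if r.label(target) is not None]
    if len(labeled) < 10:
        raise ValueError(
            f"need at least 10 labeled records, got {len(labeled)}"
        )
    indices = _feature_indices(target, config)
    X = np.stack([r.movement_scores[indices] for r in labeled])
    y = np.array([r.label(target) for r in labeled], dtype=float)

    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    metadata = {"n": len(labeled), "seed": seed}

    if np.ptp(y) == 0.0:
        warnings.warn(
            f"constant {target} labels; model will predict {y[0]:.2f}",
            stacklevel=2,
        )
        model = FmaMappingModel(
            target=target,
            feature_indices=indices,
            feature_names=[config.movement_ids[i] for i in indices],
            scaler_mean=scaler.mean_,
            scaler_scale=scaler.scale_,
            gamma=1.0 / len(indices),
            C=1.0,
            epsilon=EPSILON_GRID[0],
            support_vectors=np.empty((0, len(indices))),
            dual_coef=np.empty(0),
            intercept=float(y[0]),
            output_range=OUTPUT_RANGES[target],
            metadata={**metadata, "cv_score": 1.0, "constant_label": True},
        )
        return model

    var = Z.var()
    gamma_scale = 1.0 / (Z.shape[1] * var) if var > 0 else 1.0 / Z.shape[1]
    grid = {
        "C": list(C_GRID),
        "gamma": [f * gamma_scale for f in GAMMA_FACTORS],
        "epsilon": list(EPSILON_GRID),
    }
    cv = KFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(SVR(kernel="rbf"), grid, cv=cv, scoring="r2", n_jobs=1)
    search.fit(Z, y)
    best: SVR = search.best_estimator_
    return FmaMappingModel(
        target=target,
        feature_indices=indices,
        feature_names=[config.movement_ids[i] for i in indices],
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
        gamma=float(best.gamma),
        C=float(best.C),
        epsilon=float(best.epsilon),
        support_vectors=best.support_vectors_,
        dual_coef=best.dual_coef_.ravel(),
        intercept=float(best.intercept_.ravel()[0]),
        output_range=OUTPUT_RANGES[target],
        metadata={**metadata, "cv_score": float(search.best_score_)},
    )


def predict_fma(model: FmaMappingModel, record: AssessmentRecord | np.ndarray) -> float:
    """Predict one FMA target score, clamped to the model's output range."""
    if isinstance(record, AssessmentRecord):
        scores = record.movement_scores
        max_index = max(model.feature_indices)
        if scores.size <= max_index:
            raise ValueError(
                f"record has {scores.size} movement scores; model needs "
                f"index {max_index}"
            )
    else:
        scores = np.asarray(record, dtype=float)
    raw = float(model.decision(scores)[0])
    lo, hi = model.output_range
    return float(min(max(raw, lo), hi))


def save_model(model: FmaMappingModel, path: str | Path) -> None:
    """Persist a model as versioned, human-readable JSON."""
    payload = {
        "version": MODEL_FORMAT_VERSION,
        "target": model.target,
        "feature_indices": model.feature_indices,
        "feature_names": model.feature_names,
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "gamma": model.gamma,
        "C": model.C,
        "epsilon": model.epsilon,
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "output_range": list(model.output_range),
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> FmaMappingModel:
    """Load a persisted model; predictions round-trip within 1e-9."""
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(
            f"malformed model file {path}: line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}"
        ) from exc
    version = payload.get("version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model file version {version!r} (expected "
            f"{MODEL_FORMAT_VERSION!r})"
        )
    try:
        return FmaMappingModel(
            target=payload["target"],
            feature_indices=list(payload["feature_indices"]),
            feature_names=list(payload["feature_names"]),
            scaler_mean=np.array(payload["scaler_mean"]),
            scaler_scale=np.array(payload["scaler_scale"]),
            gamma=float(payload["gamma"]),
            C=float(payload["C"]),
            epsilon=float(payload["epsilon"]),
            support_vectors=np.array(payload["support_vectors"], dtype=float).reshape(
                len(payload["dual_coef"]) or 0, len(payload["feature_indices"])
            ),
            dual_coef=np.array(payload["dual_coef"], dtype=float),
            intercept=float(payload["intercept"]),
            output_range=tuple(payload["output_range"]),
            metadata=dict(payload.get("metadata", {})),
        )
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"model file {path} missing field: {exc}") from exc
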