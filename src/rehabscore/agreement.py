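"""Method-agreement statistics between system scores and physician scores.

Implements the evaluation protocol used to compare the wearable system with
the clinician's Fugl-Meyer assessment:

* calibration regression — OLS of the system score (y) on the physician
  score (x): intercept, slope, 95% CI of the slope (t distribution), R^2,
  two-sided p for slope != 0;
* Bland-Altman analysis of deviations (physician - system) and relative
  deviations (100 * deviation / physician, subjects with a zero physician
  score excluded and counted), with limits of agreement at
  mean +/- 1.96 * SD and inclusive within-limit counting;
* assessment-time comparison by Student's (pooled) two-sample t test, with
  a fixed preparation-time offset added to the system group (Welch and
  paired variants available).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "LIMIT_MULTIPLIER",
    "AgreementReport",
    "calibration_regression",
    "bland_altman",
    "time_comparison",
    "build_report",
]

LIMIT_MULTIPLIER = 1.96  # mean +/- 1.96 SD: the 95% limits of agreement


def _pair(physician, system, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(physician, dtype=float)
    s = np.asarray(system, dtype=float)
    if p.shape != s.shape or p.ndim != 1:
        raise ValueError("physician and system vectors must be equal-length 1-D")
    if p.size < min_n:
        raise ValueError(f"need at least {min_n} paired observations")
    return p, s


def calibration_regression(physician, system) -> dict:
    """OLS of system score on physician score with slope CI, R^2 and p."""
    p, s = _pair(physician, system, 3)
    if np.ptp(p) == 0.0:
        raise ValueError("physician scores are constant; regression is degenerate")
    fit = stats.linregress(p, s)
    n = p.size
    tcrit = stats.t.ppf(0.975, n - 2)
    return {
        "intercept": float(fit.intercept),
        "slope": float(fit.slope),
        "slope_ci_95": [
            float(fit.slope - tcrit * fit.stderr),
            float(fit.slope + tcrit * fit.stderr),
        ],
        "r_squared": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
        "n": int(n),
    }


def _deviation_block(values: np.ndarray) -> dict:
    n = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    tcrit = stats.t.ppf(0.975, n - 1) if n > 1 else np.nan
    half = tcrit * sd / np.sqrt(n) if n > 1 else 0.0
    lower = mean - LIMIT_MULTIPLIER * sd
    upper = mean + LIMIT_MULTIPLIER * sd
    within = int(np.sum((values >= lower) & (values <= upper)))  # inclusive
    return {
        "mean": mean,
        "sd": sd,
        "mean_ci_95": [float(mean - half), float(mean + half)],
        "limits": [float(lower), float(upper)],
        "within_limit_count": within,
        "outside_limit_count": int(n - within),
        "within_limit_percent": float(100.0 * within / n),
        "n": int(n),
    }


def bland_altman(physician, system) -> dict:
    """Deviation and relative-deviation agreement blocks.

    deviation_k = physician_k - system_k; relative deviation (%) is
    100 * deviation_k / physician_k with zero-physician records excluded
    from the relative statistics (their count is reported).
    """
    p, s = _pair(physician, system, 3)
    dev = p - s
    block = {"deviation": _deviation_block(dev)}
    nonzero = p != 0.0
    excluded = int(np.sum(~nonzero))
    if nonzero.sum() == 0:
        block["relative_deviation"] = {
            "available": False,
            "excluded_zero_count": excluded,
        }
    else:
        rel = 100.0 * dev[nonzero] / p[nonzero]
        rel_block = _deviation_block(rel)
        rel_block["available"] = True
        rel_block["excluded_zero_count"] = excluded
        block["relative_deviation"] = rel_block
    return block


def time_comparison(
    system_times,
    physician_times,
    preparation_min: float = 1.0,
    pooled: bool = True,
    paired: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Compare assessment durations (minutes) between system and physician.

    ``preparation_min`` (default 1 min: donning the devices and opening the
    software) is added to the system group before testing. Student's pooled
    two-sample t test by default; Welch via ``pooled=False``, paired via
    ``paired=True``.
    """
    sys_t = np.asarray(system_times, dtype=float) + preparation_min
    phy_t = np.asarray(physician_times, dtype=float)
    if sys_t.size < 2 or phy_t.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired:
        if sys_t.size != phy_t.size:
            raise ValueError("paired comparison needs equal group sizes")
        result = stats.ttest_rel(sys_t, phy_t)
    else:
        result = stats.ttest_ind(sys_t, phy_t, equal_var=pooled)
    return {
        "system_mean": float(sys_t.mean()),
        "system_sd": float(sys_t.std(ddof=1)),
        "physician_mean": float(phy_t.mean()),
        "physician_sd": float(phy_t.std(ddof=1)),
        "preparation_min": float(preparation_min),
        "t_statistic": float(result.statistic),
        "p_value": float(result.pvalue),
        "significant": bool(result.pvalue < alpha),
        "n_system": int(sys_t.size),
        "n_physician": int(phy_t.size),
    }


_TARGETS = ("total", "upper", "lower")


@dataclass
class AgreementReport:
    """Full agreement analysis for total, upper-limb and lower-limb scores."""

    regression: dict
    deviations: dict
    timing: dict | None
    n: int

    def to_dict(self) -> dict:
        return {
            "regression": self.regression,
            "deviations": self.deviations,
            "timing": self.timing,
            "n": self.n,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "AgreementReport":
        return cls(
            regression=payload["regression"],
            deviations=payload["deviations"],
            timing=payload.get("timing"),
            n=int(payload["n"]),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "AgreementReport":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def to_markdown(self) -> str:
        """Human-readable summary tables."""
        lines = [
            "## Regression of system score on physician score",
            "",
            "| Item | Intercept | Slope | 95% CI of slope | R^2 | p value |",
            "| --- | --- | --- | --- | --- | --- |",
        ]
        for target in _TARGETS:
            r = self.regression[target]
            lo, hi = r["slope_ci_95"]
            lines.append(
                f"| {target.capitalize()} score | {r['intercept']:.2f} | "
                f"{r['slope']:.2f} | {lo:.2f}-{hi:.2f} | "
                f"{r['r_squared']:.4f} | {r['p_value']:.4g} |"
            )
        lines += [
            "",
            "## Score deviation (physician - system) and relative deviation (%)",
            "",
            "| Item | Deviation mean +/- SD | Within limits | "
            "Relative deviation mean +/- SD | Within limits |",
            "| --- | --- | --- | --- | --- |",
        ]
        for target in _TARGETS:
            d = self.deviations[target]["deviation"]
            r = self.deviations[target]["relative_deviation"]
            if r.get("available", True):
                rel = (
                    f"{r['mean']:.2f} +/- {r['sd']:.2f} | "
                    f"{r['within_limit_count']} ({r['within_limit_percent']:.2f}%)"
                )
            else:
                rel = "n/a | n/a"
            lines.append(
                f"| {target.capitalize()} score | {d['mean']:.2f} +/- {d['sd']:.2f} | "
                f"{d['within_limit_count']} ({d['within_limit_percent']:.2f}%) | {rel} |"
            )
        if self.timing is not None:
            t = self.timing
            lines += [
                "",
                "## Assessment time (min)",
                "",
                f"System {t['system_mean']:.2f} +/- {t['system_sd']:.2f}, "
                f"physician {t['physician_mean']:.2f} +/- {t['physician_sd']:.2f}; "
                f"t = {t['t_statistic']:.3f}, p = {t['p_value']:.4g}.",
            ]
        return "\n".join(lines) + "\n"


def build_report(
    records,
    system_times=None,
    physician_times=None,
    preparation_min: float = 1.0,
) -> AgreementReport:
    """Assemble the full agreement report from predicted, labeled records.

    ``records`` are AssessmentRecords carrying both physician labels and
    system predictions for total, upper and lower scores.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    regression: dict = {}
    deviations: dict = {}
    for target in _TARGETS:
        physician = [getattr(r, f"physician_{target}") for r in records]
        system = [getattr(r, f"system_{target}") for r in records]
        if any(v is None for v in physician):
            raise ValueError(f"missing physician {target} labels")
        if any(v is None for v in system):
            raise ValueError(f"missing system {target} predictions")
        regression[target] = calibration_regression(physician, system)
        deviations[target] = bland_altman(physician, system)
    timing = None
    if system_times is not None and physician_times is not None:
        timing = time_comparison(
            system_times, physician_times, preparation_min=preparation_min
        )
    return AgreementReport(
        regression=regression, deviations=deviations, timing=timing, n=len(records)
    )
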