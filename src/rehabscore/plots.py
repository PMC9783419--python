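"""Optional agreement plots (requires matplotlib).

Mirrors the usual method-comparison figures: a calibration scatter with
the fitted line and identity, and Bland-Altman scatters with the mean and
the 95% limits of agreement.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["regression_plot", "bland_altman_plot"]


def _axes():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib (install rehabscore[plots])"
        ) from exc
    return plt


def regression_plot(physician, system, regression: dict, path: str | Path) -> None:
    """Scatter of system vs physician score with fitted and identity lines."""
    plt = _axes()
    p = np.asarray(physician, dtype=float)
    s = np.asarray(system, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(p, s, s=18, alpha=0.7, edgecolor="none")
    grid = np.linspace(p.min(), p.max(), 50)
    ax.plot(
        grid,
        regression["intercept"] + regression["slope"] * grid,
        "r-",
        label=(
            f"y = {regression['intercept']:.2f} + {regression['slope']:.2f}x, "
            f"$R^2$ = {regression['r_squared']:.4f}"
        ),
    )
    ax.plot(grid, grid, "k--", lw=0.8, label="identity")
    ax.set_xlabel("Physician FMA score")
    ax.set_ylabel("System score")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bland_altman_plot(physician, system, block: dict, path: str | Path) -> None:
    """Bland-Altman scatter with mean and 95% limits of agreement."""
    plt = _axes()
    p = np.asarray(physician, dtype=float)
    s = np.asarray(system, dtype=float)
    mean_scores = (p + s) / 2.0
    dev = p - s
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(mean_scores, dev, s=18, alpha=0.7, edgecolor="none")
    ax.axhline(block["mean"], color="r", label=f"mean {block['mean']:.2f}")
    for limit in block["limits"]:
        ax.axhline(limit, color="r", ls="--", lw=0.8)
    ax.set_xlabel("Mean of physician and system score")
    ax.set_ylabel("Deviation (physician - system)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
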