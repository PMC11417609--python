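"""Regression and Bland-Altman figures for cross-calibration reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import BlandAltmanResult, bland_altman

__all__ = ["regression_plot", "bland_altman_plot", "save_figure"]


def regression_plot(measured, estimated, parameter: str = "", ax=None):
    """Measured vs estimated scatter with the line of unity (dashed)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    ax.scatter(measured, estimated, s=18, color="k")
    lo = min(measured.min(), estimated.min())
    hi = max(measured.max(), estimated.max())
    pad = 0.05 * (hi - lo or 1.0)
    ax.plot([lo - pad, hi + pad], [lo - pad, hi + pad], "k--", lw=1,
            label="line of unity")
    ax.set_xlabel(f"measured {parameter}".strip())
    ax.set_ylabel(f"estimated {parameter}*".strip())
    ax.legend(frameon=False, fontsize=8)
    return ax


def bland_altman_plot(a, b, parameter: str = "", ax=None,
                      result: BlandAltmanResult | None = None):
    """Difference-vs-mean plot with mean difference (solid), 95% limits of
    agreement (dashed) and zero (gray)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if result is None:
        result = bland_altman(a, b)
    means = (a + b) / 2.0
    diffs = a - b
    ax.scatter(means, diffs, s=18, color="k")
    ax.axhline(0.0, color="0.6", lw=1)
    ax.axhline(result.mean_difference, color="k", lw=1.2)
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel(f"mean {parameter}".strip())
    ax.set_ylabel("difference")
    return ax


def save_figure(fig, path: str | Path) -> None:
    """Save with stripped timestamps so identical runs give identical bytes."""
    fig.savefig(str(path), dpi=150, metadata={"Date": None}
                if str(path).endswith(".png") else {})
    plt.close(fig)
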