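"""Plot renderers for the comparison report (Bland-Altman, regression)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement_stats import BlandAltmanResult, RegressionFit


def bland_altman_plot(result: BlandAltmanResult, title: str, path: str | Path) -> None:
    """Scatter of differences against the reference, LoA lines, and the
    histogram of differences in a side panel."""
    fig, (ax, axh) = plt.subplots(
        1, 2, figsize=(8, 3.6), gridspec_kw={"width_ratios": [3, 1]}
    )
    ax.scatter(result.x_values, result.differences, s=12, alpha=0.7, color="#2f4b7c")
    ax.axhline(result.mean_difference, color="k", lw=1.2)
    for loa in (result.loa_low, result.loa_high):
        ax.axhline(loa, color="k", lw=0.8, ls="--")
    ax.set_xlabel("reference fibrosis (%)")
    ax.set_ylabel("difference (test - reference, %)")
    ax.set_title(title, fontsize=10)
    counts, edges = result.histogram
    axh.barh(
        (edges[:-1] + edges[1:]) / 2,
        counts,
        height=np.diff(edges),
        color="#2f4b7c",
        alpha=0.7,
    )
    axh.set_xlabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def regression_plot(fit: RegressionFit, xlabel: str, ylabel: str, path: str | Path) -> None:
    """Scatter with the OLS line and 95% confidence band of the mean response."""
    fig, ax = plt.subplots(figsize=(4.6, 4.0))
    ax.scatter(fit.x, fit.y, s=12, alpha=0.7, color="#a05195")
    xs = np.linspace(float(np.min(fit.x)), float(np.max(fit.x)), 100)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="k", lw=1.2)
    lo, hi = fit.confidence_band(xs)
    ax.fill_between(xs, lo, hi, color="k", alpha=0.15, lw=0)
    suffix = " (ln)" if fit.transform == "ln" else ""
    ax.set_xlabel(xlabel + suffix)
    ax.set_ylabel(ylabel + suffix)
    ax.set_title(
        f"slope {fit.slope:.3f}, intercept {fit.intercept:.3f}, r$^2$ {fit.r_squared:.3f}",
        fontsize=10,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
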