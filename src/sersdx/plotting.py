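"""Matplotlib figures for the study outputs (score plot, regression
vector, ROC curve, difference spectrum). All functions return the Figure;
rendering is optional everywhere else in the package."""

from __future__ import annotations

import numpy as np

from .model import OSCPLSDAResults
from .validation import ValidationReport
from .spectra import Spectrum

__all__ = ["score_plot", "regression_vector_plot", "roc_plot", "spectrum_plot"]


def _fig(figsize):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=figsize)


def score_plot(results: OSCPLSDAResults, labels=None, figsize=(5, 4)):
    """First two LV scores, colored by class; axes annotated with
    per-LV explained X-variance."""
    fig, ax = _fig(figsize)
    T = results.scores
    ev = 100 * results.explained_x_variance
    y = results.model.y
    groups = {"FM": y == 1.0, "non-FM": y == 2.0}
    for (name, mask), color in zip(groups.items(), ("tab:red", "tab:blue")):
        ax.scatter(T[mask, 0], T[mask, 1], s=18, label=name, color=color, alpha=0.8)
    ax.set_xlabel(f"LV1 ({ev[0]:.1f}% X-var)")
    ax.set_ylabel(f"LV2 ({ev[1]:.1f}% X-var)" if T.shape[1] > 1 else "LV2")
    ax.legend()
    ax.set_title("OSC-PLS-DA score plot")
    fig.tight_layout()
    return fig


def regression_vector_plot(results: OSCPLSDAResults, top_k: int = 8, figsize=(7, 3.5)):
    fig, ax = _fig(figsize)
    grid = results.pls.grid
    b = results.regression_vector
    ax.plot(grid, b, lw=0.9, color="k")
    report = results.band_report(top_k=top_k)
    for _, row in report.iterrows():
        ax.axvline(row.wavenumber, color="tab:red", lw=0.5, alpha=0.5)
        ax.annotate(
            f"{row.wavenumber:.0f}",
            (row.wavenumber, row.coefficient),
            fontsize=7,
            rotation=90,
        )
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("regression coefficient")
    ax.set_title("Regression vector")
    fig.tight_layout()
    return fig


def roc_plot(report: ValidationReport, figsize=(4, 4)):
    fig, ax = _fig(figsize)
    ax.plot(report.roc_fpr, report.roc_tpr, drawstyle="steps-post", color="tab:red")
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC (AUC = {report.auc:.3f})")
    fig.tight_layout()
    return fig


def spectrum_plot(*spectra: Spectrum, labels=None, figsize=(7, 3.5)):
    fig, ax = _fig(figsize)
    for i, s in enumerate(spectra):
        lab = labels[i] if labels else (s.sample_id or s.label)
        ax.plot(s.wavenumbers, s.intensities, lw=0.9, label=lab)
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("intensity (a.u.)")
    if len(spectra) > 1 or labels:
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
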