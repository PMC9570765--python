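"""Diagnostic plots for potency modeling runs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def potency_histogram(y, ax=None, bins: int = 30, title: str = "Potency distribution"):
    """Histogram of gene-silencing potencies."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.asarray(y, float), bins=bins, color="0.45", edgecolor="white")
    ax.set_xlabel("potency")
    ax.set_ylabel("count")
    ax.set_title(title)
    return ax.figure


def component_scan_plot(scan: pd.DataFrame, ax=None):
    """Pearson r versus number of PLS components, train and test."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 3.5))
    labels = [str(v) for v in scan["n_components"]]
    x = np.arange(len(labels))
    ax.plot(x, scan["train_r"], "o-", label="training", color="tab:green")
    if "test_r" in scan:
        ax.plot(x, scan["test_r"], "s-", label="test", color="0.4")
    ax.set_xticks(x, labels)
    ax.set_xlabel("number of PLS components")
    ax.set_ylabel("Pearson r")
    ax.legend()
    return ax.figure


def predicted_vs_actual(y, p, ax=None, title: str = "Predicted vs actual potency"):
    """Scatter of model-predicted against actual potency with identity line."""
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 4.2))
    ax.scatter(y, p, s=12, alpha=0.6, color="tab:blue", edgecolors="none")
    lims = [min(y.min(), p.min()), max(y.max(), p.max())]
    ax.plot(lims, lims, "--", color="0.6", lw=1)
    ax.set_xlabel("actual potency")
    ax.set_ylabel("predicted potency")
    ax.set_title(title)
    return ax.figure


def importance_bars(series: pd.Series, ax=None, title: str = "Relative importance"):
    """Bar chart of a per-position or per-descriptor importance marginal."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4.0, 0.3 * len(series)), 3.2))
    ax.bar(range(len(series)), series.to_numpy(), color="0.5")
    ax.set_xticks(range(len(series)), list(series.index), rotation=90, fontsize=7)
    ax.set_ylabel("relative importance")
    ax.set_title(title)
    ax.figure.tight_layout()
    return ax.figure
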