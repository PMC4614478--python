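"""Standard figures: risk against vulnerability, and risk ratio."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .designs import SHORT_NAMES

_STYLE = {
    "A": dict(color="#c02020"),
    "B": dict(color="#e07020"),
    "C": dict(color="#2050c0"),
    "D": dict(color="#20a0a0"),
    "E": dict(color="#208040"),
    "F": dict(color="#80b020", linestyle="--"),
    "G": dict(color="#8040a0"),
    "N": dict(color="#606060"),
}


def _label(d: str) -> str:
    return f"{d}: {SHORT_NAMES.get(d, d)}"


def plot_risk(sweep_df: pd.DataFrame, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Risk against vulnerability, one line per design (lower is safer)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for design, grp in sweep_df.groupby("design", sort=True):
        g = grp.sort_values("v")
        ax.plot(g["v"], g["risk"], marker=".", markersize=3,
                label=_label(design), **_STYLE.get(design, {}))
    ax.set_xlabel("vulnerability v")
    ax.set_ylabel("risk r")
    ax.set_title("Risk against vulnerability")
    ax.legend(fontsize=8)
    return ax


def plot_risk_ratio(sweep_df: pd.DataFrame, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Risk ratio r/v against vulnerability; defective designs diverge as v→0."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    df = sweep_df[sweep_df["v"] > 0]
    for design, grp in df.groupby("design", sort=True):
        g = grp.sort_values("v")
        ax.plot(g["v"], g["risk_ratio"], marker=".", markersize=3,
                label=_label(design), **_STYLE.get(design, {}))
    ax.set_xlabel("vulnerability v")
    ax.set_ylabel("risk ratio r / v")
    ax.set_yscale("log")
    ax.set_title("Risk ratio against vulnerability")
    ax.legend(fontsize=8)
    return ax


def save_figures(sweep_df: pd.DataFrame, risk_path, ratio_path) -> None:
    ax = plot_risk(sweep_df)
    ax.figure.savefig(risk_path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
    ax = plot_risk_ratio(sweep_df)
    ax.figure.savefig(ratio_path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
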