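"""Report figures: per-group boxplots of the three metrics and the
anterior-pressure vs ratio scatter with the cut-off rectangle."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .classify import CutoffRule

_METRIC_LABELS = {
    "circumferential": "Mean circumferential pressure (mmHg)",
    "anterior": "Mean anterior pressure (mmHg)",
    "ratio": "Anterior : circumferential ratio",
}


def metric_boxplots(patient_frame: pd.DataFrame, path: str | Path) -> Path:
    """Boxplots of each patient-mean metric by group (A = abnormal sphincter)."""
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.5))
    for ax, metric in zip(axes, _METRIC_LABELS):
        col = f"{metric}_mean"
        data = [
            patient_frame.loc[patient_frame["group"] == g, col].dropna()
            for g in ("A", "B")
        ]
        ax.boxplot(data, tick_labels=["Group A", "Group B"])
        ax.set_ylabel(_METRIC_LABELS[metric])
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def cutoff_scatter(
    patient_frame: pd.DataFrame, rule: CutoffRule, path: str | Path
) -> Path:
    """Scatter of mean anterior pressure vs ratio with the cut-off rectangle."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, marker, color in (("A", "s", "tab:red"), ("B", "o", "tab:blue")):
        sub = patient_frame[patient_frame["group"] == group]
        ax.scatter(
            sub["anterior_mean"],
            sub["ratio_mean"],
            marker=marker,
            color=color,
            label=f"Group {group}",
            alpha=0.8,
        )
    ax.axvline(rule.anterior_threshold, color="gray", linestyle="--", linewidth=1)
    ax.axhline(rule.ratio_threshold, color="gray", linestyle="--", linewidth=1)
    ax.set_xlabel("Mean anterior pressure (mmHg)")
    ax.set_ylabel("Anterior : circumferential ratio")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
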