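"""Diagnostic plots (requires matplotlib, an optional dependency)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_quality_vs_maf(records: pd.DataFrame, out_path: str | Path) -> None:
    """Scatter IQS and dosage correlation against true MAF, one panel
    per metric, one colour per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharex=True)
    for ax, (metric, flag) in zip(
        axes, (("iqs", "valid_iqs"), ("correlation", "valid_corr"))
    ):
        for method, sub in records[records[flag]].groupby("method"):
            ax.scatter(sub["true_maf"], sub[metric], s=6, alpha=0.4, label=method)
        ax.set_xlabel("true MAF")
        ax.set_ylabel(metric.upper() if metric == "iqs" else "dosage correlation")
        ax.set_xscale("log")
        ax.axhline(0, color="grey", lw=0.5)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
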