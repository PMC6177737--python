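"""Static figures for the evaluation/QC report."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .evaluate import CalibrationBin, RocPoint


def plot_roc(curves: Mapping[str, Sequence[RocPoint]], path: str | Path, title: str = "") -> None:
    """Ranked accuracy curves: true deletions recovered vs false-positive
    calls admitted as the quality threshold descends, one line per caller."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for caller, points in sorted(curves.items()):
        xs = [0] + [p.fp_count for p in points]
        ys = [0] + [p.tp_truth_count for p in points]
        ax.step(xs, ys, where="post", label=caller)
    ax.set_xlabel("False positive calls")
    ax.set_ylabel("Simulated deletions detected")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_calibration(
    bins_by_caller: Mapping[str, Sequence[CalibrationBin]], path: str | Path
) -> None:
    """Empirical precision per quality-score bin, one line per caller."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for caller, bins in sorted(bins_by_caller.items()):
        mids = [(b.score_low + b.score_high) / 2 for b in bins]
        ax.plot(mids, [b.precision for b in bins], marker="o", label=caller)
    ax.set_xlabel("Quality score (bin midpoint)")
    ax.set_ylabel("Empirical precision")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_sample_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Per-sample call counts, grouped by caller; outliers highlighted."""
    callers = sorted(counts["caller"].unique())
    fig, axes = plt.subplots(
        len(callers), 1, figsize=(8, 2.5 * len(callers)), squeeze=False, sharex=True
    )
    for ax, caller in zip(axes.ravel(), callers):
        sub = counts[counts["caller"] == caller].sort_values("sample_id")
        colors = ["tab:red" if o else "tab:blue" for o in sub["outlier"]]
        ax.bar(sub["sample_id"], sub["n_calls"], color=colors)
        ax.set_ylabel(caller, fontsize=8)
        ax.tick_params(axis="x", labelrotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_genome_distribution(dist: pd.DataFrame, path: str | Path) -> None:
    """Call density along the genome in fixed-width bins, per caller."""
    callers = sorted(dist["caller"].unique())
    fig, axes = plt.subplots(
        len(callers), 1, figsize=(8, 2.0 * len(callers)), squeeze=False, sharex=True
    )
    # lay contigs end to end on one axis
    offsets: dict[str, int] = {}
    pos = 0
    for chrom, sub in dist.groupby("chrom", sort=False):
        offsets[chrom] = pos
        pos += int(sub["bin_end"].max())
    for ax, caller in zip(axes.ravel(), callers):
        sub = dist[dist["caller"] == caller]
        xs = [offsets[c] + s for c, s in zip(sub["chrom"], sub["bin_start"])]
        widths = (sub["bin_end"] - sub["bin_start"]).tolist()
        ax.bar(xs, sub["n_overlapping_calls"], width=widths, align="edge")
        ax.set_ylabel(caller, fontsize=8)
    for chrom, off in offsets.items():
        axes.ravel()[-1].annotate(chrom, (off, 0), fontsize=6, annotation_clip=False)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
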