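"""Best-effort matplotlib renderings of the diagnostic tables.

Each function takes the source table produced by the corresponding
diagnostics routine and returns a matplotlib Figure; the tables are
the contract, the images a convenience.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .diagnostics import MetaProfile

FRAME_COLORS = {0: "#1b9e77", 1: "#d95f02", 2: "#7570b3"}


def plot_length_distribution(dist: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(dist["length"], dist["pct"], color="#4c72b0")
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("% of reads")
    fig.tight_layout()
    return fig

def plot_region_stats(stats: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    x = range(len(stats))
    width = 0.38
    ax.bar([i - width / 2 for i in x], stats["observed_pct"], width, label="P-sites")
    ax.bar([i + width / 2 for i in x], stats["expected_pct"], width, label="region length")
    ax.set_xticks(list(x), stats["region"])
    ax.set_ylabel("%")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig

def plot_frame_stats(stats: pd.DataFrame):
    regions = [r for r in ("utr5", "cds", "utr3") if r in set(stats["region"])]
    fig, axes = plt.subplots(1, len(regions), figsize=(2.2 * len(regions), 3.2), squeeze=False)
    for ax, region in zip(axes[0], regions):
        sub = stats[stats["region"] == region]
        if "length" in sub.columns:
            sub = sub.groupby("frame", as_index=False)["pct"].mean()
        ax.bar(sub["frame"], sub["pct"], color=[FRAME_COLORS[f] for f in sub["frame"]])
        ax.set_title(region)
        ax.set_xlabel("frame")
        ax.set_xticks([0, 1, 2])
    axes[0][0].set_ylabel("% of P-sites")
    fig.tight_layout()
    return fig

def plot_metaprofile(meta: MetaProfile):
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.vlines(meta.counts.index, 0, meta.counts.to_numpy(), color="#4c72b0")
    ax.axvline(0, color="crimson", lw=0.8, ls="--")
    ax.set_xlabel(f"distance from {meta.anchor} codon (nt)")
    ax.set_ylabel("P-site count")
    fig.tight_layout()
    return fig

def plot_ends_heatmap(data: pd.DataFrame, anchor: str = "start"):
    sub = data[data["anchor"] == anchor]
    fig, axes = plt.subplots(2, 1, figsize=(6, 4.6), sharex=True)
    for ax, extremity in zip(axes, ("five_prime", "three_prime")):
        panel = sub[sub["extremity"] == extremity]
        if len(panel):
            pivot = panel.pivot_table(
                index="length", columns="x", values="count", fill_value=0
            )
            ax.imshow(
                pivot.to_numpy(),
                aspect="auto",
                origin="lower",
                extent=[pivot.columns.min(), pivot.columns.max(),
                        pivot.index.min(), pivot.index.max()],
                cmap="viridis",
            )
        ax.set_ylabel(f"{extremity}\nlength")
    axes[1].set_xlabel(f"distance from {anchor} codon (nt)")
    fig.tight_layout()
    return fig

def plot_codon_usage(table: pd.DataFrame):
    ordered = table.sort_values("usage_index", ascending=False)
    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.bar(ordered["codon"], ordered["usage_index"], color="#4c72b0")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("codon usage index")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    return fig

def plot_transcript_profile(coverage: pd.Series, transcript_id: str = ""):
    fig, ax = plt.subplots(figsize=(6, 2.6))
    ax.vlines(coverage.index, 0, coverage.to_numpy(), color="#4c72b0")
    ax.set_xlabel(f"position along {transcript_id or 'transcript'} (nt)")
    ax.set_ylabel("P-site coverage")
    fig.tight_layout()
    return fig
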