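"""Plots: AF-vs-residue profiles (with onset box) and annotated chromatograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_aggregation_profile",
    "plot_profile_overlay",
    "plot_chromatogram",
]


def _annotate_onset(ax, labels, af, onset_label):
    if onset_label is None or onset_label not in labels:
        return
    i = labels.index(onset_label)
    lo = max(0.0, min(af[i:]) - 0.05)
    hi = max(af[i:]) + 0.05
    ax.axvspan(i - 0.5, len(labels) - 0.5, color="0.85", zorder=0)
    ax.annotate(
        f"onset after {onset_label}",
        xy=(i, af[i]),
        xytext=(i, hi),
        arrowprops={"arrowstyle": "->"},
        fontsize=8,
    )


def plot_aggregation_profile(profile, ax=None):
    """AF against residue in synthesis order, onset region shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.4 * len(profile)), 3.5))
    labels = list(profile.labels)
    af = np.asarray(profile.af)
    x = np.arange(len(labels))
    ax.plot(x, af, "o-", ms=4, label=profile.name or None)
    for i, l in enumerate(labels):
        if l in profile.excluded_labels:
            ax.plot(i, af[i], "x", color="crimson", ms=8, zorder=5)
    _annotate_onset(ax, labels, af, profile.onset_label)
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_xlabel("residue (synthesis order, C→N)")
    ax.set_ylabel("aggregation factor")
    ax.axhline(0.0, color="0.7", lw=0.8)
    if profile.name:
        ax.legend(frameon=False, fontsize=8)
    ax.figure.tight_layout()
    return ax


def plot_profile_overlay(profiles, names=None, ax=None):
    """Overlay several AF profiles (e.g. tagged vs untagged) on shared residues."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    if names is None:
        names = [p.name or f"profile_{i}" for i, p in enumerate(profiles)]
    base = profiles[0]
    common = [l for l in base.labels if all(l in p.labels for p in profiles)]
    x = np.arange(len(common))
    for name, p in zip(names, profiles):
        style = "-" if p is base else "--"
        ax.plot(x, [p.af_of(l) for l in common], style, marker="o", ms=3, label=name)
        if p.onset_label in common:
            ax.axvline(common.index(p.onset_label), color="0.8", lw=0.8, zorder=0)
    ax.set_xticks(x)
    ax.set_xticklabels(common, rotation=90, fontsize=7)
    ax.set_xlabel("residue (synthesis order, C→N)")
    ax.set_ylabel("aggregation factor")
    ax.legend(frameon=False, fontsize=8)
    ax.figure.tight_layout()
    return ax


def plot_chromatogram(chrom, table=None, ax=None):
    """Chromatogram with integrated peaks annotated by area fraction."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(chrom.time_min, chrom.absorbance_au, lw=0.8)
    if table:
        for e in table:
            ax.annotate(
                f"{100 * e.area_fraction:.1f}%",
                xy=(e.rt_min, e.height_au),
                xytext=(0, 4),
                textcoords="offset points",
                ha="center",
                fontsize=7,
            )
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel(f"absorbance at {chrom.wavelength_nm:.0f} nm (AU)")
    ax.figure.tight_layout()
    return ax
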