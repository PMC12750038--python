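"""Optional report figures (accuracy histograms, per-group RMSD boxes,
stage-comparison histograms). All functions write a PNG and return the path."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def lddt_pli_histogram(values, path: str | Path, bin_width: float = 0.1):
    """Histogram of LDDT-PLI values across all submissions."""
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.arange(0.0, 1.0 + bin_width, bin_width)
    ax.hist(np.clip(values, 0, 1), bins=bins, edgecolor="black")
    ax.set_xlabel("LDDT-PLI")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def rmsd_boxes_by_group(rmsds_by_group: dict[int, list[float]], path: str | Path,
                        y_max: float = 14.0):
    """Per-group RMSD distribution summary (min/max whiskers, quartile boxes)."""
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(rmsds_by_group)), 4))
    groups = sorted(rmsds_by_group)
    ax.boxplot([rmsds_by_group[g] for g in groups], tick_labels=[str(g) for g in groups],
               whis=(0, 100), showmeans=False)
    ax.set_ylim(0, y_max)
    ax.set_xlabel("group")
    ax.set_ylabel("RMSD (A)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def stage_tau_histograms(stage1_taus, stage2_taus, path: str | Path):
    """Normalized overlapping histograms of per-group tau for the two stages."""
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(-1, 1, 21)
    ax.hist(stage1_taus, bins=bins, density=True, alpha=0.6, label="stage 1")
    ax.hist(stage2_taus, bins=bins, density=True, alpha=0.6, label="stage 2")
    ax.set_xlabel("Kendall tau")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
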