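"""Diagnostic figures: F-value bars, RMSE/accuracy curves, confusion
matrices and LISA/Gi* maps.  All functions take data, return the
matplotlib Figure, and optionally save it; rendering is headless."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_DIST_COLORS = {
    "spread": "#c0392b",
    "saltatory": "#e67e22",
    "latent": "#f1c40f",
    "healthy": "#27ae60",
    "unclassified": "#bdc3c7",
}


def _finish(fig, save):
    fig.tight_layout()
    if save is not None:
        fig.savefig(save, dpi=120)
        plt.close(fig)
    return fig


def plot_f_values(f_values: dict, threshold: float, save=None):
    names = list(f_values)
    vals = [f_values[n] for n in names]
    fig, ax = plt.subplots(figsize=(max(6, len(names) * 0.25), 4))
    ax.bar(range(len(names)), vals, color="#2c7fb8")
    ax.axhline(threshold, color="red", ls="--", label=f"threshold {threshold:g}")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=90, fontsize=6)
    ax.set_yscale("log")
    ax.set_ylabel("ANOVA F")
    ax.legend()
    return _finish(fig, save)


def plot_rmse_curve(sizes, rmse, chosen_size=None, save=None):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(sizes, rmse, "o-", ms=3)
    if chosen_size is not None:
        ax.axvline(chosen_size, color="red", ls="--", label=f"chosen: {chosen_size}")
        ax.legend()
    ax.set_xlabel("number of features")
    ax.set_ylabel("CV RMSE")
    return _finish(fig, save)


def plot_accuracy_curve(accuracy, chosen_size=None, save=None):
    sizes = np.arange(1, len(accuracy) + 1)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(sizes, accuracy, "o-", ms=3)
    if chosen_size is not None:
        ax.axvline(chosen_size, color="red", ls="--", label=f"chosen: {chosen_size}")
        ax.legend()
    ax.set_xlabel("number of features")
    ax.set_ylabel("CV accuracy")
    return _finish(fig, save)


def plot_confusion(counts, levels, title="", save=None):
    counts = np.asarray(counts)
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(counts, cmap="Blues")
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            ax.text(j, i, f"{counts[i, j]:.0f}", ha="center", va="center", fontsize=8)
    ax.set_xticks(range(len(levels)))
    ax.set_xticklabels(levels)
    ax.set_yticks(range(len(levels)))
    ax.set_yticklabels(levels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    return _finish(fig, save)


def plot_distribution_map(x, y, distribution_type, save=None):
    fig, ax = plt.subplots(figsize=(7, 4))
    for dtype, color in _DIST_COLORS.items():
        m = np.asarray(distribution_type) == dtype
        if m.any():
            ax.scatter(np.asarray(x)[m], np.asarray(y)[m], s=6, c=color, label=dtype)
    ax.set_aspect("equal")
    ax.legend(markerscale=2, fontsize=7)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return _finish(fig, save)


def render_run_figures(run_dir, fig_dir) -> None:
    """Best-effort figure pack for a completed pipeline run directory."""
    run_dir, fig_dir = Path(run_dir), Path(fig_dir)
    for p in sorted(run_dir.glob("selection_*.json")):
        doc = json.loads(p.read_text())
        d = doc["diagnostics"]
        stem = p.stem
        if doc["method"] == "ANOVA":
            plot_f_values(
                d["f_values"], d["threshold_used"], save=fig_dir / f"{stem}.png"
            )
        elif doc["method"] == "SPA":
            plot_rmse_curve(
                d["sizes"], d["rmse_curve"], d["chosen_size"],
                save=fig_dir / f"{stem}.png",
            )
        elif doc["method"] == "SFS":
            plot_accuracy_curve(
                d["accuracy_curve"], d["chosen_size"], save=fig_dir / f"{stem}.png"
            )
    for p in sorted(run_dir.glob("model_*.json")):
        doc = json.loads(p.read_text())
        plot_confusion(
            doc["confusion"], doc["levels"],
            title=f"{p.stem}  OA={doc['oa']:.3f}",
            save=fig_dir / f"{p.stem}.png",
        )
    sp = run_dir / "spatial.csv"
    if sp.exists():
        df = pd.read_csv(sp)
        plot_distribution_map(
            df["x"], df["y"], df["distribution_type"],
            save=fig_dir / "distribution_map.png",
        )
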