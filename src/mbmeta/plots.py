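"""Figure rendering: forest plots, bubble plots and per-cell summaries.

All plot functions draw from exported table structures (forest rows,
driver-effect lists, category summaries) rather than from fitted model
objects, so every figure is reproducible from the CSV artifacts alone.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["forest_plot", "bubble_plot", "per_cell_plot"]


def forest_plot(rows: Sequence, path, title: str = "") -> None:
    """Render forest-table rows (study points, subgroup/overall diamonds)."""
    n = len(rows)
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.32 * n + 1.2)))
    ys = np.arange(n)[::-1]
    for y, row in zip(ys, rows):
        if row.kind == "study":
            ax.plot([row.ci_low, row.ci_high], [y, y], color="0.4", lw=1)
            ax.plot(row.estimate, y, "s", color="0.2", ms=4)
            label = f"  {row.label}"
        else:
            color = "firebrick" if row.kind == "overall" else "steelblue"
            xs = [row.ci_low, row.estimate, row.ci_high, row.estimate]
            ax.fill(xs, [y, y + 0.3, y, y - 0.3], color=color, alpha=0.8)
            label = row.label
        weight = f" ({row.weight_pct:.1f}%)" if row.weight_pct is not None else ""
        ax.text(
            1.01, y, f"{label}{weight}", transform=ax.get_yaxis_transform(),
            va="center", fontsize=7,
        )
    ax.axvline(0.0, color="0.7", lw=0.8, ls="--")
    ax.set_yticks([])
    ax.set_xlabel("effect (% change)")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, metadata={"Title": title} if str(path).endswith(".svg") else None)
    plt.close(fig)


def bubble_plot(
    effects: Sequence,
    regression: dict,
    path,
    reference: float = 0.0,
    title: str = "",
) -> None:
    """Driver effects vs cell counts, bubble area = regression weight."""
    usable = [e for e in effects if e.cell_count is not None]
    x = np.array([e.cell_count for e in usable], dtype=float)
    y = np.array([e.effect for e in usable])
    w = np.array([e.n_experiments for e in usable], dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    # gid encodes the weight so the plotting contract is checkable from SVG
    for xi, yi, wi, e in zip(x, y, w, usable):
        ax.scatter(
            xi, yi, s=60.0 * wi, alpha=0.5, color="steelblue",
            gid=f"bubble:{e.driver}:w={wi:g}",
        )
    xs = np.linspace(0.0, max(x) * 1.05, 50)
    ax.plot(xs, regression["intercept"] + regression["slope"] * xs, color="navy", lw=1.5)
    ax.axhline(reference, color="0.6", lw=1.0)
    ax.set_xlabel("driver cell count")
    ax.set_ylabel("residual learning effect (%)")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def per_cell_plot(categories: dict, path, title: str = "") -> None:
    """One marker + CI per lobe category of per-cell effect estimates."""
    names = list(categories)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for i, name in enumerate(names):
        c = categories[name]
        ax.errorbar(
            i, c["estimate"],
            yerr=[[c["estimate"] - c["ci_low"]], [c["ci_high"] - c["estimate"]]],
            fmt="o", color="steelblue", capsize=3, gid=f"category:{name}",
        )
    ax.axhline(0.0, color="0.6", lw=0.8, ls="--")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("effect per cell (%/cell)")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
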