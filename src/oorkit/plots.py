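"""Optional quick-look plots (no acceptance weight).

Uses the Agg backend so plotting works headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import GROUPS
from .io import RunConfig


def plot_oor_by_condition(cells: pd.DataFrame, condition_column: str, path: Path) -> None:
    """Histogram of log10(OOR) per condition level."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    vals = cells["oor"].to_numpy(dtype=float)
    logv = np.log10(np.clip(vals, 1e-12, None))
    for level, sub in cells.groupby(condition_column):
        ax.hist(
            logv[cells[condition_column] == level],
            bins=40, alpha=0.55, label=str(level), density=True,
        )
    ax.set_xlabel("log10(OOR)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_group_fractions(cells: pd.DataFrame, condition_column: str | None, path: Path) -> None:
    """Stacked bar of group fractions, optionally split by condition."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if condition_column is not None and condition_column in cells.columns:
        levels = sorted(cells[condition_column].unique())
    else:
        condition_column, levels = None, ["all"]
    bottoms = np.zeros(len(levels))
    for g in GROUPS:
        fracs = []
        for i, level in enumerate(levels):
            sub = cells if condition_column is None else cells[cells[condition_column] == level]
            fracs.append((sub["group"] == g).mean() if len(sub) else 0.0)
        ax.bar(levels, fracs, bottom=bottoms, label=g)
        bottoms += np.asarray(fracs)
    ax.set_ylabel("fraction of cells")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def quicklook_plots(cells: pd.DataFrame, config: RunConfig, out_dir: Path) -> list[str]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    cond = config.reference.condition_column
    if "oor" in cells.columns and cond in cells.columns:
        p = out_dir / "oor_by_condition.png"
        plot_oor_by_condition(cells, cond, p)
        written.append(str(p))
    if "group" in cells.columns:
        p = out_dir / "group_fractions.png"
        plot_group_fractions(cells, cond if cond in cells.columns else None, p)
        written.append(str(p))
    return written
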