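"""Figure helpers: per-bin density bar charts with standard-error bars."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .quantify import BIN_LABELS


def plot_density_bars(density_summary: pd.DataFrame, out_path: str | Path) -> Path:
    """One subplot per size bin: mean density +/- SE per condition.

    ``density_summary`` is the output of
    :func:`partiquant.recovery.density_summary` (columns condition, bin,
    mean_density, sem_density, n_slides).
    """
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), constrained_layout=True)
    for ax, b in zip(axes.ravel(), BIN_LABELS):
        sub = density_summary[density_summary["bin"] == b].sort_values("condition")
        ax.bar(
            sub["condition"],
            sub["mean_density"],
            yerr=sub["sem_density"].fillna(0.0),
            capsize=3,
            color="#4878a8",
        )
        ax.set_title(f"{b} μm")
        ax.set_ylabel("particles / mm$^2$")
        ax.set_xlabel("condition")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
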