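"""Figure panels for the standard readouts (matplotlib, headless)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .measure import TimeSeriesTable

__all__ = ["plot_tables", "plot_sweep_slice"]


def plot_tables(tables: dict[str, TimeSeriesTable], path, title: str = "",
                ylabel: str = "") -> None:
    """Overlay mean ± SD bands of one readout across conditions."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for name, t in tables.items():
        x = t.bin_centers
        ax.plot(x, t.values, label=name)
        ax.fill_between(x, t.values - t.spread, t.values + t.spread,
                        alpha=0.2)
    first = next(iter(tables.values()))
    ax.set_xlabel(first.bin_axis.replace("_", " "))
    ax.set_ylabel(ylabel or first.quantity.replace("_", " "))
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep_slice(agg, path, axis: str = "psm_psm") -> None:
    """Regime ratio and labels along a one-parameter sweep slice."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = agg[f"scaled_{axis}"]
    colors = agg["label"].map(
        {"CONVERGENCE": "tab:blue", "ELONGATION": "tab:red"}
    ).fillna("gray")
    ax.scatter(x, agg["ratio"], c=colors, s=30)
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel(f"scaled {axis} repulsion")
    ax.set_ylabel("elongation / convergence ratio")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
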