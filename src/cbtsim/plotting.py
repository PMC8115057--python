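"""Figure export for sweep and exposure results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_sweep", "plot_exposure", "make_figures"]


def _check(table: pd.DataFrame, cols: set[str], what: str) -> None:
    if len(table) == 0:
        raise ValueError(f"empty result table for {what} plot")
    missing = cols - set(table.columns)
    if missing:
        raise ValueError(f"{what} table is missing columns: {sorted(missing)}")


def plot_sweep(table: pd.DataFrame, path: str | Path) -> Path:
    """Approach percentage vs P(safe), one curve per CAB interaction level."""
    _check(table, {"p_safe", "cab_i", "approach_rate"}, "sweep")
    fig, ax = plt.subplots(figsize=(5, 4))
    for cab, grp in table.groupby("cab_i"):
        grp = grp.sort_values("p_safe")
        ax.plot(grp["p_safe"], 100 * grp["approach_rate"], marker="o", label=f"CAB-i = {cab:g}")
    ax.set_xlabel("prior P(safe)")
    ax.set_ylabel("approach decisions (%)")
    ax.set_ylim(-2, 102)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_exposure(table: pd.DataFrame, path: str | Path) -> Path:
    """Probe approach percentage vs exposure length, one curve per CAB level."""
    _check(table, {"exposure_length", "cab_i", "approach_rate"}, "exposure")
    fig, ax = plt.subplots(figsize=(5, 4))
    for cab, grp in table.groupby("cab_i"):
        grp = grp.sort_values("exposure_length")
        ax.plot(
            grp["exposure_length"], 100 * grp["approach_rate"], marker="o", label=f"CAB-i = {cab:g}"
        )
    ax.set_xlabel("exposure length (trials)")
    ax.set_ylabel("probe approach decisions (%)")
    ax.set_ylim(-2, 102)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def make_figures(results_dir: str | Path) -> list[Path]:
    """Render PNG figures for every recognized result CSV in a directory.

    ``sweep.csv`` yields approach-vs-P(safe) curves; ``exposure.csv`` yields
    approach-vs-exposure-length curves.  Raises if no result file is found or
    a found table is empty/malformed.
    """
    results_dir = Path(results_dir)
    written: list[Path] = []
    sweep_csv = results_dir / "sweep.csv"
    if sweep_csv.exists():
        written.append(plot_sweep(pd.read_csv(sweep_csv), results_dir / "sweep.png"))
    exposure_csv = results_dir / "exposure.csv"
    if exposure_csv.exists():
        written.append(plot_exposure(pd.read_csv(exposure_csv), results_dir / "exposure.png"))
    if not written:
        raise FileNotFoundError(f"no sweep.csv or exposure.csv found in {results_dir}")
    return written
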