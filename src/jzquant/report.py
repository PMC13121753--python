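"""Report assembly: one directory of tidy CSV tables, a machine-readable
summary JSON and overview figures (displacement profiles, polar histograms,
aligned constriction curves, depth histograms)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = ["build_report"]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def _plot_profile(df: pd.DataFrame, path: Path, ylabel: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = 0.5 * (df["bin_lo_pct"] + df["bin_hi_pct"])
    ax.errorbar(x, df["mean_um"], yerr=df["sem_um"], fmt="o-", capsize=3)
    ax.set_xlabel("start distance to midline (% half-width)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_polar(df: pd.DataFrame, path: Path, title: str) -> None:
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    theta = np.deg2rad(0.5 * (df["bin_lo_deg"] + df["bin_hi_deg"]))
    width = np.deg2rad(df["bin_hi_deg"] - df["bin_lo_deg"])
    ax.bar(theta, df["weight"], width=width, align="center", alpha=0.8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_constriction(df: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for group, sub in df.groupby("group") if "group" in df.columns else [("all", df)]:
        ax.errorbar(sub["aligned_min"], sub["mean_norm_area"], yerr=sub["sem"], label=str(group))
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("time from maximal area (min)")
    ax.set_ylabel("normalised apical area")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_depth(df: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = 0.5 * (df["bin_lo_pct"] + df["bin_hi_pct"])
    ax.bar(x, df["count"], width=0.9 * (df["bin_hi_pct"] - df["bin_lo_pct"]))
    ax.set_xlabel("relative depth (% , 0 = dorsal surface)")
    ax.set_ylabel("cells")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


_PLOTTERS = {
    "profile": lambda df, p: _plot_profile(df, p, "displacement (um)"),
    "polar": _plot_polar,
    "constriction": _plot_constriction,
    "depth_histogram": _plot_depth,
}


def build_report(
    out_dir: str | Path,
    sections: Mapping[str, Mapping[str, object]],
    expected: Sequence[str] | None = None,
) -> Path:
    """Assemble analysis outputs into one report directory.

    ``sections`` maps a section name (e.g. ``tracks``, ``depth``) to a
    mapping of table name -> DataFrame (written as CSV, plotted where a
    plotter is known) or summary name -> dict (merged into
    ``summary.json``).  When ``expected`` names sections, any missing ones
    raise an error listing them by name.  Deterministic: identical inputs
    produce byte-identical tables.
    """
    if expected is not None:
        missing = [name for name in expected if name not in sections]
        if missing:
            raise ValidationError(f"missing report inputs: {', '.join(missing)}")
    if not sections:
        raise ValidationError("missing report inputs: no analysis outputs given")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for section, items in sections.items():
        sec_summary: dict = {}
        for name, obj in items.items():
            if isinstance(obj, pd.DataFrame):
                _write_csv(obj, out / f"{section}_{name}.csv")
                for key, plotter in _PLOTTERS.items():
                    if key in name:
                        if key == "polar":
                            plotter(obj, out / f"{section}_{name}.png", name)
                        else:
                            plotter(obj, out / f"{section}_{name}.png")
                        break
            elif isinstance(obj, dict):
                sec_summary[name] = obj
            else:
                raise ValidationError(f"unsupported report item {section}/{name}: {type(obj)}")
        if sec_summary:
            summary[section] = sec_summary
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True, default=float))
    return out
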