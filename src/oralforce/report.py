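"""Reporting layer: rounding for display and the ratio-vs-year figure.

All model arithmetic is carried at full float precision; only here are
headcounts and FTE figures rounded to whole practitioners, supply/
requirement ratios to one decimal, and annual capacity to whole hours.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd


def round_half_up(x: float) -> float:
    """Round to the nearest integer, ties away from zero (printed-figure
    convention; avoids float banker's rounding surprises)."""
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def reported_capacity_hours(capacity_minutes: float) -> int:
    """Annual capacity in whole hours as printed in reports (1579.5 h -> 1580)."""
    return int(round_half_up(capacity_minutes / 60.0))


def reported_ratio(fte_supply: float, fte_requirement: float) -> float:
    """Supply/requirement ratio to one decimal, from unrounded FTEs."""
    if fte_requirement <= 0:
        return float("nan")
    return round_half_up(10.0 * fte_supply / fte_requirement) / 10.0


def format_results(results: pd.DataFrame) -> pd.DataFrame:
    """Projection results at printed precision: whole-practitioner stock
    and FTEs, ratio to one decimal; input frame untouched."""
    out = results.copy()
    for col in ("stock", "fte_supply", "fte_requirement"):
        out[col] = out[col].map(lambda v: int(round_half_up(v)))
    out["ratio"] = out["ratio"].map(
        lambda v: float("nan") if pd.isna(v) else round_half_up(10.0 * v) / 10.0
    )
    return out


def plot_ratio(results: pd.DataFrame, path: str | Path) -> Path:
    """Plot the supply/requirement ratio per year, one line per scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    df = results if "scenario" in results.columns else results.assign(scenario="baseline")
    for name, grp in df.groupby("scenario", sort=False):
        ax.plot(grp["year"], grp["ratio"], label=name)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("year")
    ax.set_ylabel("FTE supply / FTE requirement")
    ax.set_title("Provider supply relative to needs-based requirement")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
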