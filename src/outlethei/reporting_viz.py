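"""Radar plots and tabular reports of HEI-2015 score patterns.

Component scores are scaled to percent of their maximum and drawn on a
13-axis radar chart: the center is a score of zero, the outer ring the
maximum, one closed polygon per series (outlet or cycle).  Axis order is
fixed to the canonical component listing so shapes are comparable across
plots.  Score tables are written as CSV with one row per (outlet, cycle),
values rounded to two decimals (round-half-even) with a letter grade.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .hei_engine import HEIScoreSet, ScoringStandard, grade

__all__ = ["RadarSeries", "AXIS_ORDER", "to_percent_of_max", "render_radar", "write_score_report"]

#: Canonical axis order for radar plots and report columns.
AXIS_ORDER: tuple[str, ...] = (
    "total_fruits",
    "whole_fruits",
    "total_vegetables",
    "greens_and_beans",
    "whole_grains",
    "dairy",
    "total_protein_foods",
    "seafood_plant_proteins",
    "fatty_acids",
    "refined_grains",
    "sodium",
    "added_sugars",
    "saturated_fats",
)


@dataclass(frozen=True)
class RadarSeries:
    """One labelled polygon: component scores in percent of maximum."""

    label: str
    values: tuple[float, ...]  # aligned with `axes`
    axes: tuple[str, ...] = AXIS_ORDER

    def __post_init__(self) -> None:
        if len(self.values) != len(self.axes):
            raise ValueError("values and axes length mismatch")
        if any(not 0 <= v <= 100 for v in self.values):
            raise ValueError("percent-of-maximum values must lie in [0, 100]")


def to_percent_of_max(
    score_set: HEIScoreSet, standards: Sequence[ScoringStandard]
) -> RadarSeries:
    """Scale each component score to percent of its maximum points."""
    max_points = {s.component: s.max_points for s in standards}
    values = tuple(
        100.0 * score_set.component_scores[c] / max_points[c] for c in AXIS_ORDER
    )
    return RadarSeries(label=score_set.group, values=values)


def render_radar(series_list: Sequence[RadarSeries], path: str | Path) -> Path:
    """Draw one closed polygon per series on a fixed 13-axis radar chart."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not series_list:
        raise ValueError("at least one series is required")
    axes = series_list[0].axes
    if any(s.axes != axes for s in series_list):
        raise ValueError("all series must share the same axis order")
    n = len(axes)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    ax.set_theta_offset(np.pi / 2)
    ax.set_theta_direction(-1)
    for series in series_list:
        values = np.concatenate([series.values, series.values[:1]])
        theta = np.concatenate([angles, angles[:1]])
        ax.plot(theta, values, label=series.label, linewidth=1.5)
        ax.fill(theta, values, alpha=0.08)
    ax.set_xticks(angles)
    ax.set_xticklabels([a.replace("_", " ") for a in axes], fontsize=8)
    ax.set_ylim(0, 100)
    ax.set_yticks([20, 40, 60, 80, 100])
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def write_score_report(
    score_sets: Sequence[HEIScoreSet],
    path: str | Path,
    ses: Mapping[str, float] | None = None,
) -> Path:
    """Write one CSV row per score set: total, 13 components, SE, grade.

    The ``group`` label of each score set keys the optional *ses* mapping
    (BRR standard error of the total).  Values are rounded to two decimals
    with round-half-even; an empty input yields a header-only file.
    """
    import csv

    path = Path(path)
    header = ["group", "total", *AXIS_ORDER, "total_se", "grade"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for score_set in score_sets:
            se = (ses or {}).get(score_set.group)
            writer.writerow(
                [
                    score_set.group,
                    _round2(score_set.total),
                    *[_round2(score_set.component_scores[c]) for c in AXIS_ORDER],
                    "" if se is None else _round2(se),
                    grade(score_set.total, 100.0),
                ]
            )
    return path
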