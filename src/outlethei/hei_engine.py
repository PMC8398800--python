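"""HEI-2015 scoring of weighted food mixes via the population ratio method.

The Healthy Eating Index 2015 (HEI-2015) measures how well a mix of foods
aligns with the 2015–2020 Dietary Guidelines for Americans.  It is
density-based: thirteen components are each expressed relative to energy —
per 1000 kcal (cup/oz equivalents, sodium in g), as percent of energy
(added sugars at 16 kcal per tsp-equivalent, saturated fat at 9 kcal/g), or
as the dimensionless (MUFA+PUFA)/SFA fatty-acid ratio — and scored
piecewise-linearly between a zero-score and a full-score cut-point.  Nine
adequacy components (more is better) and four moderation components (less
is better) sum to a 0–100 total.

Group scores use the *population ratio method*: weighted component and
energy totals are summed over all items in the group first, and the single
ratio of totals is scored.  This differs from averaging per-person scores
and is the recommended estimator of a population's mean diet quality.

Numeric cut-points ship as an editable standards file; the engine treats
them purely as configuration, so synthetic standards can be scored the same
way.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .recall_io import CANONICAL_COMPONENTS

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringStandard",
    "ComponentTotals",
    "HEIScoreSet",
    "ScoringError",
    "load_standards",
    "aggregate",
    "densities",
    "score_component",
    "score_group",
    "densities_for_scores",
    "grade",
    "calorie_shares",
    "make_group_score_fn",
]

#: kcal conversion factors for percent-of-energy components.
KCAL_PER_TSP_ADDED_SUGARS = 16.0
KCAL_PER_G_FAT = 9.0

_FAT_RATIO_SOURCES = ("mufa_g", "pufa_g", "sfa_g")


class ScoringError(ValueError):
    """Raised for malformed standards or degenerate scoring inputs."""


@dataclass(frozen=True)
class ScoringStandard:
    """Cut-points and direction for one HEI component.

    ``unit`` is one of ``per_1000kcal``, ``percent_energy`` or ``fat_ratio``;
    ``source`` names the canonical item column feeding the density (unused
    for the fatty-acid ratio); ``scale`` converts the stored unit into the
    scoring unit (e.g. 0.001 for sodium mg -> g); ``kcal_per_unit`` converts
    percent-of-energy sources into kcal.
    """

    component: str
    max_points: float
    direction: str  # adequacy | moderation | ratio
    unit: str
    source: str | None
    max_score_at: float
    zero_score_at: float
    scale: float = 1.0
    kcal_per_unit: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("adequacy", "moderation", "ratio"):
            raise ScoringError(f"unknown direction {self.direction!r}")
        if self.unit not in ("per_1000kcal", "percent_energy", "fat_ratio"):
            raise ScoringError(f"unknown unit {self.unit!r}")
        if self.max_score_at == self.zero_score_at:
            raise ScoringError(
                f"standard {self.component!r} has equal cut-points"
            )
        if self.direction == "moderation":
            if not self.zero_score_at > self.max_score_at:
                raise ScoringError(
                    f"moderation standard {self.component!r} needs zero_score_at > max_score_at"
                )
        elif not self.zero_score_at < self.max_score_at:
            raise ScoringError(
                f"{self.direction} standard {self.component!r} needs zero_score_at < max_score_at"
            )


@dataclass(frozen=True)
class ComponentTotals:
    """Weighted sums of canonical components and energy for one group."""

    group: str
    sums: Mapping[str, float]
    energy_kcal: float


@dataclass(frozen=True)
class HEIScoreSet:
    """Thirteen component scores plus the total for one (outlet, cycle) group."""

    group: str
    component_scores: Mapping[str, float]
    total: float


def load_standards(path: str | Path | None = None) -> tuple[ScoringStandard, ...]:
    """Load scoring standards from a columnar text file (packaged default)."""
    src = path if path is not None else files("outlethei.data") / "hei2015_standards.csv"
    frame = pd.read_csv(src)  # type: ignore[arg-type]
    standards = []
    for row in frame.itertuples(index=False):
        standards.append(
            ScoringStandard(
                component=row.component,
                max_points=float(row.max_points),
                direction=row.direction,
                unit=row.unit,
                source=None if pd.isna(row.source) else row.source,
                scale=1.0 if pd.isna(row.scale) else float(row.scale),
                kcal_per_unit=None if pd.isna(row.kcal_per_unit) else float(row.kcal_per_unit),
                max_score_at=float(row.max_score_at),
                zero_score_at=float(row.zero_score_at),
            )
        )
    return tuple(standards)


def _weight_series(weights: pd.DataFrame | pd.Series) -> pd.Series:
    if isinstance(weights, pd.DataFrame):
        return pd.Series(
            weights["day1_weight"].to_numpy(float),
            index=weights["respondent_id"].astype(str),
        )
    return weights.astype(float)


def aggregate(
    items: pd.DataFrame,
    weights: pd.DataFrame | pd.Series,
    group: str = "",
) -> ComponentTotals:
    """Weighted sums of every canonical component and energy over *items*.

    *weights* is either a respondent table (uses ``day1_weight``) or a
    Series of weights indexed by respondent id; each item inherits its
    respondent's day-1 weight.
    """
    w = _weight_series(weights)
    item_w = items["respondent_id"].astype(str).map(w)
    if item_w.isna().any():
        missing = items.loc[item_w.isna(), "respondent_id"].unique()[:5]
        raise ScoringError(f"items reference respondents without weights: {list(missing)}")
    item_w = item_w.to_numpy(float)
    sums = {
        col: float(np.dot(items[col].to_numpy(float), item_w))
        for col in CANONICAL_COMPONENTS
    }
    energy = float(np.dot(items["energy_kcal"].to_numpy(float), item_w))
    return ComponentTotals(group=group, sums=sums, energy_kcal=energy)


def _density_from_totals(
    sums: Mapping[str, float], energy: float, standard: ScoringStandard
) -> float:
    if standard.unit == "fat_ratio":
        mono_poly = sums["mufa_g"] + sums["pufa_g"]
        sfa = sums["sfa_g"]
        if sfa == 0:
            return math.inf if mono_poly > 0 else 0.0
        return mono_poly / sfa
    amount = sums[standard.source] * standard.scale  # type: ignore[index]
    if standard.unit == "per_1000kcal":
        return amount / (energy / 1000.0)
    # percent of energy
    return 100.0 * amount * (standard.kcal_per_unit or 1.0) / energy


def densities(
    totals: ComponentTotals, standards: Sequence[ScoringStandard]
) -> dict[str, float]:
    """Translate weighted totals into per-component densities.

    Each density is the ratio of the group's weighted component total to its
    weighted energy total, in the component's scoring unit; the fatty-acid
    component is (MUFA+PUFA)/SFA.
    """
    if totals.energy_kcal <= 0:
        raise ScoringError(
            f"group {totals.group!r} has zero weighted energy; densities undefined"
        )
    return {
        s.component: _density_from_totals(totals.sums, totals.energy_kcal, s)
        for s in standards
    }


def score_component(density: float, standard: ScoringStandard) -> float:
    """Piecewise-linear score of one density against one standard.

    Adequacy/ratio components rise linearly from the zero-score cut-point to
    full points at the full-score cut-point; moderation components fall
    linearly from full points to zero.  Values beyond either cut-point are
    clamped.
    """
    if density < 0:
        raise ScoringError("density must be non-negative")
    if standard.direction == "moderation":
        frac = (standard.zero_score_at - density) / (
            standard.zero_score_at - standard.max_score_at
        )
    else:
        if math.isinf(density):
            return standard.max_points
        frac = (density - standard.zero_score_at) / (
            standard.max_score_at - standard.zero_score_at
        )
    return standard.max_points * min(1.0, max(0.0, frac))


def score_group(
    items: pd.DataFrame,
    weights: pd.DataFrame | pd.Series,
    standards: Sequence[ScoringStandard],
    group: str = "",
) -> HEIScoreSet:
    """Population-ratio HEI score of a weighted group of items."""
    totals = aggregate(items, weights, group)
    dens = densities(totals, standards)
    scores = {s.component: score_component(dens[s.component], s) for s in standards}
    return HEIScoreSet(group=group, component_scores=scores, total=sum(scores.values()))


def densities_for_scores(
    scores: Mapping[str, float], standards: Sequence[ScoringStandard]
) -> dict[str, float]:
    """Invert the piecewise-linear scoring map (used to build ground truth).

    For a target score strictly between 0 and the maximum the inverse is
    unique; at the end points the cut-point density itself is returned.
    """
    out: dict[str, float] = {}
    for s in standards:
        frac = scores[s.component] / s.max_points
        if not 0.0 <= frac <= 1.0:
            raise ScoringError(f"target score for {s.component!r} out of range")
        if s.direction == "moderation":
            out[s.component] = s.zero_score_at - frac * (s.zero_score_at - s.max_score_at)
        else:
            out[s.component] = s.zero_score_at + frac * (s.max_score_at - s.zero_score_at)
    return out


def grade(score: float, max_possible: float = 100.0) -> str:
    """A–F grade for a total or component score.

    Percentages of the maximum map to half-open bands: >=90 "A", 80–89.99
    "B", 70–79.99 "C", 60–69.99 "D", anything below 60 "F".
    """
    if not 0 <= score <= max_possible:
        raise ScoringError(f"score {score} outside [0, {max_possible}]")
    pct = 100.0 * score / max_possible
    for threshold, letter in ((90, "A"), (80, "B"), (70, "C"), (60, "D")):
        if pct >= threshold:
            return letter
    return "F"


def calorie_shares(
    items: pd.DataFrame,
    respondents: pd.DataFrame,
    age_bins: Sequence[tuple[float, float]],
    detailed: pd.Series | None = None,
) -> pd.DataFrame:
    """Percent of weighted calories obtained from each outlet, by age bin.

    *age_bins* are ``(low, high)`` intervals, low inclusive / high
    exclusive, that must partition ages from 2 upward.  Items are bucketed
    by their detailed outlet category (community food program, homegrown
    and other keep their own buckets), so each row sums to 100 for
    non-empty bins; empty bins yield a zero row and a logged warning.
    """
    from .outlet_mapping import DETAILED_CATEGORIES, categorize_items

    lows = sorted(b[0] for b in age_bins)
    if lows[0] != 2:
        raise ScoringError("age bins must start at age 2")
    cat = (
        categorize_items(items)["detailed"]
        if detailed is None
        else detailed
    )
    w = _weight_series(respondents)
    ages = pd.Series(
        respondents["age_years"].to_numpy(float),
        index=respondents["respondent_id"].astype(str),
    )
    item_w = items["respondent_id"].astype(str).map(w).to_numpy(float)
    item_age = items["respondent_id"].astype(str).map(ages).to_numpy(float)
    wk = items["energy_kcal"].to_numpy(float) * item_w

    rows = {}
    for low, high in age_bins:
        label = f"{low:g}-{high:g}" if math.isfinite(high) else f"{low:g}+"
        mask = (item_age >= low) & (item_age < high)
        totals = (
            pd.Series(wk[mask])
            .groupby(pd.Series(cat[mask].to_numpy()))
            .sum()
            .reindex(list(DETAILED_CATEGORIES), fill_value=0.0)
        )
        denom = totals.sum()
        if denom == 0:
            logger.warning("calorie_shares: age bin %s has no items", label)
            rows[label] = totals
        else:
            rows[label] = 100.0 * totals / denom
    out = pd.DataFrame(rows).T
    out.index.name = "age_bin"
    return out


def make_group_score_fn(
    items: pd.DataFrame,
    respondents: pd.DataFrame,
    standards: Sequence[ScoringStandard],
    outlets: Sequence[str] = ("store", "school", "full_service", "quick_service"),
    component: str | None = None,
) -> Callable[[object, np.ndarray | pd.Series], dict[str, float]]:
    """Build a fast per-outlet scoring statistic for replicate-weight loops.

    Returns ``fn(data, weights) -> {outlet: score}`` where *weights* is a
    vector aligned with *respondents* row order (or a Series indexed by
    respondent id).  Item-to-respondent and item-to-outlet assignments plus
    the component matrix are precomputed once, so evaluating the statistic
    under hundreds of replicate weight vectors costs a few matrix products.
    ``component=None`` scores the total; otherwise the named component.
    """
    from .outlet_mapping import select_group

    resp_ids = respondents["respondent_id"].astype(str)
    pos = pd.Series(np.arange(len(resp_ids)), index=resp_ids)
    columns = ("energy_kcal",) + CANONICAL_COMPONENTS
    per_outlet: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for outlet in outlets:
        sub = select_group(items, outlet)
        matrix = sub[list(columns)].to_numpy(float)
        idx = sub["respondent_id"].astype(str).map(pos).to_numpy(int)
        per_outlet[outlet] = (matrix, idx)

    def fn(_data: object, weights: np.ndarray | pd.Series) -> dict[str, float]:
        if isinstance(weights, pd.Series):
            w = weights.reindex(resp_ids).to_numpy(float)
        else:
            w = np.asarray(weights, float)
        out: dict[str, float] = {}
        for outlet, (matrix, idx) in per_outlet.items():
            totals_vec = matrix.T @ w[idx]
            sums = dict(zip(columns, totals_vec))
            energy = sums.pop("energy_kcal")
            if energy <= 0:
                raise ScoringError(f"group {outlet!r} has zero weighted energy")
            if component is None:
                out[outlet] = sum(
                    score_component(_density_from_totals(sums, energy, s), s)
                    for s in standards
                )
            else:
                (s,) = [s for s in standards if s.component == component]
                out[outlet] = score_component(
                    _density_from_totals(sums, energy, s), s
                )
        return out

    return fn
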