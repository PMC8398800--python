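"""Reading and filtering 24-h dietary recall microdata.

Handles respondent demographics and item-level recall tables in CSV or SAS
transport (XPT) dialects, links raw item columns to the canonical
pattern-equivalent components needed for HEI-2015 scoring, and applies the
standard eligibility filters (age >= 2 years, reliable recall, not consuming
human milk).

Canonical component columns are fixed: the 14 quantities the HEI-2015 needs
plus energy.  Legume amounts are expected to be pre-added into both the
vegetable and protein canonicals upstream (at the component-dictionary
level), following the HEI-2015 convention that legumes count toward both.
Missing component cells are treated as zero ("none consumed"), with the
number of imputed cells logged, so weighted totals stay additive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_COMPONENTS",
    "RESPONDENT_COLUMNS",
    "RecallDataError",
    "RespondentRecord",
    "FoodItemRecord",
    "ComponentDictionary",
    "read_table",
    "read_respondents",
    "read_items",
    "link_components",
    "apply_eligibility_filters",
]

#: Canonical per-item component columns (scoring inputs), excluding energy.
CANONICAL_COMPONENTS: tuple[str, ...] = (
    "total_fruits",
    "whole_fruits",
    "total_vegetables",
    "greens_and_beans",
    "whole_grains",
    "refined_grains",
    "dairy",
    "total_protein",
    "seafood_plant_protein",
    "mufa_g",
    "pufa_g",
    "sfa_g",
    "sodium_mg",
    "added_sugars_tsp",
)

RESPONDENT_COLUMNS: tuple[str, ...] = (
    "respondent_id",
    "cycle",
    "age_years",
    "day1_weight",
    "stratum",
    "psu",
    "recall_reliable",
    "consumes_human_milk",
)

ITEM_KEY_COLUMNS: tuple[str, ...] = ("respondent_id", "source_code", "energy_kcal")


class RecallDataError(ValueError):
    """Raised when a recall table violates its contract."""


@dataclass(frozen=True)
class RespondentRecord:
    """One survey respondent with design variables and day-1 dietary weight."""

    respondent_id: str
    cycle: str
    age_years: float
    day1_weight: float
    stratum: str
    psu: str
    recall_reliable: bool
    consumes_human_milk: bool


@dataclass(frozen=True)
class FoodItemRecord:
    """One reported food/beverage with energy and pattern-equivalent amounts."""

    respondent_id: str
    source_code: str
    energy_kcal: float
    components: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ComponentDictionary:
    """Per-cycle mapping of canonical component names to raw source columns.

    Real survey files rename pattern-equivalent columns across cycles; the
    dictionary keeps those names out of code.  A cycle key of ``"*"`` applies
    to every cycle.  Composite HEI quantities (e.g. whole fruits, legumes
    folded into vegetables and protein) must be pre-summed into a single
    derived source column before linkage, since each canonical name maps to
    exactly one column per cycle.
    """

    entries: Mapping[str, Mapping[str, str]]  # canonical -> {cycle -> column}

    @classmethod
    def from_csv(cls, path: str | Path) -> "ComponentDictionary":
        frame = pd.read_csv(path, dtype=str)
        required = {"canonical", "cycle", "source_column"}
        missing = required - set(frame.columns)
        if missing:
            raise RecallDataError(
                f"component dictionary {path} lacks columns: {sorted(missing)}"
            )
        entries: dict[str, dict[str, str]] = {}
        for row in frame.itertuples(index=False):
            per_cycle = entries.setdefault(row.canonical, {})
            if row.cycle in per_cycle:
                raise RecallDataError(
                    f"duplicate dictionary entry for {row.canonical!r} in cycle {row.cycle!r}"
                )
            per_cycle[row.cycle] = row.source_column
        return cls(entries=entries)

    @classmethod
    def synthetic(cls) -> "ComponentDictionary":
        """Identity dictionary for the synthetic-data dialect."""
        from importlib.resources import files

        return cls.from_csv(  # type: ignore[arg-type]
            files("outlethei.data") / "component_dictionary_synthetic.csv"
        )

    def column_for(self, canonical: str, cycle: str) -> str:
        per_cycle = self.entries.get(canonical)
        if per_cycle is None:
            raise RecallDataError(f"no dictionary entry for component {canonical!r}")
        if cycle in per_cycle:
            return per_cycle[cycle]
        if "*" in per_cycle:
            return per_cycle["*"]
        raise RecallDataError(
            f"component dictionary does not cover cycle {cycle!r} for {canonical!r}"
        )

    def covers_cycle(self, cycle: str) -> bool:
        try:
            for canonical in (*CANONICAL_COMPONENTS, "energy_kcal"):
                self.column_for(canonical, cycle)
        except RecallDataError:
            return False
        return True


def read_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a CSV or SAS transport (XPT) table into a DataFrame.

    The dialect is inferred from the file suffix when *format* is None.
    """
    path = Path(path)
    if not path.exists():
        raise RecallDataError(f"file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "xpt":
        frame = pd.read_sas(path, format="xport")
        # SAS transport stores strings as bytes
        for col in frame.columns:
            if frame[col].dtype == object:
                frame[col] = frame[col].map(
                    lambda v: v.decode() if isinstance(v, bytes) else v
                )
        return frame
    raise RecallDataError(f"unsupported format {fmt!r} (expected 'csv' or 'xpt')")


def _require_columns(frame: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise RecallDataError(f"{what} table is missing required column(s): {missing}")


def read_respondents(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read and validate a respondent demographics table.

    Returns one row per respondent with the columns of
    :data:`RESPONDENT_COLUMNS`.  Rows violating invariants (negative weight,
    negative age) raise :class:`RecallDataError` naming the offending row
    index.
    """
    frame = read_table(path, format)
    _require_columns(frame, RESPONDENT_COLUMNS, "respondent")
    frame = frame.loc[:, list(RESPONDENT_COLUMNS)].copy()
    frame["respondent_id"] = frame["respondent_id"].astype(str)
    frame["stratum"] = frame["stratum"].astype(str)
    frame["psu"] = frame["psu"].astype(str)
    frame["recall_reliable"] = frame["recall_reliable"].astype(bool)
    frame["consumes_human_milk"] = frame["consumes_human_milk"].astype(bool)
    for col, label in (("day1_weight", "weight"), ("age_years", "age")):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[values.isna() | (values < 0)]
        if len(bad):
            raise RecallDataError(
                f"negative or non-numeric {label} in respondent row(s) {list(bad[:10])}"
            )
        frame[col] = values.astype(float)
    dup = frame["respondent_id"].duplicated()
    if dup.any():
        raise RecallDataError(
            f"duplicate respondent_id in row(s) {list(frame.index[dup][:10])}"
        )
    return frame.reset_index(drop=True)


def read_items(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a raw item-level recall table (one row per reported food)."""
    frame = read_table(path, format)
    _require_columns(frame, ("respondent_id", "source_code"), "item")
    frame = frame.copy()
    frame["respondent_id"] = frame["respondent_id"].astype(str)
    frame["source_code"] = frame["source_code"].astype(str)
    return frame.reset_index(drop=True)


def link_components(
    items: pd.DataFrame, dictionary: ComponentDictionary, cycle: str
) -> pd.DataFrame:
    """Attach canonical pattern-equivalent columns to raw item rows.

    Every output row carries all canonical components plus ``energy_kcal``;
    missing cells are imputed as zero (absence encodes "none consumed") and
    the imputed count is logged to stderr.
    """
    if not dictionary.covers_cycle(cycle):
        raise RecallDataError(f"component dictionary does not cover cycle {cycle!r}")
    _require_columns(items, ("respondent_id", "source_code"), "item")
    carry = ["respondent_id", "source_code"] + (["cycle"] if "cycle" in items.columns else [])
    out = items.loc[:, carry].copy()
    n_imputed = 0
    for canonical in (*CANONICAL_COMPONENTS, "energy_kcal"):
        column = dictionary.column_for(canonical, cycle)
        if column in items.columns:
            values = pd.to_numeric(items[column], errors="coerce")
        else:
            values = pd.Series(np.nan, index=items.index)
        n_imputed += int(values.isna().sum())
        out[canonical] = values.fillna(0.0).astype(float)
    negative = (out[list(CANONICAL_COMPONENTS) + ["energy_kcal"]] < 0).any(axis=1)
    if negative.any():
        raise RecallDataError(
            f"negative component amount in item row(s) {list(out.index[negative][:10])}"
        )
    if n_imputed:
        logger.warning("link_components: imputed %d missing component cells as 0", n_imputed)
    return out


def apply_eligibility_filters(
    respondents: pd.DataFrame, items: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Apply the analytic-sample eligibility rules.

    Keeps respondents aged >= 2 years with a reliable day-1 recall who are
    not consuming human milk; kept items are exactly those of kept
    respondents.  Returns ``(respondents, items, tally)`` where *tally*
    counts exclusions per reason (a respondent is tallied under the first
    matching reason, in the order under_2, unreliable, human_milk).
    """
    _require_columns(
        respondents, ("respondent_id", "age_years", "recall_reliable", "consumes_human_milk"),
        "respondent",
    )
    under_2 = respondents["age_years"] < 2
    unreliable = ~respondents["recall_reliable"] & ~under_2
    human_milk = respondents["consumes_human_milk"] & ~under_2 & ~unreliable
    excluded = under_2 | unreliable | human_milk
    tally = {
        "under_2": int(under_2.sum()),
        "unreliable": int(unreliable.sum()),
        "human_milk": int(human_milk.sum()),
    }
    kept = respondents.loc[~excluded].reset_index(drop=True)
    kept_ids = set(kept["respondent_id"])
    kept_items = items.loc[items["respondent_id"].isin(kept_ids)].reset_index(drop=True)
    n_dropped = len(items) - len(kept_items)
    if n_dropped:
        logger.info("eligibility filters dropped %d item rows", n_dropped)
    return kept, kept_items, tally
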