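"""Food-outlet categorization of recall items.

Each reported food carries a "source" label or numeric code recording where
it was obtained.  Sources collapse into seven mutually exclusive detailed
categories — store, school, full-service restaurant, quick-service
restaurant, community food program, homegrown, other — of which the first
four are the analytic outlets; community/homegrown/other items appear only
in the all-outlets aggregate (too few reported foods for outlet-level
comparison).

The source -> category table ships as an editable two-column data file
(numeric codes and normalized text labels); unknown sources raise rather
than being silently bucketed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import pandas as pd

__all__ = [
    "DETAILED_CATEGORIES",
    "ANALYTIC_OUTLETS",
    "GROUPS",
    "OutletCategory",
    "UnknownSourceError",
    "load_source_table",
    "map_source",
    "categorize_items",
    "tabulate_categories",
    "select_group",
]

DETAILED_CATEGORIES: tuple[str, ...] = (
    "store",
    "school",
    "full_service",
    "quick_service",
    "community_food_program",
    "homegrown",
    "other",
)

#: Detailed categories promoted to analytic outlets; the rest map to "none".
ANALYTIC_OUTLETS: tuple[str, ...] = ("store", "school", "full_service", "quick_service")

#: Valid group names for selection (analytic outlets plus the aggregate).
GROUPS: tuple[str, ...] = ANALYTIC_OUTLETS + ("all_outlets",)


class UnknownSourceError(KeyError):
    """Raised for a source label/code absent from the mapping table."""


@dataclass(frozen=True)
class OutletCategory:
    detailed: str
    analytic: str  # one of ANALYTIC_OUTLETS or "none"

    def __post_init__(self) -> None:
        if self.detailed not in DETAILED_CATEGORIES:
            raise ValueError(f"unknown detailed category {self.detailed!r}")
        expected = self.detailed if self.detailed in ANALYTIC_OUTLETS else "none"
        if self.analytic != expected:
            raise ValueError(
                f"analytic category {self.analytic!r} inconsistent with detailed "
                f"{self.detailed!r} (expected {expected!r})"
            )


def _analytic(detailed: str) -> str:
    return detailed if detailed in ANALYTIC_OUTLETS else "none"


def _normalize(source: object) -> str:
    text = str(source).strip().lower().replace("–", "-").replace("—", "-")
    # numeric codes may arrive as floats from SAS/CSV readers ("3.0")
    try:
        return str(int(float(text)))
    except ValueError:
        return " ".join(text.split())


def load_source_table(path: str | Path | None = None) -> dict[str, str]:
    """Load the source -> detailed-category table (packaged default)."""
    src = path if path is not None else files("outlethei.data") / "food_sources.csv"
    frame = pd.read_csv(src, dtype=str)  # type: ignore[arg-type]
    table: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        key = _normalize(row.source)
        detailed = row.detailed.strip()
        if detailed not in DETAILED_CATEGORIES:
            raise ValueError(f"mapping table assigns unknown category {detailed!r}")
        if key in table and table[key] != detailed:
            raise ValueError(f"conflicting mapping for source {key!r}")
        table[key] = detailed
    return table


_DEFAULT_TABLE: dict[str, str] | None = None


def _default_table() -> dict[str, str]:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_source_table()
    return _DEFAULT_TABLE


def map_source(source: object, table: dict[str, str] | None = None) -> OutletCategory:
    """Map one source label or numeric code to its outlet category."""
    table = table if table is not None else _default_table()
    key = _normalize(source)
    try:
        detailed = table[key]
    except KeyError:
        raise UnknownSourceError(
            f"food source {source!r} is not in the outlet mapping table"
        ) from None
    return OutletCategory(detailed=detailed, analytic=_analytic(detailed))


def categorize_items(
    items: pd.DataFrame, table: dict[str, str] | None = None
) -> pd.DataFrame:
    """Return *items* with ``detailed`` and ``analytic`` outlet columns added."""
    table = table if table is not None else _default_table()
    out = items.copy()
    keys = items["source_code"].map(_normalize)
    unknown = sorted(set(keys) - set(table))
    if unknown:
        raise UnknownSourceError(
            f"food source(s) not in the outlet mapping table: {unknown[:10]}"
        )
    out["detailed"] = keys.map(table)
    out["analytic"] = out["detailed"].map(_analytic)
    return out


def tabulate_categories(
    items: pd.DataFrame,
    by_cycle: pd.Series | None = None,
    table: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Count items per detailed category (rows), optionally per cycle (columns).

    Row/column sums equal the item count; every detailed category appears
    even when empty.
    """
    if items.empty:
        cols = ["all"] if by_cycle is None else sorted(pd.unique(by_cycle))
        return pd.DataFrame(0, index=list(DETAILED_CATEGORIES), columns=cols or ["all"])
    cat = categorize_items(items, table)
    cycles = pd.Series("all", index=cat.index) if by_cycle is None else by_cycle
    counts = (
        pd.crosstab(cat["detailed"], cycles)
        .reindex(list(DETAILED_CATEGORIES), fill_value=0)
    )
    counts.index.name = "detailed"
    return counts


def select_group(
    items: pd.DataFrame,
    outlet: str,
    cycle: str | None = None,
    cycle_column: pd.Series | None = None,
    table: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Select the item subset for one analytic outlet or the aggregate.

    ``all_outlets`` keeps every item (including community food program,
    homegrown and other sources); a named outlet keeps items whose analytic
    category matches.
    """
    if outlet not in GROUPS:
        raise ValueError(f"unknown outlet {outlet!r}; expected one of {GROUPS}")
    out = items
    if cycle is not None and cycle_column is not None:
        out = out.loc[cycle_column == cycle]
    if outlet == "all_outlets":
        return out.reset_index(drop=True)
    cat = categorize_items(out, table)
    return out.loc[cat["analytic"] == outlet].reset_index(drop=True)
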