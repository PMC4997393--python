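"""Post-mapping quality checks: energy agreement, per-group range
outliers, resolution bookkeeping and the per-group agreement report.

Outlier screening uses, for each food group and label nutrient, the
minimum-maximum range observed in the generic reference catalog; branded
groups that have no direct reference equivalent resolve through an
explicit group list or a description keyword (e.g. a "frozen foods" group
built from every reference item whose description contains "frozen").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .mapping import blend_panel, pct_diff
from .model import (
    BOP_NUTRIENTS,
    BrandedItem,
    GenericFood,
    MappingResult,
    QCFlag,
)


@dataclass
class GroupRule:
    """How one branded food group resolves to reference items."""

    reference_groups: tuple[str, ...] = ()
    keyword: Optional[str] = None  # case-insensitive substring of description


@dataclass
class GroupRangeTable:
    """(group, nutrient) -> inclusive (min, max) per 100 g."""

    ranges: dict[tuple[str, str], tuple[float, float]]
    provenance: str = ""

    def get(self, group: str, nutrient: str) -> Optional[tuple[float, float]]:
        return self.ranges.get((group, nutrient))


def build_group_ranges(
    generics: Sequence[GenericFood],
    group_mapping: dict[str, GroupRule],
    nutrients: Sequence[str] = BOP_NUTRIENTS,
    provenance: str = "",
) -> GroupRangeTable:
    """Min/max per (target group, nutrient) over the resolved reference items.

    A nutrient absent from every resolved item produces no range row and
    downstream checks skip it; a group resolving to zero items is an error.
    """
    ranges: dict[tuple[str, str], tuple[float, float]] = {}
    for group, rule in group_mapping.items():
        members = [
            g for g in generics
            if g.food_group in rule.reference_groups
            or (rule.keyword and rule.keyword.lower() in g.description.lower())
        ]
        if not members:
            raise ValueError(f"group mapping resolves to zero reference items: {group}")
        for key in nutrients:
            values = [g.panel.get(key) for g in members]
            values = [v for v in values if v is not None]
            if values:
                ranges[(group, key)] = (min(values), max(values))
    return GroupRangeTable(ranges=ranges, provenance=provenance)


def energy_agreement_check(
    enriched_catalog: Sequence[BrandedItem],
    mappings: Sequence[MappingResult],
    generics: Sequence[GenericFood],
    threshold_pct: float = 100.0,
    epsilon: float = 0.1,
    cap: float = 1e9,
) -> list[QCFlag]:
    """Flag items whose blended generic energy strays far from the label.

    The percentage difference is taken relative to the label (back of
    pack) energy; |difference| > threshold flags the item.  The magnitude
    is recorded so extreme cases (diet drinks mapped to sugary generics
    can exceed 1000%) remain distinguishable from borderline ones.
    """
    index = {g.code: g for g in generics}
    by_item = {m.item_id: m for m in mappings}
    flags: list[QCFlag] = []
    for item in enriched_catalog:
        m = by_item.get(item.item_id)
        if m is None or item.panel.energy_kcal is None:
            continue
        blended = blend_panel(m.allocations, index)
        d = pct_diff(item.panel.energy_kcal, blended.energy_kcal,
                     epsilon=epsilon, cap=cap)
        if d is not None and abs(d) > threshold_pct:
            flags.append(QCFlag(
                flag_id=f"ea:{item.item_id}",
                item_id=item.item_id,
                rule_id="energy_agreement",
                nutrient_key="energy_kcal",
                observed=item.panel.energy_kcal,
                bound_low=None,
                bound_high=None,
                note=f"pct_diff={d:.1f}",
            ))
    return flags


@dataclass
class RangeCheckOutcome:
    flags: list[QCFlag]
    unchecked: list[str]  # item_ids whose group has no range rows


def range_outlier_check(
    catalog: Sequence[BrandedItem],
    range_table: GroupRangeTable,
    nutrients: Sequence[str] = BOP_NUTRIENTS,
) -> RangeCheckOutcome:
    """Flag nutrient values strictly outside their group's reference range.

    Boundary values count as in-range.  One item may raise several flags
    — a mis-entered record is typically wrong on more than one nutrient.
    Items whose group has no ranges at all are reported as unchecked,
    never silently passed.
    """
    flags: list[QCFlag] = []
    unchecked: list[str] = []
    for item in catalog:
        group_rows = [k for (grp, k) in range_table.ranges if grp == item.food_group]
        if not group_rows:
            unchecked.append(item.item_id)
            continue
        for key in nutrients:
            rng = range_table.get(item.food_group, key)
            value = item.panel.get(key)
            if rng is None or value is None:
                continue
            lo, hi = rng
            if value < lo or value > hi:
                flags.append(QCFlag(
                    flag_id=f"gr:{item.item_id}:{key}",
                    item_id=item.item_id,
                    rule_id="group_range",
                    nutrient_key=key,
                    observed=value,
                    bound_low=lo,
                    bound_high=hi,
                ))
    return RangeCheckOutcome(flags=flags, unchecked=unchecked)


@dataclass
class Resolution:
    flag_id: str
    outcome: str  # remove | update | keep
    new_value: Optional[float] = None


@dataclass
class ResolutionAudit:
    kept: int = 0
    updated: int = 0
    removed_flags: int = 0
    items_hidden: int = 0
    values_changed: list[tuple[str, str, float, float]] = field(default_factory=list)


def apply_resolutions(
    catalog: Sequence[BrandedItem],
    flags: Sequence[QCFlag],
    resolutions: Sequence[Resolution],
) -> tuple[list[BrandedItem], ResolutionAudit]:
    """Apply human verdicts to open flags.

    remove: the product is presumed discontinued — the item is hidden
    (status="hidden") and all its open flags close.  update: the value was
    reformulated — the flagged nutrient is replaced and the flag closes.
    keep: the outlier is genuine — value untouched, flag closes.
    Items are returned (copied) in input order; hidden items stay in the
    list so item counts are conserved: active out + hidden = in.
    """
    by_flag = {f.flag_id: f for f in flags}
    out = [it.copy() for it in catalog]
    by_item = {it.item_id: it for it in out}
    audit = ResolutionAudit()
    hidden: set[str] = set()

    for res in resolutions:
        flag = by_flag.get(res.flag_id)
        if flag is None:
            raise KeyError(f"resolution references unknown flag id: {res.flag_id}")
        item = by_item.get(flag.item_id)
        if item is None:
            raise KeyError(f"flag {flag.flag_id} references unknown item "
                           f"{flag.item_id}")
        if res.outcome == "keep":
            flag.resolution = "kept"
            audit.kept += 1
        elif res.outcome == "update":
            if res.new_value is None:
                raise ValueError(f"update resolution for {res.flag_id} "
                                 "requires new_value")
            old = item.panel.get(flag.nutrient_key)
            item.panel.set(flag.nutrient_key, res.new_value)
            flag.resolution = "updated"
            audit.updated += 1
            audit.values_changed.append(
                (item.item_id, flag.nutrient_key, old, res.new_value))
        elif res.outcome == "remove":
            item.status = "hidden"
            flag.resolution = "removed"
            audit.removed_flags += 1
            hidden.add(item.item_id)
            # a removed item closes all its other open flags
            for other in flags:
                if other.item_id == item.item_id and other.resolution == "pending":
                    other.resolution = "removed"
        else:
            raise ValueError(f"unknown resolution outcome: {res.outcome}")
    audit.items_hidden = len(hidden)
    return out, audit


def agreement_report(
    enriched_catalog: Sequence[BrandedItem],
    mappings: Sequence[MappingResult],
    generics: Sequence[GenericFood],
    within_pct: float = 10.0,
    epsilon: float = 0.1,
    cap: float = 1e9,
) -> tuple[pd.DataFrame, float]:
    """Per-group mapping agreement for energy, plus the overall share of
    items mapped within ``within_pct`` percent.

    Returns a table (group, count, pct_of_total, mean_pct_diff_energy)
    ordered by descending count, and the fraction (in %) of mapped items
    whose |percentage difference| on energy is <= within_pct.  The signed
    difference is generic blend relative to the label value, so groups
    whose products under-declare energy relative to their generic
    counterpart (diet drinks) come out positive.
    """
    index = {g.code: g for g in generics}
    by_item = {m.item_id: m for m in mappings}
    rows = []
    for item in enriched_catalog:
        m = by_item.get(item.item_id)
        if m is None or item.panel.energy_kcal is None:
            continue
        blended = blend_panel(m.allocations, index)
        d = pct_diff(item.panel.energy_kcal, blended.energy_kcal,
                     epsilon=epsilon, cap=cap)
        if d is not None:
            rows.append({"food_group": item.food_group, "pct_diff": d})
    if not rows:
        return (pd.DataFrame(columns=["food_group", "count", "pct_of_total",
                                      "mean_pct_diff_energy"]), float("nan"))
    df = pd.DataFrame(rows)
    table = (df.groupby("food_group")
               .agg(count=("pct_diff", "size"),
                    mean_pct_diff_energy=("pct_diff", "mean"))
               .reset_index())
    table["pct_of_total"] = 100.0 * table["count"] / table["count"].sum()
    table = table.sort_values(["count", "food_group"],
                              ascending=[False, True]).reset_index(drop=True)
    table = table[["food_group", "count", "pct_of_total", "mean_pct_diff_energy"]]
    share_within = 100.0 * (df["pct_diff"].abs() <= within_pct).mean()
    return table, share_within
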