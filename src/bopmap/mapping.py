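"""Candidate ranking and blend enumeration for micronutrient mapping.

A branded item is compared with generic reference foods on four macros
(energy, fat, protein, carbohydrate).  Each candidate is scored by the sum
of absolute percentage differences, percentages taken relative to the
branded (label) value, and candidates are ranked ascending so the closest
matches come first.  Two-food blends are enumerated on a percentage grid
(default 10% steps).  Chosen allocations then populate micronutrients by
allocation-weighted blending of the generic panels; the label macros are
never overwritten.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    Allocation,
    BOP_NUTRIENTS,
    BrandedItem,
    GenericFood,
    MappingResult,
    NutrientPanel,
    RANKING_NUTRIENTS,
)

#: Sentinel returned when two panels share no ranking nutrient.
INCOMPARABLE = None


@dataclass
class DistanceConfig:
    """Knobs of the percentage-difference score.

    epsilon floors the denominator so zero label values (diet drinks) do
    not divide out to infinity; per_nutrient_cap bounds any one nutrient's
    contribution so a single extreme ratio cannot dominate the ranking.
    """

    ranking_nutrients: tuple[str, ...] = RANKING_NUTRIENTS
    epsilon: float = 0.1
    per_nutrient_cap: float = 500.0
    step_percent: int = 10

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if 100 % self.step_percent != 0:
            raise ValueError("step_percent must divide 100")


def pct_diff(
    branded_value: Optional[float],
    reference_value: Optional[float],
    epsilon: float = 0.1,
    cap: float = 500.0,
) -> Optional[float]:
    """Signed percentage difference of reference vs branded label value.

    100 x (reference - branded) / max(branded, epsilon), clamped to
    [-cap, +cap].  Either value missing -> None (incomparable).
    """
    if branded_value is None or reference_value is None:
        return INCOMPARABLE
    denom = max(branded_value, epsilon)
    raw = 100.0 * (reference_value - branded_value) / denom
    return max(-cap, min(cap, raw))


def distance(
    branded_panel: NutrientPanel,
    candidate_panel: NutrientPanel,
    config: Optional[DistanceConfig] = None,
) -> Optional[float]:
    """Summed |percentage difference| over the ranking nutrients.

    Computed as the mean over nutrients present in BOTH panels, rescaled
    by the full nutrient count, so fully-populated panels give the plain
    four-nutrient sum while partially-populated panels stay comparable.
    Returns None when no ranking nutrient is shared.
    """
    cfg = config or DistanceConfig()
    diffs = []
    for key in cfg.ranking_nutrients:
        d = pct_diff(branded_panel.get(key), candidate_panel.get(key),
                     cfg.epsilon, cfg.per_nutrient_cap)
        if d is not None:
            diffs.append(abs(d))
    if not diffs:
        return INCOMPARABLE
    return sum(diffs) / len(diffs) * len(cfg.ranking_nutrients)


def rank_single(
    branded: BrandedItem,
    generics: Sequence[GenericFood],
    config: Optional[DistanceConfig] = None,
    top_k: int = 10,
) -> list[MappingResult]:
    """Rank single-generic candidates, ascending by distance.

    Ties break on generic code lexicographic order.  All-incomparable
    input yields an empty list with a warning.
    """
    if not generics:
        raise ValueError("generic catalog is empty")
    cfg = config or DistanceConfig()
    scored = []
    for g in generics:
        d = distance(branded.panel, g.panel, cfg)
        if d is not None:
            scored.append((d, g.code))
    if not scored:
        warnings.warn(f"item {branded.item_id}: no comparable generic candidates")
        return []
    scored.sort()
    return [
        MappingResult(
            item_id=branded.item_id,
            allocations=[Allocation(code, 100.0)],
            distance=d,
            rank=i + 1,
            method="auto_single",
        )
        for i, (d, code) in enumerate(scored[:top_k])
    ]


@dataclass
class BlendEnumeration:
    """Ranked blend candidates plus enumeration bookkeeping for audit."""

    results: list[MappingResult]
    evaluations: int  # pair x split evaluations before dedup
    unique_candidates: int


def enumerate_blends(
    branded: BrandedItem,
    group_a_generics: Sequence[GenericFood],
    group_b_generics: Sequence[GenericFood],
    config: Optional[DistanceConfig] = None,
    top_k: int = 10,
) -> BlendEnumeration:
    """Score every two-group blend on the percentage grid.

    For every pair (a, b) and split p in {0, step, ..., 100} the blended
    panel p%*a + (100-p)%*b is scored against the branded panel.  The
    degenerate splits p=0 and p=100 collapse to single foods and are
    deduplicated by canonical candidate key before ranking.
    """
    if not group_a_generics or not group_b_generics:
        raise ValueError("both generic lists must be non-empty")
    cfg = config or DistanceConfig()
    index = {g.code: g for g in (*group_a_generics, *group_b_generics)}
    splits = list(range(0, 101, cfg.step_percent))

    evaluations = 0
    seen: dict[tuple, list[Allocation]] = {}
    for a in group_a_generics:
        for b in group_b_generics:
            for p in splits:
                evaluations += 1
                if p == 100:
                    allocs = [Allocation(a.code, 100.0)]
                elif p == 0:
                    allocs = [Allocation(b.code, 100.0)]
                elif a.code == b.code:
                    allocs = [Allocation(a.code, 100.0)]
                else:
                    allocs = [Allocation(a.code, float(p)),
                              Allocation(b.code, float(100 - p))]
                key = tuple(sorted((al.generic_code, al.percent) for al in allocs))
                seen.setdefault(key, allocs)

    scored = []
    for key, allocs in seen.items():
        panel = blend_panel(allocs, index)
        d = distance(branded.panel, panel, cfg)
        if d is not None:
            scored.append((d, key, allocs))
    scored.sort(key=lambda t: (t[0], t[1]))
    results = [
        MappingResult(
            item_id=branded.item_id,
            allocations=allocs,
            distance=d,
            rank=i + 1,
            method="auto_blend",
        )
        for i, (d, _key, allocs) in enumerate(scored[:top_k])
    ]
    return BlendEnumeration(results=results, evaluations=evaluations,
                            unique_candidates=len(seen))


def blend_panel(
    allocations: Sequence[Allocation],
    generics_index: dict[str, GenericFood],
) -> NutrientPanel:
    """Allocation-weighted nutrient blend of the constituent generic panels.

    A nutrient missing from any constituent is missing from the blend —
    a partial weighted sum would understate the true content.
    """
    total = sum(a.percent for a in allocations)
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"allocation percents sum to {total}, expected 100")
    panels = []
    for a in allocations:
        if a.generic_code not in generics_index:
            raise KeyError(f"unresolvable generic code: {a.generic_code}")
        panels.append((a.percent / 100.0, generics_index[a.generic_code].panel))

    out = NutrientPanel()
    keys = {k for _, p in panels for k in (*BOP_NUTRIENTS, "salt_g")
            if p.get(k) is not None}
    keys |= {k for _, p in panels for k in p.micronutrients}
    for key in keys:
        values = [p.get(key) for _, p in panels]
        if any(v is None for v in values):
            continue
        out.set(key, sum(w * v for (w, _), v in zip(panels, values)))
    return out


@dataclass
class ApplyOutcome:
    catalog: list[BrandedItem]
    unmapped: list[str] = field(default_factory=list)


def apply_mappings(
    branded_catalog: Sequence[BrandedItem],
    mappings: Sequence[MappingResult],
    generics: Sequence[GenericFood],
) -> ApplyOutcome:
    """Populate micronutrients from the chosen allocations.

    The 8 label macros are never overwritten — except for items mapped by
    description alone (no usable label panel), where the blend fills both
    macros and micros.  Items without a mapping pass through unchanged and
    are listed as unmapped.
    """
    index = {g.code: g for g in generics}
    by_item: dict[str, MappingResult] = {}
    known = {it.item_id for it in branded_catalog}
    for m in mappings:
        if m.item_id not in known:
            raise KeyError(f"mapping references unknown item_id: {m.item_id}")
        best = by_item.get(m.item_id)
        if best is None or m.rank < best.rank:
            by_item[m.item_id] = m

    out: list[BrandedItem] = []
    unmapped: list[str] = []
    for item in branded_catalog:
        m = by_item.get(item.item_id)
        enriched = item.copy()
        if m is None:
            unmapped.append(item.item_id)
        else:
            blend = blend_panel(m.allocations, index)
            for key, value in blend.micronutrients.items():
                enriched.panel.micronutrients[key] = value
            if m.method == "description_only":
                for key in BOP_NUTRIENTS:
                    v = blend.get(key)
                    if v is not None:
                        enriched.panel.set(key, v)
        out.append(enriched)
    return ApplyOutcome(catalog=out, unmapped=unmapped)


def recipe_mapping(
    branded: BrandedItem,
    manual_allocations: Sequence[tuple[str, float]],
    generics: Sequence[GenericFood],
    config: Optional[DistanceConfig] = None,
) -> MappingResult:
    """Validate and renormalize a hand-coded recipe allocation.

    Percents must sum to 100 +/- 0.5 (label rounding slack) and are then
    renormalized to exactly 100; the distance against the implied blend is
    computed for audit.
    """
    total = sum(p for _, p in manual_allocations)
    if not (99.5 <= total <= 100.5):
        raise ValueError(
            f"recipe percents sum to {total}; must be within [99.5, 100.5]"
        )
    allocs = [Allocation(code, p * 100.0 / total) for code, p in manual_allocations]
    index = {g.code: g for g in generics}
    d = distance(branded.panel, blend_panel(allocs, index), config)
    return MappingResult(
        item_id=branded.item_id,
        allocations=allocs,
        distance=d,
        rank=1,
        method="manual_recipe",
    )
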