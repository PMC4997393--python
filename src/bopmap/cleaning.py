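"""Catalog cleaning: non-food removal, plausibility screens, error
suggestions, multipack collapsing and missing-panel population.

Cleaning never mutates nutrient values.  It partitions catalogs into
kept/removed sets and emits flags and suggestions; applying a correction
is a separate, human-reviewed resolution step (see :mod:`bopmap.qc`).
"""

from __future__ import annotations

import difflib
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    BOP_NUTRIENTS,
    BrandedItem,
    GenericFood,
    MappingResult,
    Allocation,
    QCFlag,
    Suggestion,
)

#: Maximum plausible label values per 100 g; values strictly above are
#: flagged for manual inspection (the stated cut-offs are "<= x" acceptable
#: ranges, so a value equal to the cut-off passes).
DEFAULT_GLOBAL_CUTOFFS: dict[str, float] = {
    "energy_kcal": 900.0,
    "carb_g": 99.9,
    "protein_g": 89.0,
    "sugars_g": 100.0,
    "fat_g": 99.9,
    "satfat_g": 86.0,
    "fibre_g": 54.0,
    "salt_g": 39.0,
}

DEFAULT_SEASONAL_KEYWORDS = ("easter", "christmas", "advent", "halloween")


@dataclass
class CleaningRuleSet:
    nonfood_keywords: tuple[str, ...] = ()
    seasonal_keywords: tuple[str, ...] = DEFAULT_SEASONAL_KEYWORDS
    multipack_policy: str = "remove_if_single_exists"  # or "keep"
    global_cutoffs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GLOBAL_CUTOFFS))


def _keyword_pattern(keywords: Sequence[str]) -> Optional[re.Pattern]:
    if not keywords:
        return None
    alts = "|".join(re.escape(k) for k in keywords)
    return re.compile(rf"\b(?:{alts})s?\b", re.IGNORECASE)


def remove_nonfood(
    catalog: Sequence[BrandedItem],
    ruleset: CleaningRuleSet,
) -> tuple[list[BrandedItem], list[BrandedItem]]:
    """Partition into (kept, removed) — non-food flags or keyword matches.

    Keywords match case-insensitively on whole words (an optional plural
    's' is tolerated, so "cigarette" removes "cigarettes 20 pack").
    """
    pat = _keyword_pattern(ruleset.nonfood_keywords)
    kept, removed = [], []
    for item in catalog:
        nonfood = (not item.is_food) or bool(pat and pat.search(item.description))
        (removed if nonfood else kept).append(item)
    return kept, removed


def remove_seasonal(
    catalog: Sequence[BrandedItem],
    ruleset: CleaningRuleSet,
) -> tuple[list[BrandedItem], list[BrandedItem]]:
    """Partition out seasonal-celebration items by description keyword."""
    pat = _keyword_pattern(ruleset.seasonal_keywords)
    kept, removed = [], []
    for item in catalog:
        seasonal = bool(pat and pat.search(item.description))
        (removed if seasonal else kept).append(item)
    return kept, removed


def flag_global_outliers(
    catalog: Sequence[BrandedItem],
    ruleset: Optional[CleaningRuleSet] = None,
) -> list[QCFlag]:
    """Flag every (item, nutrient) strictly above its plausibility cut-off.

    Salt is screened via its sodium-derived equivalent when not explicit.
    """
    rules = ruleset or CleaningRuleSet()
    flags: list[QCFlag] = []
    for item in catalog:
        for key, cutoff in rules.global_cutoffs.items():
            value = (item.panel.salt_equivalent_g() if key == "salt_g"
                     else item.panel.get(key))
            if value is not None and value > cutoff:
                flags.append(QCFlag(
                    flag_id=f"gmax:{item.item_id}:{key}",
                    item_id=item.item_id,
                    rule_id="global_max",
                    nutrient_key=key,
                    observed=value,
                    bound_low=0.0,
                    bound_high=cutoff,
                ))
    return flags


def detect_decimal_shift(
    item: BrandedItem,
    group_ranges: dict[tuple[str, str], tuple[float, float]],
) -> list[Suggestion]:
    """Suggest a x10 / /10 correction for out-of-range nutrient values.

    If a value falls outside its food group's reference range but the
    value shifted one decimal place lands inside it, the shift is the
    likely data-entry error.  Suggestions are never auto-applied.
    """
    suggestions: list[Suggestion] = []
    for key in BOP_NUTRIENTS:
        rng = group_ranges.get((item.food_group, key))
        value = item.panel.get(key)
        if rng is None or value is None:
            continue
        lo, hi = rng
        if lo <= value <= hi:
            continue
        for factor, label in ((0.1, "/10"), (10.0, "x10")):
            shifted = value * factor
            if lo <= shifted <= hi:
                suggestions.append(Suggestion(
                    item_id=item.item_id,
                    rule_id="decimal_shift",
                    nutrient_key=key,
                    observed=value,
                    proposed=shifted,
                    note=f"out of group range [{lo}, {hi}]; {label} lands in range",
                ))
                break
    return suggestions


def detect_salt_sodium_swap(item: BrandedItem) -> Optional[Suggestion]:
    """Suggest a swap when the salt field holds the sodium number.

    Pattern: salt_g numerically equals sodium expressed in grams while the
    proper conversion (sodium g x 2.5) disagrees by more than 20% — the
    two fields were filled with the same underlying number.
    """
    salt = item.panel.salt_g
    sodium = item.panel.sodium_mg
    if salt is None or sodium is None:
        return None
    sodium_g = sodium / 1000.0
    expected_salt = sodium_g * 2.5
    if abs(salt - sodium_g) < 1e-3 and expected_salt > 0:
        if abs(expected_salt - salt) / expected_salt > 0.20:
            return Suggestion(
                item_id=item.item_id,
                rule_id="salt_sodium_swap",
                nutrient_key="salt_g",
                observed=salt,
                proposed=expected_salt,
                note="salt field equals sodium in g; 2.5x conversion disagrees",
            )
    return None


_PACK_TOKENS = re.compile(r"\b\d+\s*(?:pack|x|multipack)\b", re.IGNORECASE)
_PUNCT = re.compile(r"[^\w\s]")


def _twin_key(item: BrandedItem) -> tuple[str, str]:
    """Brand + description normalized: lowercase, no punctuation, pack
    tokens stripped — multipacks and their single twin share this key."""
    desc = _PUNCT.sub(" ", item.description.lower())
    desc = _PACK_TOKENS.sub(" ", desc)
    desc = re.sub(r"\bmultipack\b", " ", desc)
    return item.brand.strip().lower(), " ".join(desc.split())


def _is_multipack(item: BrandedItem) -> bool:
    if item.multipack_count is not None and item.multipack_count >= 2:
        return True
    return bool(_PACK_TOKENS.search(item.description))


@dataclass
class MultipackOutcome:
    kept: list[BrandedItem]
    removed: list[BrandedItem]
    per_item_portions: dict[str, float]  # item_id -> grams per single item


def collapse_multipacks(
    catalog: Sequence[BrandedItem],
    policy: str = "remove_if_single_exists",
) -> MultipackOutcome:
    """Remove multipacks that duplicate a single item; derive per-item
    portions for the rest.

    A multipack whose brand + pack-token-stripped description matches a
    non-multipack item is redundant and removed (under the default
    policy).  A surviving multipack with a pack weight gains a "per item"
    portion of pack_weight_g / multipack_count.
    """
    singles = {_twin_key(it) for it in catalog if not _is_multipack(it)}
    kept, removed = [], []
    portions: dict[str, float] = {}
    for item in catalog:
        if not _is_multipack(item):
            kept.append(item)
            continue
        if policy == "remove_if_single_exists" and _twin_key(item) in singles:
            removed.append(item)
            continue
        kept.append(item)
        if item.multipack_count and item.multipack_count >= 2:
            if item.pack_weight_g is None:
                warnings.warn(
                    f"multipack {item.item_id} has a count but no pack weight")
            else:
                portions[item.item_id] = item.pack_weight_g / item.multipack_count
    return MultipackOutcome(kept=kept, removed=removed, per_item_portions=portions)


def token_set_similarity(a: str, b: str) -> float:
    """Order-insensitive description similarity on [0, 1].

    Tokenizes both strings, then takes the best difflib ratio among the
    sorted common-token string and each side's common+distinct string —
    robust to word order and to one description being a superset of the
    other.
    """
    ta = set(_PUNCT.sub(" ", a.lower()).split())
    tb = set(_PUNCT.sub(" ", b.lower()).split())
    if not ta or not tb:
        return 0.0
    common = " ".join(sorted(ta & tb))
    sa = (common + " " + " ".join(sorted(ta - tb))).strip()
    sb = (common + " " + " ".join(sorted(tb - ta))).strip()
    pairs = [(common, sa), (common, sb), (sa, sb)]
    return max(difflib.SequenceMatcher(None, x, y).ratio()
               for x, y in pairs if x or y)


@dataclass
class PanelPopulation:
    proposals: list[MappingResult]
    queued: list[str]  # item_ids needing manual review


def populate_missing_panels(
    branded: Sequence[BrandedItem],
    generics: Sequence[GenericFood],
    threshold: float = 0.6,
) -> PanelPopulation:
    """Propose description-only mappings for items with incomplete labels.

    Items lacking one or more of the 8 label nutrients (alcoholic drinks
    are the classic case — no mandatory label) are matched to the generic
    with the most similar description; both macros and micros will be
    filled from the generic when the mapping is applied.  Below-threshold
    matches are queued for manual review instead.
    """
    if not generics:
        raise ValueError("generic catalog is empty")
    proposals: list[MappingResult] = []
    queued: list[str] = []
    for item in branded:
        if not item.panel.missing_bop():
            continue
        best_score, best_code = 0.0, None
        for g in generics:
            s = token_set_similarity(item.description, g.description)
            if s > best_score or (s == best_score and best_code is not None
                                  and g.code < best_code):
                best_score, best_code = s, g.code
        if best_code is not None and best_score >= threshold:
            proposals.append(MappingResult(
                item_id=item.item_id,
                allocations=[Allocation(best_code, 100.0)],
                distance=None,
                rank=1,
                method="description_only",
            ))
        else:
            queued.append(item.item_id)
    return PanelPopulation(proposals=proposals, queued=queued)
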