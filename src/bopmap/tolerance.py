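"""EU FIC nutrition-declaration tolerance bands and negligible-amount rules.

Label values are legal "average values"; regulation grants each nutrient a
declared-value-dependent tolerance interval (inclusive of measurement
uncertainty) within which a measured or reference value is compliant.
Macronutrients use banded absolute/percent tolerances; vitamins and
minerals carry asymmetric percent tolerances.  All values are g per 100 g
unless noted (sodium is handled on a gram basis here, converted from the
catalog's mg where needed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence


@dataclass(frozen=True)
class Band:
    """One tolerance band: applies on [low, high) of the declared value."""

    low: float
    high: float  # exclusive; inf for the open top band
    abs_tol: Optional[float] = None     # +/- grams
    pct_tol: Optional[float] = None     # +/- percent of declared
    upper_pct: Optional[float] = None   # asymmetric percent, upward
    lower_pct: Optional[float] = None   # asymmetric percent, downward


@dataclass(frozen=True)
class ToleranceRule:
    nutrient_key: str
    bands: tuple[Band, ...]
    negligible_threshold: Optional[float] = None  # g per 100 g
    negligible_label: Optional[str] = None


_INF = float("inf")

# Banded scheme shared by carbohydrate, sugars, protein and fibre:
# <10 g: +/-2 g; 10-40 g: +/-20%; >40 g: +/-8 g.  Boundary membership:
# exactly 10 and exactly 40 fall in the percentage band.
_G2_BANDS = (
    Band(0.0, 10.0, abs_tol=2.0),
    Band(10.0, 40.0 + 1e-12, pct_tol=20.0),
    Band(40.0 + 1e-12, _INF, abs_tol=8.0),
)

_FAT_BANDS = (
    Band(0.0, 10.0, abs_tol=1.5),
    Band(10.0, 40.0 + 1e-12, pct_tol=20.0),
    Band(40.0 + 1e-12, _INF, abs_tol=8.0),
)

_SAT_BANDS = (
    Band(0.0, 4.0, abs_tol=0.8),
    Band(4.0, _INF, pct_tol=20.0),
)

DEFAULT_RULES: dict[str, ToleranceRule] = {
    "carb_g": ToleranceRule("carb_g", _G2_BANDS, 0.5, "<0.5 g"),
    "sugars_g": ToleranceRule("sugars_g", _G2_BANDS, 0.5, "<0.5 g"),
    "protein_g": ToleranceRule("protein_g", _G2_BANDS, 0.5, "<0.5 g"),
    "fibre_g": ToleranceRule("fibre_g", _G2_BANDS),
    "fat_g": ToleranceRule("fat_g", _FAT_BANDS, 0.5, "<0.5 g"),
    "satfat_g": ToleranceRule("satfat_g", _SAT_BANDS, 0.1, "<0.1 g"),
    "monounsat_g": ToleranceRule("monounsat_g", _SAT_BANDS),
    "polyunsat_g": ToleranceRule("polyunsat_g", _SAT_BANDS),
    "sodium_g": ToleranceRule("sodium_g", (
        Band(0.0, 0.5, abs_tol=0.15),
        Band(0.5, _INF, pct_tol=20.0),
    )),
    # Negligible salt: threshold and label as printed in the regulation
    # guidance (threshold 0.0125 g but label "<0.01 g").
    "salt_g": ToleranceRule("salt_g", (
        Band(0.0, 1.25, abs_tol=0.375),
        Band(1.25, _INF, pct_tol=20.0),
    ), 0.0125, "<0.01 g"),
    "vitamin": ToleranceRule("vitamin", (
        Band(0.0, _INF, upper_pct=50.0, lower_pct=35.0),
    )),
    "mineral": ToleranceRule("mineral", (
        Band(0.0, _INF, upper_pct=45.0, lower_pct=35.0),
    )),
}

#: Nutrient-key prefixes routed to the vitamin/mineral generic rules.
_VITAMIN_PREFIXES = ("vitamin", "folate", "thiamin", "riboflavin", "niacin", "biotin")
_MINERAL_KEYS = ("iron", "calcium", "zinc", "magnesium", "potassium", "iodine",
                 "selenium", "copper", "phosphorus", "manganese")


def _resolve(nutrient_key: str,
             rules: Optional[dict[str, ToleranceRule]] = None) -> ToleranceRule:
    table = rules or DEFAULT_RULES
    if nutrient_key in table:
        return table[nutrient_key]
    stem = nutrient_key.lower()
    if any(stem.startswith(p) for p in _VITAMIN_PREFIXES):
        return table["vitamin"]
    if any(stem.startswith(p) for p in _MINERAL_KEYS):
        return table["mineral"]
    raise KeyError(f"no tolerance rule for nutrient: {nutrient_key}")


def tolerance_bounds(
    nutrient_key: str,
    declared_value: float,
    rules: Optional[dict[str, ToleranceRule]] = None,
    vitamin_c_liquid_upper_multiplier: float = 1.0,
) -> tuple[float, float]:
    """Compliance interval (low, high) around a declared label value.

    ``vitamin_c_liquid_upper_multiplier`` widens the upper vitamin bound
    for vitamin C in liquids, where higher upper tolerances may be
    accepted; default 1.0 leaves the standard bound.
    """
    if declared_value < 0:
        raise ValueError("declared value must be >= 0")
    rule = _resolve(nutrient_key, rules)
    for band in rule.bands:
        if band.low <= declared_value < band.high:
            if band.abs_tol is not None:
                lo, hi = declared_value - band.abs_tol, declared_value + band.abs_tol
            elif band.pct_tol is not None:
                delta = declared_value * band.pct_tol / 100.0
                lo, hi = declared_value - delta, declared_value + delta
            else:
                up = band.upper_pct * vitamin_c_liquid_upper_multiplier
                lo = declared_value * (1 - band.lower_pct / 100.0)
                hi = declared_value * (1 + up / 100.0)
            return max(0.0, lo), hi
    raise ValueError(f"no band covers declared value {declared_value}")


def within_tolerance(
    nutrient_key: str,
    declared_value: float,
    reference_value: float,
    rules: Optional[dict[str, ToleranceRule]] = None,
) -> tuple[bool, float]:
    """Is a reference value inside the declared value's tolerance interval?

    Returns (ok, margin): margin is 0 inside the interval, otherwise the
    signed distance to the nearest violated bound (positive above the
    upper bound, negative below the lower one).
    """
    lo, hi = tolerance_bounds(nutrient_key, declared_value, rules)
    if reference_value > hi:
        return False, reference_value - hi
    if reference_value < lo:
        return False, reference_value - lo
    return True, 0.0


def negligible_declaration(
    nutrient_key: str,
    value: float,
    rules: Optional[dict[str, ToleranceRule]] = None,
) -> Optional[str]:
    """Label text when an amount is negligible, else None.

    Exactly zero declares "0 g"; values at or below the nutrient's
    negligible threshold declare the "<X g" form.
    """
    if value < 0:
        raise ValueError("value must be >= 0")
    rule = _resolve(nutrient_key, rules)
    if rule.negligible_threshold is None:
        return None
    if value == 0:
        return "0 g"
    if value <= rule.negligible_threshold:
        return rule.negligible_label
    return None


def check_catalog_tolerances(
    declared: Sequence[tuple[str, str, float, float]],
    rules: Optional[dict[str, ToleranceRule]] = None,
) -> list[dict]:
    """Batch check (item_id, nutrient_key, declared, reference) tuples."""
    out = []
    for item_id, key, dec, ref in declared:
        ok, margin = within_tolerance(key, dec, ref, rules)
        lo, hi = tolerance_bounds(key, dec, rules)
        out.append({
            "item_id": item_id, "nutrient_key": key, "declared": dec,
            "reference": ref, "low": lo, "high": hi,
            "within": ok, "margin": margin,
        })
    return out
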