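"""Domain types for branded ("Back of Pack") and generic food catalogs.

The eight label-declared nutrients per 100 g form the fixed macro panel;
everything else lives in an open-ended micronutrient map whose units are
fixed per key by a nutrient registry.  A blank label cell is *missing*,
never zero — the distinction is preserved end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

#: The 8 back-of-pack nutrients, per 100 g, in their label units.
BOP_NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "fat_g",
    "satfat_g",
    "carb_g",
    "sugars_g",
    "fibre_g",
    "sodium_mg",
)

#: The four macros used to rank generic candidates against a branded item.
RANKING_NUTRIENTS: tuple[str, ...] = ("energy_kcal", "fat_g", "protein_g", "carb_g")

#: EU labelling convention: salt (g) = sodium (g) x 2.5.
SALT_FROM_SODIUM = 2.5

#: Default micronutrient registry: key -> unit per 100 g.  The reference
#: dataset carries ~120 nutrient fields; the registry is extensible and this
#: default covers a representative panel.
DEFAULT_MICRONUTRIENTS: dict[str, str] = {
    "iron_mg": "mg",
    "calcium_mg": "mg",
    "zinc_mg": "mg",
    "magnesium_mg": "mg",
    "potassium_mg": "mg",
    "vitamin_a_ug": "ug",
    "vitamin_c_mg": "mg",
    "vitamin_d_ug": "ug",
    "vitamin_b12_ug": "ug",
    "folate_ug": "ug",
}


def default_registry() -> dict[str, str]:
    """Unit registry for all known nutrient keys (macros + default micros)."""
    reg = {k: ("kcal" if k == "energy_kcal" else "mg" if k == "sodium_mg" else "g")
           for k in BOP_NUTRIENTS}
    reg["salt_g"] = "g"
    reg.update(DEFAULT_MICRONUTRIENTS)
    return reg


@dataclass
class NutrientPanel:
    """Per-100 g nutrient vector.  Every field is individually optional."""

    energy_kcal: Optional[float] = None
    protein_g: Optional[float] = None
    fat_g: Optional[float] = None
    satfat_g: Optional[float] = None
    carb_g: Optional[float] = None
    sugars_g: Optional[float] = None
    fibre_g: Optional[float] = None
    sodium_mg: Optional[float] = None
    salt_g: Optional[float] = None
    micronutrients: dict[str, float] = field(default_factory=dict)

    def get(self, key: str) -> Optional[float]:
        if key in BOP_NUTRIENTS or key == "salt_g":
            return getattr(self, key)
        return self.micronutrients.get(key)

    def set(self, key: str, value: Optional[float]) -> None:
        if key in BOP_NUTRIENTS or key == "salt_g":
            setattr(self, key, value)
        elif value is None:
            self.micronutrients.pop(key, None)
        else:
            self.micronutrients[key] = value

    def salt_equivalent_g(self) -> Optional[float]:
        """Salt in g: the explicit value, else derived from sodium."""
        if self.salt_g is not None:
            return self.salt_g
        if self.sodium_mg is not None:
            return self.sodium_mg / 1000.0 * SALT_FROM_SODIUM
        return None

    def missing_bop(self) -> tuple[str, ...]:
        return tuple(k for k in BOP_NUTRIENTS if getattr(self, k) is None)

    def validate(self, atol: float = 0.01) -> list[str]:
        """Internal-consistency problems, empty when the panel is coherent.

        Saturates may not exceed total fat and sugars may not exceed total
        carbohydrate (within a rounding tolerance); an explicit salt value
        must agree with sodium under the 2.5 conversion.
        """
        problems: list[str] = []
        for k in BOP_NUTRIENTS:
            v = getattr(self, k)
            if v is not None and v < 0:
                problems.append(f"{k} negative ({v})")
        for k, v in self.micronutrients.items():
            if v < 0:
                problems.append(f"{k} negative ({v})")
        if self.satfat_g is not None and self.fat_g is not None:
            if self.satfat_g > self.fat_g + atol:
                problems.append(f"satfat_g {self.satfat_g} > fat_g {self.fat_g}")
        if self.sugars_g is not None and self.carb_g is not None:
            if self.sugars_g > self.carb_g + atol:
                problems.append(f"sugars_g {self.sugars_g} > carb_g {self.carb_g}")
        if self.salt_g is not None and self.sodium_mg is not None:
            expected = self.sodium_mg / 1000.0 * SALT_FROM_SODIUM
            if not math.isclose(self.salt_g, expected, abs_tol=1e-6):
                problems.append(
                    f"salt_g {self.salt_g} inconsistent with sodium_mg "
                    f"{self.sodium_mg} (expected {expected})"
                )
        return problems

    def copy(self) -> "NutrientPanel":
        return replace(self, micronutrients=dict(self.micronutrients))


@dataclass
class BrandedItem:
    """A branded product record with label provenance and pack metadata."""

    item_id: str
    description: str
    brand: str = ""
    barcode: Optional[str] = None
    food_group: str = ""
    panel: NutrientPanel = field(default_factory=NutrientPanel)
    pack_weight_g: Optional[float] = None
    multipack_count: Optional[int] = None
    serving_descriptions: list[tuple[str, float]] = field(default_factory=list)
    is_food: bool = True
    status: str = "active"  # active | hidden | removed

    def copy(self) -> "BrandedItem":
        return replace(
            self,
            panel=self.panel.copy(),
            serving_descriptions=list(self.serving_descriptions),
        )


@dataclass
class GenericFood:
    """A reference food code with a full macro + micronutrient panel."""

    code: str
    description: str
    food_group: str = ""
    panel: NutrientPanel = field(default_factory=NutrientPanel)

    def copy(self) -> "GenericFood":
        return replace(self, panel=self.panel.copy())


@dataclass(frozen=True)
class Allocation:
    """The percentage weight one generic code contributes to a blend."""

    generic_code: str
    percent: float

    def __post_init__(self) -> None:
        if not (0 < self.percent <= 100):
            raise ValueError(
                f"allocation percent must be in (0, 100], got {self.percent}"
            )


@dataclass
class MappingResult:
    """A ranked candidate allocation of generic codes to one branded item."""

    item_id: str
    allocations: list[Allocation]
    distance: Optional[float]
    rank: int = 1
    method: str = "auto_single"  # auto_single | auto_blend | manual_recipe | description_only

    def __post_init__(self) -> None:
        codes = [a.generic_code for a in self.allocations]
        if len(codes) != len(set(codes)):
            raise ValueError(f"duplicate generic_code in allocations: {codes}")
        total = sum(a.percent for a in self.allocations)
        if self.allocations and not math.isclose(total, 100.0, abs_tol=1e-6):
            raise ValueError(f"allocation percents sum to {total}, expected 100")


@dataclass
class QCFlag:
    """One rule violation on one (item, nutrient) with its resolution state."""

    flag_id: str
    item_id: str
    rule_id: str
    nutrient_key: Optional[str] = None
    observed: Optional[float] = None
    bound_low: Optional[float] = None
    bound_high: Optional[float] = None
    resolution: str = "pending"  # pending | kept | updated | removed
    note: str = ""


@dataclass
class Suggestion:
    """A proposed (never auto-applied) correction to one nutrient value."""

    item_id: str
    rule_id: str
    nutrient_key: str
    observed: float
    proposed: float
    note: str = ""


@dataclass
class RejectRecord:
    """A row or cell that failed parsing; collected, never silently dropped."""

    row: int
    record_id: str
    field: str
    raw_value: str
    reason: str
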