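"""Deterministic synthetic branded/generic catalog generator.

Emulates the statistical structure the pipeline assumes: a generic
reference catalog with group-specific macro profiles and micronutrient
panels, and a branded catalog in which each product derives from one
generic (or a two-generic blend on the percentage grid) with
multiplicative label noise, plus injected data pathologies — decimal
shifts, salt/sodium swaps, missing label panels, multipacks and "diet"
variants.  Every draw flows from one seeded random stream, so a fixed
seed reproduces catalogs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    BOP_NUTRIENTS,
    BrandedItem,
    DEFAULT_MICRONUTRIENTS,
    GenericFood,
    NutrientPanel,
    SALT_FROM_SODIUM,
)

#: Per-group plausible macro ranges (low, high per 100 g), all inside the
#: global plausibility cut-offs.  Groups echo a retail food taxonomy.
_GROUP_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "cakes_biscuits_snacks": {"energy_kcal": (350, 550), "protein_g": (3, 9),
                              "fat_g": (10, 30), "carb_g": (45, 75),
                              "sugars_g": (15, 45), "satfat_g": (4, 15),
                              "fibre_g": (1, 6), "sodium_mg": (100, 600)},
    "alcoholic_drinks": {"energy_kcal": (30, 300), "protein_g": (0.1, 1),
                         "fat_g": (0.1, 0.5), "carb_g": (1, 25),
                         "sugars_g": (0.5, 20), "satfat_g": (0.1, 0.3),
                         "fibre_g": (0.1, 0.5), "sodium_mg": (5, 60)},
    "sauces_condiments": {"energy_kcal": (40, 450), "protein_g": (0.5, 6),
                          "fat_g": (0.5, 40), "carb_g": (4, 30),
                          "sugars_g": (2, 25), "satfat_g": (0.1, 6),
                          "fibre_g": (0.3, 3), "sodium_mg": (200, 1400)},
    "dairy_eggs": {"energy_kcal": (40, 400), "protein_g": (3, 25),
                   "fat_g": (0.5, 35), "carb_g": (1, 15),
                   "sugars_g": (1, 12), "satfat_g": (0.3, 20),
                   "fibre_g": (0.1, 0.5), "sodium_mg": (40, 800)},
    "ready_meals": {"energy_kcal": (80, 250), "protein_g": (4, 14),
                    "fat_g": (2, 12), "carb_g": (8, 25),
                    "sugars_g": (1, 6), "satfat_g": (0.5, 5),
                    "fibre_g": (1, 4), "sodium_mg": (200, 800)},
    "bread_grains": {"energy_kcal": (220, 380), "protein_g": (7, 14),
                     "fat_g": (1, 8), "carb_g": (40, 75),
                     "sugars_g": (1, 8), "satfat_g": (0.2, 2),
                     "fibre_g": (2, 9), "sodium_mg": (300, 600)},
    "meat_poultry": {"energy_kcal": (100, 350), "protein_g": (15, 30),
                     "fat_g": (2, 25), "carb_g": (0.1, 5),
                     "sugars_g": (0.1, 2), "satfat_g": (0.5, 10),
                     "fibre_g": (0.1, 0.5), "sodium_mg": (60, 1200)},
    "fruit_vegetables": {"energy_kcal": (15, 120), "protein_g": (0.5, 4),
                         "fat_g": (0.1, 1.5), "carb_g": (2, 25),
                         "sugars_g": (1, 20), "satfat_g": (0.1, 0.3),
                         "fibre_g": (1, 7), "sodium_mg": (2, 100)},
    "frozen_foods": {"energy_kcal": (60, 300), "protein_g": (2, 15),
                     "fat_g": (1, 18), "carb_g": (5, 35),
                     "sugars_g": (0.5, 10), "satfat_g": (0.3, 7),
                     "fibre_g": (0.5, 5), "sodium_mg": (50, 700)},
    "soft_drinks": {"energy_kcal": (1, 55), "protein_g": (0.1, 0.5),
                    "fat_g": (0.1, 0.3), "carb_g": (0.5, 14),
                    "sugars_g": (0.5, 13), "satfat_g": (0.1, 0.2),
                    "fibre_g": (0.1, 0.3), "sodium_mg": (2, 40)},
}

_ADJECTIVES = ("classic", "original", "finest", "family", "organic",
               "smooth", "crunchy", "golden", "rich", "light")
_BRANDS = ("Redgate", "Ambervale", "Northfield", "Calder & Sons", "Brookhouse",
           "Farleigh", "Westmoor", "Hartley Row", "Ainsdale", "Queensferry")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic catalog pair.

    Defaults give a desk-scale catalog: 8 reference groups of 25 generics
    (200 codes) and 500 branded items carrying 5% multiplicative label
    noise on the four ranking macros, with low single-digit error rates
    typical of hand-keyed label data.
    """

    seed: int = 0
    n_groups: int = 8
    n_generics_per_group: int = 25
    n_branded: int = 500
    noise_sd_pct: float = 5.0
    error_rates: dict[str, float] = field(default_factory=lambda: {
        "decimal_shift": 0.0,
        "salt_swap": 0.0,
        "missing_panel": 0.0,
        "multipack": 0.0,
        "diet_variant": 0.0,
    })
    blend_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name, p in self.error_rates.items():
            if not 0 <= p <= 1:
                raise ValueError(f"error rate {name}={p} outside [0, 1]")
        if not 0 <= self.blend_fraction <= 1:
            raise ValueError("blend_fraction must lie in [0, 1]")
        if self.n_groups > len(_GROUP_PROFILES):
            raise ValueError(
                f"at most {len(_GROUP_PROFILES)} groups available")


def generate_generics(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[GenericFood], pd.DataFrame]:
    """Generic reference catalog plus a truth table of group macro ranges."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    groups = list(_GROUP_PROFILES)[: config.n_groups]
    foods: list[GenericFood] = []
    truth_rows = []
    for gi, group in enumerate(groups):
        profile = _GROUP_PROFILES[group]
        for j in range(config.n_generics_per_group):
            panel = NutrientPanel()
            for key in BOP_NUTRIENTS:
                lo, hi = profile[key]
                panel.set(key, round(float(rng.uniform(lo, hi)), 2))
            # keep the panel internally coherent
            if panel.satfat_g > panel.fat_g:
                panel.satfat_g = round(panel.fat_g * 0.5, 2)
            if panel.sugars_g > panel.carb_g:
                panel.sugars_g = round(panel.carb_g * 0.8, 2)
            for key in DEFAULT_MICRONUTRIENTS:
                panel.micronutrients[key] = round(float(rng.uniform(0.01, 20.0)), 3)
            adj = _ADJECTIVES[int(rng.integers(len(_ADJECTIVES)))]
            foods.append(GenericFood(
                code=f"G{gi:02d}{j:03d}",
                description=f"{group.replace('_', ' ')} item {j} {adj}",
                food_group=group,
                panel=panel,
            ))
        for key in BOP_NUTRIENTS:
            vals = [f.panel.get(key) for f in foods if f.food_group == group]
            truth_rows.append({"food_group": group, "nutrient": key,
                               "min": min(vals), "max": max(vals)})
    return foods, pd.DataFrame(truth_rows)


def _noisy(value: float, sd_pct: float, rng: np.random.Generator) -> float:
    """Log-normal multiplicative noise: positive, scales with magnitude."""
    if sd_pct == 0:
        return value
    sigma = np.log1p(sd_pct / 100.0)
    return float(value * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def generate_branded(
    config: SimulationConfig,
    generics: list[GenericFood],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[BrandedItem], pd.DataFrame]:
    """Branded catalog derived from the generics, plus a truth table.

    The truth table records, per item: the parent code (or blend codes and
    the grid split) and every injected error with the original value, so
    detection sensitivity is measurable exactly.
    """
    if not generics:
        raise ValueError("generics must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n_groups = len({g.food_group for g in generics})
    if config.blend_fraction > 0 and n_groups < 2:
        raise ValueError("blend_fraction > 0 requires generics from >= 2 groups")

    by_group: dict[str, list[GenericFood]] = {}
    for g in generics:
        by_group.setdefault(g.food_group, []).append(g)
    groups = sorted(by_group)

    items: list[BrandedItem] = []
    truth_rows = []
    for i in range(config.n_branded):
        item_id = f"B{i:05d}"
        brand = _BRANDS[int(rng.integers(len(_BRANDS)))]
        is_blend = bool(rng.random() < config.blend_fraction)
        row: dict[str, object] = {"item_id": item_id, "is_blend": is_blend,
                                  "parent_code": None, "blend_codes": None,
                                  "blend_split": None}
        panel = NutrientPanel()
        if is_blend:
            ga, gb = rng.choice(len(groups), size=2, replace=False)
            a = by_group[groups[ga]][int(rng.integers(len(by_group[groups[ga]])))]
            b = by_group[groups[gb]][int(rng.integers(len(by_group[groups[gb]])))]
            p = int(rng.integers(1, 10)) * 10  # interior split on the 10% grid
            parent_group = a.food_group if p >= 50 else b.food_group
            for key in BOP_NUTRIENTS:
                va, vb = a.panel.get(key), b.panel.get(key)
                base = p / 100.0 * va + (100 - p) / 100.0 * vb
                panel.set(key, round(_noisy(base, config.noise_sd_pct, rng), 2))
            desc = f"{a.description} & {b.description} blend"
            row.update(blend_codes=f"{a.code}|{b.code}", blend_split=p)
        else:
            parent = generics[int(rng.integers(len(generics)))]
            parent_group = parent.food_group
            for key in BOP_NUTRIENTS:
                panel.set(key, round(_noisy(parent.panel.get(key),
                                            config.noise_sd_pct, rng), 2))
            desc = f"{brand} {parent.description}"
            row.update(parent_code=parent.code)

        item = BrandedItem(
            item_id=item_id,
            description=desc,
            brand=brand,
            barcode=f"50{int(rng.integers(10**10, 10**11))}",
            food_group=parent_group,
            panel=panel,
            pack_weight_g=round(float(rng.uniform(100, 1000)), 0),
            is_food=True,
        )
        row["errors"] = _inject_errors(item, config, rng, truth_rows)
        items.append(item)
        truth_rows.append({**row, "error": None, "nutrient": None,
                           "original": None, "kind": "item"})
    truth = pd.DataFrame(truth_rows)
    return items, truth


def _inject_errors(
    item: BrandedItem,
    config: SimulationConfig,
    rng: np.random.Generator,
    truth_rows: list[dict],
) -> str:
    """Mutate one item in place per the configured error rates; record
    each injection in the truth table.  Returns a summary string."""
    rates = config.error_rates
    applied: list[str] = []

    if rng.random() < rates.get("decimal_shift", 0.0):
        key = BOP_NUTRIENTS[int(rng.integers(len(BOP_NUTRIENTS)))]
        original = item.panel.get(key)
        item.panel.set(key, original * 10.0)
        applied.append("decimal_shift")
        truth_rows.append({"item_id": item.item_id, "kind": "error",
                           "error": "decimal_shift", "nutrient": key,
                           "original": original, "is_blend": None,
                           "parent_code": None, "blend_codes": None,
                           "blend_split": None, "errors": None})

    if rng.random() < rates.get("salt_swap", 0.0) and item.panel.sodium_mg:
        # the label's salt field was filled with the sodium number
        sodium_g = item.panel.sodium_mg / 1000.0
        original = sodium_g * SALT_FROM_SODIUM
        item.panel.salt_g = round(sodium_g, 4)
        applied.append("salt_swap")
        truth_rows.append({"item_id": item.item_id, "kind": "error",
                           "error": "salt_swap", "nutrient": "salt_g",
                           "original": original, "is_blend": None,
                           "parent_code": None, "blend_codes": None,
                           "blend_split": None, "errors": None})

    if rng.random() < rates.get("missing_panel", 0.0):
        n_drop = int(rng.integers(1, len(BOP_NUTRIENTS) + 1))
        dropped = rng.choice(len(BOP_NUTRIENTS), size=n_drop, replace=False)
        for idx in dropped:
            key = BOP_NUTRIENTS[int(idx)]
            truth_rows.append({"item_id": item.item_id, "kind": "error",
                               "error": "missing_panel", "nutrient": key,
                               "original": item.panel.get(key), "is_blend": None,
                               "parent_code": None, "blend_codes": None,
                               "blend_split": None, "errors": None})
            item.panel.set(key, None)
        applied.append("missing_panel")

    if rng.random() < rates.get("multipack", 0.0):
        count = int(rng.integers(2, 13))
        item.multipack_count = count
        item.description = f"{item.description} {count} pack"
        if item.pack_weight_g:
            item.pack_weight_g = round(item.pack_weight_g * count, 0)
        applied.append("multipack")
        truth_rows.append({"item_id": item.item_id, "kind": "error",
                           "error": "multipack", "nutrient": None,
                           "original": float(count), "is_blend": None,
                           "parent_code": None, "blend_codes": None,
                           "blend_split": None, "errors": None})

    if rng.random() < rates.get("diet_variant", 0.0):
        original = item.panel.energy_kcal
        scale = float(rng.uniform(0.005, 0.05))  # residual energy <= 5%
        if original is not None:
            item.panel.energy_kcal = round(original * scale, 2)
        item.panel.sugars_g = 0.0
        item.description = f"{item.description} diet"
        applied.append("diet_variant")
        truth_rows.append({"item_id": item.item_id, "kind": "error",
                           "error": "diet_variant", "nutrient": "energy_kcal",
                           "original": original, "is_blend": None,
                           "parent_code": None, "blend_codes": None,
                           "blend_split": None, "errors": None})

    return "|".join(applied)


def generate_catalogs(
    config: SimulationConfig,
) -> tuple[list[GenericFood], list[BrandedItem], pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: one seeded stream drives both catalogs."""
    rng = np.random.default_rng(config.seed)
    generics, generic_truth = generate_generics(config, rng)
    branded, branded_truth = generate_branded(config, generics, rng)
    return generics, branded, generic_truth, branded_truth
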