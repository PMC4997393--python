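"""Portion assembly: merge serving-size sources by priority, derive
pack-based options and attach portion-image keys.

Primary serving weights come from a standard portion-size table (the FSA
Food Portion Sizes style source); an averaged-survey fallback table fills
food types the primary source lacks.  Pack weights and per-item multipack
weights are appended as additional options.  Food "type" is a
config-supplied grouping column — coarser than an item, finer than a food
group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import BrandedItem

IMAGES_PER_TYPE = 7


@dataclass(frozen=True)
class PortionOption:
    label: str
    grams: float
    source: str  # fsa | dante_average | pack | per_item | manual | image
    image_key: Optional[str] = None

    def __post_init__(self) -> None:
        if self.grams <= 0:
            raise ValueError(f"portion grams must be > 0, got {self.grams}")


def merge_portion_sources(
    item: BrandedItem,
    food_type: str,
    fsa_table: dict[str, list[tuple[str, float]]],
    fallback_table: dict[str, list[tuple[str, float]]],
    per_item_grams: Optional[float] = None,
    max_plausible_pack_g: float = 5000.0,
) -> list[PortionOption]:
    """Portion options for one item, primary source winning per food type.

    The fallback (survey-average) table is consulted only when the primary
    table has no entry for the food type.  A plausible pack weight adds a
    "whole pack" option; a multipack-derived single-item weight adds a
    "per item" option.  Labels are deduplicated, first source winning.
    """
    options: list[PortionOption] = []
    if food_type in fsa_table:
        options += [PortionOption(label, g, "fsa")
                    for label, g in fsa_table[food_type]]
    elif food_type in fallback_table:
        options += [PortionOption(label, g, "dante_average")
                    for label, g in fallback_table[food_type]]
    if item.pack_weight_g and 0 < item.pack_weight_g <= max_plausible_pack_g:
        options.append(PortionOption("whole pack", item.pack_weight_g, "pack"))
    if per_item_grams is not None:
        options.append(PortionOption("per item", per_item_grams, "per_item"))
    seen: dict[str, PortionOption] = {}
    for opt in options:
        seen.setdefault(opt.label, opt)
    return list(seen.values())


def attach_images(
    catalog: Sequence[BrandedItem],
    food_types: dict[str, str],
    image_map: dict[str, Sequence[str]],
) -> tuple[int, int, dict[str, list[PortionOption]]]:
    """Give items of image-mapped food types their portion-image options.

    Every mapped food type must carry exactly seven image keys (the seven
    portion-size photographs a user picks between); image lists may be
    shared across similar food types, and shared keys are counted once.

    Returns (items_with_images, distinct_image_keys, options_per_item).
    """
    for ftype, keys in image_map.items():
        if len(keys) != IMAGES_PER_TYPE:
            raise ValueError(
                f"food type {ftype!r} maps to {len(keys)} image keys; "
                f"exactly {IMAGES_PER_TYPE} required")
    options: dict[str, list[PortionOption]] = {}
    distinct: set[str] = set()
    for item in catalog:
        ftype = food_types.get(item.item_id)
        keys = image_map.get(ftype) if ftype else None
        if not keys:
            continue
        options[item.item_id] = [
            PortionOption(f"portion image {i + 1}", float(i + 1), "image",
                          image_key=key)
            for i, key in enumerate(keys)
        ]
        distinct.update(keys)
    return len(options), len(distinct), options
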