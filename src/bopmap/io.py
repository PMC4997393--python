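"""Readers and writers for catalogs, mapping files and QC reports.

All delimited files are UTF-8 comma-separated CSV with quoted text fields
and per-100 g values.  Numbers are serialized at 4 decimal places; blank
cells mean *missing* and never round-trip to 0.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    Allocation,
    BOP_NUTRIENTS,
    BrandedItem,
    GenericFood,
    MappingResult,
    NutrientPanel,
    QCFlag,
    RejectRecord,
    default_registry,
)

BRANDED_COLUMNS = [
    "item_id", "description", "brand", "barcode", "food_group",
    *BOP_NUTRIENTS, "pack_weight_g", "multipack_count", "is_food",
]

MAPPING_COLUMNS = ["item_id", "rank", "generic_code", "percent", "distance", "method"]

_NUM_FMT = "{:.4f}"


def _fmt(value: Optional[float]) -> str:
    return "" if value is None else _NUM_FMT.format(float(value))


def _parse_float(raw: object) -> Optional[float]:
    """Parse a cell to float; '' / NaN -> None; junk raises ValueError."""
    if raw is None:
        return None
    s = str(raw).strip()
    if s == "" or s.lower() == "nan":
        return None
    return float(s)


def _parse_bool(raw: object, default: bool = True) -> bool:
    s = str(raw).strip().lower()
    if s in ("", "nan"):
        return default
    return s in ("true", "1", "yes", "y", "t")


def read_branded_catalog(
    path: str | Path,
    schema_config: Optional[dict[str, str]] = None,
) -> tuple[list[BrandedItem], list[RejectRecord]]:
    """Read a branded-item catalog from CSV.

    ``schema_config`` maps canonical column names to the file's column
    names; unmapped columns use canonical names.  Cells that fail numeric
    coercion leave the field missing and produce a :class:`RejectRecord`.

    Raises ``ValueError`` when mandatory columns (item_id, description)
    are absent or when item_id values are duplicated.
    """
    colmap = dict(schema_config or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.rename(columns={v: k for k, v in colmap.items()})

    missing = [c for c in ("item_id", "description") if c not in df.columns]
    if missing:
        raise ValueError(f"branded catalog missing mandatory columns: {missing}")
    dupes = df["item_id"][df["item_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate item_id values: {dupes}")

    items: list[BrandedItem] = []
    rejects: list[RejectRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        item_id = str(row["item_id"])
        panel = NutrientPanel()
        for key in BOP_NUTRIENTS:
            if key not in row:
                continue
            try:
                panel.set(key, _parse_float(row[key]))
            except ValueError:
                rejects.append(RejectRecord(i, item_id, key, str(row[key]),
                                            "not a number"))
        extras: dict[str, Optional[float]] = {}
        for key in ("pack_weight_g", "multipack_count"):
            extras[key] = None
            if key in row:
                try:
                    extras[key] = _parse_float(row[key])
                except ValueError:
                    rejects.append(RejectRecord(i, item_id, key, str(row[key]),
                                                "not a number"))
        count = extras["multipack_count"]
        items.append(BrandedItem(
            item_id=item_id,
            description=str(row.get("description", "")),
            brand=str(row.get("brand", "")),
            barcode=str(row["barcode"]) or None if "barcode" in row else None,
            food_group=str(row.get("food_group", "")),
            panel=panel,
            pack_weight_g=extras["pack_weight_g"],
            multipack_count=int(count) if count is not None else None,
            is_food=_parse_bool(row.get("is_food", "")),
            status=str(row.get("status", "") or "active"),
        ))
    return items, rejects


def read_generic_catalog(
    path: str | Path,
    nutrient_registry: Optional[dict[str, str]] = None,
) -> tuple[list[GenericFood], list[RejectRecord]]:
    """Read a generic reference catalog from CSV.

    Micronutrient columns are recognised through the registry; unknown
    columns are reported as warnings.  Rows missing any of the four
    ranking macros (energy, fat, protein, carbohydrate) are rejected —
    they cannot participate in mapping.
    """
    registry = nutrient_registry if nutrient_registry is not None else default_registry()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    base = {"code", "description", "food_group", *BOP_NUTRIENTS, "salt_g"}
    micro_cols = [c for c in df.columns if c not in base and c in registry]
    unknown = [c for c in df.columns if c not in base and c not in registry]
    if unknown:
        warnings.warn(f"generic catalog has unregistered columns: {unknown}")

    if "code" not in df.columns:
        raise ValueError("generic catalog missing mandatory column: code")
    dupes = df["code"][df["code"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate generic codes: {dupes}")

    foods: list[GenericFood] = []
    rejects: list[RejectRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        code = str(row["code"])
        panel = NutrientPanel()
        bad = False
        for key in (*BOP_NUTRIENTS, *micro_cols):
            if key not in row:
                continue
            try:
                panel.set(key, _parse_float(row[key]))
            except ValueError:
                rejects.append(RejectRecord(i, code, key, str(row[key]),
                                            "not a number"))
        for key in ("energy_kcal", "fat_g", "protein_g", "carb_g"):
            if panel.get(key) is None:
                rejects.append(RejectRecord(i, code, key, "",
                                            "ranking macro missing"))
                bad = True
        if bad:
            continue
        foods.append(GenericFood(
            code=code,
            description=str(row.get("description", "")),
            food_group=str(row.get("food_group", "")),
            panel=panel,
        ))
    return foods, rejects


def write_branded_catalog(items: Sequence[BrandedItem], path: str | Path) -> None:
    rows = []
    for it in items:
        row: dict[str, object] = {
            "item_id": it.item_id,
            "description": it.description,
            "brand": it.brand,
            "barcode": it.barcode or "",
            "food_group": it.food_group,
        }
        for k in BOP_NUTRIENTS:
            row[k] = _fmt(it.panel.get(k))
        row["pack_weight_g"] = _fmt(it.pack_weight_g)
        row["multipack_count"] = "" if it.multipack_count is None else it.multipack_count
        row["is_food"] = it.is_food
        row["status"] = it.status
        for k, v in sorted(it.panel.micronutrients.items()):
            row[k] = _fmt(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_generic_catalog(foods: Sequence[GenericFood], path: str | Path) -> None:
    micro_keys = sorted({k for f in foods for k in f.panel.micronutrients})
    rows = []
    for f in foods:
        row: dict[str, object] = {
            "code": f.code, "description": f.description, "food_group": f.food_group,
        }
        for k in BOP_NUTRIENTS:
            row[k] = _fmt(f.panel.get(k))
        for k in micro_keys:
            row[k] = _fmt(f.panel.micronutrients.get(k))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_mappings(results: Iterable[MappingResult], path: str | Path) -> None:
    """One CSV row per allocation; multi-generic blends span several rows."""
    rows = []
    for r in results:
        for a in r.allocations:
            rows.append({
                "item_id": r.item_id,
                "rank": r.rank,
                "generic_code": a.generic_code,
                "percent": _fmt(a.percent),
                "distance": _fmt(r.distance),
                "method": r.method,
            })
    pd.DataFrame(rows, columns=MAPPING_COLUMNS).to_csv(path, index=False)


def read_mappings(path: str | Path) -> list[MappingResult]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    results: list[MappingResult] = []
    for (item_id, rank), grp in df.groupby(["item_id", "rank"], sort=False):
        allocs = [Allocation(str(r["generic_code"]), float(r["percent"]))
                  for r in grp.to_dict("records")]
        dist = grp.iloc[0]["distance"]
        results.append(MappingResult(
            item_id=str(item_id),
            allocations=allocs,
            distance=None if dist == "" else float(dist),
            rank=int(rank),
            method=str(grp.iloc[0]["method"]),
        ))
    return results


_QC_FIELDS = [f.name for f in dataclasses.fields(QCFlag)]


def write_report(records: Sequence, path: str | Path, format: str = "csv") -> None:
    """Write QC flags (or any flat dataclass records) as CSV or JSON-lines.

    Round-trip stable with :func:`read_qc_report` for QCFlag records.
    """
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unsupported report format: {format}")
    dicts = []
    for rec in records:
        d = dataclasses.asdict(rec)
        dicts.append({k: (_fmt(v) if isinstance(v, float) else v)
                      for k, v in d.items()})
    columns = list(dicts[0]) if dicts else (
        _QC_FIELDS if not records else None)
    if format == "csv":
        pd.DataFrame(dicts, columns=columns).to_csv(path, index=False)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for d in dicts:
                fh.write(json.dumps(d) + "\n")


def read_qc_report(path: str | Path, format: str = "csv") -> list[QCFlag]:
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        dicts = df.to_dict("records")
    elif format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            dicts = [json.loads(line) for line in fh if line.strip()]
    else:
        raise ValueError(f"unsupported report format: {format}")
    flags = []
    for d in dicts:
        flags.append(QCFlag(
            flag_id=str(d["flag_id"]),
            item_id=str(d["item_id"]),
            rule_id=str(d["rule_id"]),
            nutrient_key=str(d["nutrient_key"]) or None
            if d.get("nutrient_key") not in (None, "") else None,
            observed=_parse_float(d.get("observed")),
            bound_low=_parse_float(d.get("bound_low")),
            bound_high=_parse_float(d.get("bound_high")),
            resolution=str(d.get("resolution", "pending")),
            note=str(d.get("note", "") or ""),
        ))
    return flags
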