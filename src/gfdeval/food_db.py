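"""Food-composition data model and I/O.

A food is described per 100 g edible portion: energy, macronutrients, fibre
and cholesterol, plus the FODMAP compounds relevant to a gluten-free diet
(fructose, glucose, lactose, the polyols sorbitol and mannitol, the
galacto-oligosaccharides raffinose and stachyose, total fructan and inulin),
a NOVA processing group, a SENC food group, and — for manufactured
gluten-free rendered foods — a gluten-free-product (GFP) flag and category.

FODMAP values mix data sources of unequal coverage (a national composition
database, literature values for plant foods and pulses, and a laboratory
fructan assay for cereal foods), so a FODMAP field may be *missing*.
Missing is represented as ``None``, never coerced to zero; downstream
engines skip missing values and report coverage.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

from pydantic import BaseModel, Field, ValidationError, model_validator

SCHEMA_VERSION = "gfdeval-food-schema v1"

__all__ = [
    "SencGroup", "NovaGroup", "GFPCategory", "FructanSource",
    "FODMAPRecord", "FoodRecord", "FoodTable", "FructanResolution",
    "load_composition_table", "write_composition_table", "resolve_fructan",
    "default_food_table", "FoodTableError",
]


class SencGroup(str, Enum):
    dairy = "dairy"
    cereals = "cereals"
    vegetables = "vegetables"
    fruits = "fruits"
    oils = "oils"
    meat = "meat"
    fish = "fish"
    eggs = "eggs"
    legumes = "legumes"
    nuts = "nuts"
    pastries = "pastries"
    other = "other"


class NovaGroup(str, Enum):
    """NOVA processing groups: G1 unprocessed/minimally processed, G2
    processed culinary ingredients, G3 processed, G4 ultra-processed."""

    G1 = "G1"
    G2 = "G2"
    G3 = "G3"
    G4 = "G4"


class GFPCategory(str, Enum):
    bread = "bread"
    pasta = "pasta"
    cake_scone_bun_biscuit = "cake_scone_bun_biscuit"
    breakfast_cereals = "breakfast_cereals"
    cookies = "cookies"
    pizza = "pizza"
    cereal_bars = "cereal_bars"
    fajita_crepe_pancake = "fajita_crepe_pancake"
    other = "other"
    none = "none"


class FructanSource(str, Enum):
    """Provenance tier of a food's total-fructan value."""

    fsanz = "fsanz"                      # national DB: inulin only
    literature_plant = "literature_plant"
    literature_pulse = "literature_pulse"
    own_cereal_assay = "own_cereal_assay"
    unknown = "unknown"


FODMAP_FIELDS = (
    "fructose_g_100g", "glucose_g_100g", "lactose_g_100g",
    "sorbitol_g_100g", "mannitol_g_100g", "raffinose_g_100g",
    "stachyose_g_100g", "total_fructan_g_100g", "inulin_g_100g",
)


class FODMAPRecord(BaseModel):
    """Per-100 g FODMAP composition; ``None`` means unknown, not zero."""

    food_id: str
    fructose_g_100g: Optional[float] = Field(None, ge=0)
    glucose_g_100g: Optional[float] = Field(None, ge=0)
    lactose_g_100g: Optional[float] = Field(None, ge=0)
    sorbitol_g_100g: Optional[float] = Field(None, ge=0)
    mannitol_g_100g: Optional[float] = Field(None, ge=0)
    raffinose_g_100g: Optional[float] = Field(None, ge=0)
    stachyose_g_100g: Optional[float] = Field(None, ge=0)
    total_fructan_g_100g: Optional[float] = Field(None, ge=0)
    inulin_g_100g: Optional[float] = Field(None, ge=0)
    fructan_source: FructanSource = FructanSource.unknown

    @property
    def has_any_data(self) -> bool:
        return any(getattr(self, f) is not None for f in FODMAP_FIELDS)


class FoodRecord(BaseModel):
    """One food's composition per 100 g edible portion."""

    food_id: str
    name: str
    senc_group: SencGroup
    nova_group: NovaGroup
    is_gfp: bool = False
    gfp_category: GFPCategory = GFPCategory.none
    energy_kcal_100g: float = Field(ge=0)
    protein_g_100g: float = Field(ge=0)
    carb_g_100g: float = Field(ge=0)
    sugars_g_100g: float = Field(ge=0)
    lipid_g_100g: float = Field(ge=0)
    sfa_g_100g: float = Field(ge=0)
    fibre_g_100g: float = Field(ge=0)
    cholesterol_mg_100g: float = Field(ge=0)
    standard_portion_g: float = Field(gt=0)
    fodmap: FODMAPRecord

    @model_validator(mode="after")
    def _invariants(self) -> "FoodRecord":
        if self.sugars_g_100g > self.carb_g_100g + 1e-9:
            raise ValueError(
                f"{self.food_id}: sugars ({self.sugars_g_100g} g) exceed "
                f"carbohydrates ({self.carb_g_100g} g)")
        if self.sfa_g_100g > self.lipid_g_100g + 1e-9:
            raise ValueError(
                f"{self.food_id}: saturated fat ({self.sfa_g_100g} g) exceeds "
                f"total lipids ({self.lipid_g_100g} g)")
        if not self.is_gfp and self.gfp_category != GFPCategory.none:
            raise ValueError(
                f"{self.food_id}: gfp_category={self.gfp_category.value} on a "
                "food not flagged as gluten-free product")
        if self.is_gfp and self.gfp_category == GFPCategory.none:
            raise ValueError(f"{self.food_id}: GFP food requires a gfp_category")
        return self


class FoodTableError(Exception):
    """Raised on schema mismatch or row-level validation failure."""


@dataclass
class FructanResolution:
    value: Optional[float]          # g per 100 g, None when unknown
    provenance: FructanSource
    lower_bound: bool = False       # True when only inulin was available


class FoodTable:
    """Collection of validated :class:`FoodRecord`, keyed by ``food_id``."""

    def __init__(self, records: Iterable[FoodRecord]):
        self._foods: dict[str, FoodRecord] = {}
        for rec in records:
            if rec.food_id in self._foods:
                raise FoodTableError(f"duplicate food_id {rec.food_id!r}")
            self._foods[rec.food_id] = rec

    def __len__(self) -> int:
        return len(self._foods)

    def __iter__(self) -> Iterator[FoodRecord]:
        return iter(self._foods.values())

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._foods

    def __getitem__(self, food_id: str) -> FoodRecord:
        try:
            return self._foods[food_id]
        except KeyError:
            raise KeyError(f"unknown food_id {food_id!r}") from None

    def get(self, food_id: str) -> Optional[FoodRecord]:
        return self._foods.get(food_id)

    @property
    def food_ids(self) -> list[str]:
        return list(self._foods)

    def n_missing_fodmap(self) -> int:
        """Foods with at least one missing FODMAP field (no silent zero-fill)."""
        return sum(
            1 for r in self
            if any(getattr(r.fodmap, f) is None for f in FODMAP_FIELDS)
        )

    def select(self, predicate) -> list[FoodRecord]:
        return [r for r in self if predicate(r)]


_EXPECTED_COLUMNS = [
    "food_id", "name", "senc_group", "nova_group", "is_gfp", "gfp_category",
    "energy_kcal_100g", "protein_g_100g", "carb_g_100g", "sugars_g_100g",
    "lipid_g_100g", "sfa_g_100g", "fibre_g_100g", "cholesterol_mg_100g",
    "standard_portion_g", *FODMAP_FIELDS, "fructan_source",
]

_FLOAT_COLUMNS = {
    "energy_kcal_100g", "protein_g_100g", "carb_g_100g", "sugars_g_100g",
    "lipid_g_100g", "sfa_g_100g", "fibre_g_100g", "cholesterol_mg_100g",
    "standard_portion_g",
}


def _record_from_row(row: dict) -> FoodRecord:
    food_id = row.get("food_id", "<unknown>")
    fod_kwargs: dict = {"food_id": food_id}
    for f in FODMAP_FIELDS:
        v = row.get(f)
        fod_kwargs[f] = None if v is None or v == "" else float(v)
    fod_kwargs["fructan_source"] = row.get("fructan_source") or "unknown"
    kwargs: dict = {}
    for c in _EXPECTED_COLUMNS:
        if c in FODMAP_FIELDS or c == "fructan_source":
            continue
        v = row[c]
        if c in _FLOAT_COLUMNS:
            v = float(v)
        elif c == "is_gfp":
            if isinstance(v, bool):
                pass
            elif str(v).strip().lower() in ("true", "1", "yes"):
                v = True
            elif str(v).strip().lower() in ("false", "0", "no"):
                v = False
            else:
                raise ValueError(f"{food_id}: unparseable is_gfp {v!r}")
        kwargs[c] = v
    return FoodRecord(fodmap=FODMAPRecord(**fod_kwargs), **kwargs)


def load_composition_table(path: str | Path, dialect: str = "csv") -> FoodTable:
    """Load and validate a composition table (CSV or JSON array).

    A leading ``#`` comment line (schema version) is permitted in CSV.
    Raises :class:`FoodTableError` naming the offending column on schema
    mismatch, or listing the failing ``food_id`` on invariant violation.
    """
    path = Path(path)
    if not path.exists():
        raise FoodTableError(f"composition table not found: {path}")
    if dialect == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            first = fh.readline()
            if not first.startswith("#"):
                fh.seek(0)
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in _EXPECTED_COLUMNS if c not in header]
            if missing:
                raise FoodTableError(
                    f"schema mismatch in {path.name}: missing column(s) "
                    + ", ".join(missing))
            rows = list(reader)
    elif dialect == "json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        if rows:
            missing = [c for c in _EXPECTED_COLUMNS if c not in rows[0]]
            if missing:
                raise FoodTableError(
                    f"schema mismatch in {path.name}: missing column(s) "
                    + ", ".join(missing))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    records, errors = [], []
    for row in rows:
        try:
            records.append(_record_from_row(row))
        except (ValidationError, ValueError) as exc:
            errors.append(f"{row.get('food_id', '<unknown>')}: {exc}")
    if errors:
        raise FoodTableError(
            "validation failed for %d row(s):\n%s" % (len(errors), "\n".join(errors)))
    return FoodTable(records)


def write_composition_table(table: FoodTable, path: str | Path,
                            dialect: str = "csv") -> None:
    """Write a table back out; ``load(write(t)) == t`` on all fields."""
    path = Path(path)
    rows = []
    for r in table:
        row = {c: getattr(r, c) for c in _EXPECTED_COLUMNS
               if c not in FODMAP_FIELDS and c != "fructan_source"}
        row["senc_group"] = r.senc_group.value
        row["nova_group"] = r.nova_group.value
        row["gfp_category"] = r.gfp_category.value
        for f in FODMAP_FIELDS:
            v = getattr(r.fodmap, f)
            row[f] = "" if v is None else v
        row["fructan_source"] = r.fodmap.fructan_source.value
        rows.append(row)
    if dialect == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(f"# {SCHEMA_VERSION}\n")
            w = csv.DictWriter(fh, fieldnames=_EXPECTED_COLUMNS)
            w.writeheader()
            w.writerows(rows)
    elif dialect == "json":
        for row in rows:
            for f in FODMAP_FIELDS:
                if row[f] == "":
                    row[f] = None
        path.write_text(json.dumps(rows, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


_SOURCE_PRIORITY = {
    FructanSource.own_cereal_assay: 3,
    FructanSource.literature_plant: 2,
    FructanSource.literature_pulse: 2,
    FructanSource.fsanz: 1,
    FructanSource.unknown: 0,
}


def resolve_fructan(record: FODMAPRecord,
                    overrides: Optional[dict] = None) -> FructanResolution:
    """Pick the best available total-fructan value for one food.

    Priority: laboratory cereal assay > literature (plant or pulse) >
    inulin as a lower-bound stand-in (the national database reports inulin
    only). ``overrides`` maps ``food_id`` to ``(value_g_100g, source)`` and
    competes at its source's tier; on a tie the record's own value wins.
    Deterministic and independent of table row order.
    """
    candidates: list[tuple[int, int, float, FructanSource, bool]] = []
    # (tier, record-preferred rank, value, provenance, lower_bound)
    if record.total_fructan_g_100g is not None:
        src = record.fructan_source
        tier = _SOURCE_PRIORITY.get(src, 0)
        if tier == 0 and record.total_fructan_g_100g is not None:
            tier = 1  # value present but unlabelled: treat as weakest real tier
            src = FructanSource.unknown
        candidates.append((tier, 1, record.total_fructan_g_100g, src, False))
    if overrides and record.food_id in overrides:
        val, src = overrides[record.food_id]
        src = FructanSource(src)
        candidates.append((_SOURCE_PRIORITY.get(src, 2), 0, float(val), src, False))
    if record.inulin_g_100g is not None:
        candidates.append((_SOURCE_PRIORITY[FructanSource.fsanz], 1,
                           record.inulin_g_100g, FructanSource.fsanz, True))
    if not candidates:
        return FructanResolution(None, FructanSource.unknown)
    tier, _, value, src, lb = max(candidates, key=lambda c: (c[0], c[1]))
    return FructanResolution(value, src, lower_bound=lb)


def default_food_table() -> FoodTable:
    """The packaged fixture table (~54 foods spanning all SENC and NOVA
    groups and eight GFP categories)."""
    ref = resources.files("gfdeval.data").joinpath("foods.csv")
    with resources.as_file(ref) as p:
        return load_composition_table(p, dialect="csv")
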