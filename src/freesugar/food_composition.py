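"""Food composition table: loading, validation and regrouping.

The food table is the reference every downstream stage consumes: one row per
food code carrying total sugar (TS), lactose and energy per 100 g plus the
classification flags the free-sugar decision ladder reads.  Foods arrive in a
fine-grained source grouping (the Irish preschool survey used 77 groups for
1652 codes) and are re-categorised into 13 coarse groups chosen to isolate the
main free-sugar sources.

Units are fixed: sugars in g/100 g, energy in MJ/100 g.  Missing lactose or
energy means "not analysed" and is kept as ``None`` — it is *not* the same as
0 g, because the ladder's TS-minus-lactose rung requires an analysed value.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FoodGroup",
    "LadderFlags",
    "FoodItem",
    "ValidationReport",
    "FoodTableError",
    "load_food_table",
    "regroup",
    "validate_food_table",
    "load_regroup_scheme",
    "KJ_PER_KCAL",
]

#: kJ per kcal, used when a table declares kcal energy units.
KJ_PER_KCAL = 4.184


class FoodGroup(str, Enum):
    """The 13-group partition used to highlight the main free-sugar sources."""

    BREAD_AND_CEREALS = "bread_and_cereals"
    RTEBC = "rtebc"  # ready-to-eat breakfast cereals
    CAKES_AND_BISCUITS = "cakes_and_biscuits"
    DAIRY_PRODUCTS = "dairy_products"
    DESSERTS_AND_PUDDINGS = "desserts_and_puddings"
    FRUIT_AND_VEGETABLES = "fruit_and_vegetables"
    FRUIT_JUICE_AND_SMOOTHIES = "fruit_juice_and_smoothies"
    SUGAR_AND_SYRUPS = "sugar_and_syrups"
    CHOCOLATE_CONFECTIONARY = "chocolate_confectionary"
    NON_CHOCOLATE_CONFECTIONARY = "non_chocolate_confectionary"
    SOFT_DRINKS_NON_DIET = "soft_drinks_non_diet"
    SOFT_DRINKS_DIET = "soft_drinks_diet"
    OTHER = "other"


@dataclass(frozen=True)
class LadderFlags:
    """Classification flags consumed by the free-sugar decision ladder.

    ``is_unprocessed_whole_food`` marks intact fruit/vegetables and plain milk
    (intrinsic sugars only).  ``is_pure_sugar_product`` marks foods whose sugar
    is entirely free (table sugar, honey, syrups, confectionery, milk-free
    non-diet soft drinks).  The two are mutually exclusive.
    """

    is_unprocessed_whole_food: bool = False
    is_pure_sugar_product: bool = False
    is_fruit_juice: bool = False
    is_diet_beverage: bool = False
    has_unsweetened_equivalent: bool = False
    unsweetened_equivalent_code: str | None = None
    recipe_fraction_free: float | None = None

    def __post_init__(self) -> None:
        if self.recipe_fraction_free is not None and not (
            0.0 <= self.recipe_fraction_free <= 1.0
        ):
            raise ValueError(
                f"recipe_fraction_free must be in [0, 1], got {self.recipe_fraction_free}"
            )


@dataclass(frozen=True)
class FoodItem:
    """One food code with its composition and ladder classification."""

    food_code: str
    description: str
    source_group: str
    group: FoodGroup
    total_sugar_per100g: float
    lactose_per100g: float | None = None
    energy_per100g: float | None = None
    flags: LadderFlags = field(default_factory=LadderFlags)


class FoodTableError(ValueError):
    """Raised when a food table violates a hard contract (duplicates, negatives)."""


@dataclass
class ValidationReport:
    """Per-rule counts of invariant violations, each naming the offending code."""

    violations: list[tuple[str, str]] = field(default_factory=list)  # (rule, food_code)

    def add(self, rule: str, food_code: str) -> None:
        self.violations.append((rule, food_code))

    @property
    def counts_by_rule(self) -> dict[str, int]:
        return dict(Counter(rule for rule, _ in self.violations))

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


_FLAG_COLUMNS = (
    "is_unprocessed_whole_food",
    "is_pure_sugar_product",
    "is_fruit_juice",
    "is_diet_beverage",
    "has_unsweetened_equivalent",
)

_REQUIRED_COLUMNS = (
    "food_code",
    "description",
    "source_group",
    "group",
    "total_sugar_per100g",
)


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n", ""}:
        return False
    raise FoodTableError(f"unparseable boolean value {value!r}")


def _optional_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def load_food_table(path: str | Path, *, energy_unit: str = "MJ") -> list[FoodItem]:
    """Load a food composition CSV into :class:`FoodItem` records.

    The CSV must carry a header row with at least ``food_code``, ``description``,
    ``source_group``, ``group``, ``total_sugar_per100g``; optional columns are
    ``lactose_per100g``, ``energy_per100g`` and the ladder-flag columns.  Empty
    lactose/energy cells are preserved as missing, never coerced to zero.

    Parameters
    ----------
    path
        CSV file path (UTF-8, '.' decimal point).
    energy_unit
        ``"MJ"`` (default) or ``"kcal"``; kcal energies are converted to
        MJ/100 g at 4.184 kJ/kcal.  Conversion is never silent: the unit must
        be declared by the caller.
    """
    if energy_unit not in {"MJ", "kcal"}:
        raise FoodTableError(f"energy_unit must be 'MJ' or 'kcal', got {energy_unit!r}")
    df = pd.read_csv(path, dtype={"food_code": str}, keep_default_na=True)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FoodTableError(f"food table missing required columns: {missing}")

    dupes = df["food_code"][df["food_code"].duplicated()].unique().tolist()
    if dupes:
        raise FoodTableError(f"duplicate food codes: {dupes}")

    items: list[FoodItem] = []
    for _, row in df.iterrows():
        code = str(row["food_code"])
        ts = float(row["total_sugar_per100g"])
        lactose = _optional_float(row.get("lactose_per100g"))
        energy = _optional_float(row.get("energy_per100g"))
        if energy is not None and energy_unit == "kcal":
            energy = energy * KJ_PER_KCAL / 1000.0
        for name, value in (
            ("total_sugar_per100g", ts),
            ("lactose_per100g", lactose),
            ("energy_per100g", energy),
        ):
            if value is not None and value < 0:
                raise FoodTableError(f"negative {name} for food_code {code!r}: {value}")
        equivalent = row.get("unsweetened_equivalent_code")
        flags = LadderFlags(
            **{c: _parse_bool(row.get(c)) for c in _FLAG_COLUMNS},
            unsweetened_equivalent_code=(
                None if pd.isna(equivalent) or equivalent == "" else str(equivalent)
            ),
            recipe_fraction_free=_optional_float(row.get("recipe_fraction_free")),
        )
        items.append(
            FoodItem(
                food_code=code,
                description=str(row["description"]),
                source_group=str(row["source_group"]),
                group=FoodGroup(str(row["group"])),
                total_sugar_per100g=ts,
                lactose_per100g=lactose,
                energy_per100g=energy,
                flags=flags,
            )
        )
    return items


def write_food_table(items: Sequence[FoodItem], path: str | Path) -> None:
    """Write items back to CSV (audit round-trip; missing values stay blank)."""
    rows = []
    for it in items:
        row: dict[str, object] = {
            "food_code": it.food_code,
            "description": it.description,
            "source_group": it.source_group,
            "group": it.group.value,
            "total_sugar_per100g": it.total_sugar_per100g,
            "lactose_per100g": it.lactose_per100g,
            "energy_per100g": it.energy_per100g,
            "unsweetened_equivalent_code": it.flags.unsweetened_equivalent_code,
            "recipe_fraction_free": it.flags.recipe_fraction_free,
        }
        for c in _FLAG_COLUMNS:
            row[c] = getattr(it.flags, c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_regroup_scheme(path: str | Path | None = None) -> dict[str, FoodGroup]:
    """Read a JSON ``{source_group: coarse_group}`` regrouping scheme.

    With no path, returns the illustrative default shipped with the package
    (the original survey's 77- and 19-group memberships are unpublished, so
    the default is a documented stand-in, not a reconstruction).
    """
    if path is None:
        from importlib import resources

        text = (
            resources.files("freesugar.data")
            .joinpath("regroup_default.json")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = json.loads(text)
    return {str(k): FoodGroup(str(v)) for k, v in raw.items()}


def regroup(
    items: Iterable[FoodItem],
    scheme: Mapping[str, FoodGroup | str],
    *,
    default: FoodGroup | None = None,
) -> list[FoodItem]:
    """Re-categorise items from their fine source groups into the 13-group partition.

    Every ``source_group`` present must appear in ``scheme`` unless ``default``
    is given explicitly (typically :attr:`FoodGroup.OTHER`); silent fallthrough
    is a data error.  Idempotent for a fixed scheme.
    """
    items = list(items)
    scheme = {k: FoodGroup(v) for k, v in scheme.items()}
    missing = sorted({it.source_group for it in items} - scheme.keys())
    if missing and default is None:
        raise FoodTableError(f"source groups missing from regroup scheme: {missing}")
    return [
        replace(it, group=scheme.get(it.source_group, default)) for it in items
    ]


def validate_food_table(items: Iterable[FoodItem]) -> ValidationReport:
    """Check every table invariant, reporting (never raising) violations.

    Rules checked, each tagged with the offending ``food_code``:

    - ``negative_composition``: any per-100 g value below zero;
    - ``lactose_exceeds_ts``: analysed lactose above total sugar;
    - ``sugar_energy_exceeds_energy``: TS × 0.017 MJ/g above the food's energy;
    - ``flag_mutual_exclusion``: unprocessed-whole-food and pure-sugar both set;
    - ``recipe_fraction_range`` is enforced at construction and re-checked here.
    """
    report = ValidationReport()
    for it in items:
        values = [
            it.total_sugar_per100g,
            it.lactose_per100g,
            it.energy_per100g,
        ]
        if any(v is not None and v < 0 for v in values):
            report.add("negative_composition", it.food_code)
        if (
            it.lactose_per100g is not None
            and it.lactose_per100g > it.total_sugar_per100g
        ):
            report.add("lactose_exceeds_ts", it.food_code)
        if (
            it.energy_per100g is not None
            # 1e-9 slack: sugar-only foods sit exactly on the energy bound
            and it.total_sugar_per100g * 0.017 > it.energy_per100g + 1e-9
        ):
            report.add("sugar_energy_exceeds_energy", it.food_code)
        if it.flags.is_unprocessed_whole_food and it.flags.is_pure_sugar_product:
            report.add("flag_mutual_exclusion", it.food_code)
        f = it.flags.recipe_fraction_free
        if f is not None and not (0.0 <= f <= 1.0):
            report.add("recipe_fraction_range", it.food_code)
    return report
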