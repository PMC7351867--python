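"""Semi-weighed food-diary records and nutrient joins.

A diary row is one food consumed at one eating occasion (snack or main meal)
on one survey day, with a gram amount.  Every diary entry counts as a
consumption.  Joining entries against the food table and the ladder's
free-sugar assignments yields a consumptions table with derived per-entry
total sugar, free sugar and energy — the input to all cohort aggregation.

Consumptions are carried as a pandas DataFrame (columns documented on
:func:`join_nutrients`); diary entries and subjects are small typed records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .food_composition import FoodGroup, FoodItem
from .fs_ladder import FSAssignment

__all__ = [
    "DiaryEntry",
    "Subject",
    "DiaryError",
    "load_diary",
    "load_subjects",
    "entries_to_frame",
    "join_nutrients",
    "enumerate_occasions",
    "CONSUMPTION_COLUMNS",
]

OCCASION_TYPES = ("snack", "main_meal")


class DiaryError(ValueError):
    pass


@dataclass(frozen=True)
class DiaryEntry:
    """A single consumption: one food at one eating occasion."""

    subject_id: str
    survey_day: int
    occasion_seq: int
    occasion_type: Literal["snack", "main_meal"]
    food_code: str
    amount_g: float

    def __post_init__(self) -> None:
        if self.occasion_type not in OCCASION_TYPES:
            raise DiaryError(
                f"occasion_type must be one of {OCCASION_TYPES}, "
                f"got {self.occasion_type!r}"
            )
        if not self.amount_g > 0:
            raise DiaryError(f"amount_g must be > 0, got {self.amount_g}")
        if self.occasion_seq < 1:
            raise DiaryError(f"occasion_seq must be >= 1, got {self.occasion_seq}")


@dataclass(frozen=True)
class Subject:
    """A surveyed child with the anthropometry the BMR equations need."""

    subject_id: str
    sex: Literal["male", "female"]
    age_months: int
    weight_kg: float
    height_cm: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DiaryError(f"sex must be male or female, got {self.sex!r}")
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise DiaryError(
                f"subject {self.subject_id}: anthropometry must be positive"
            )


_ENTRY_KEY = ["subject_id", "survey_day", "occasion_seq", "food_code"]


def entries_to_frame(entries: Sequence[DiaryEntry]) -> pd.DataFrame:
    cols = ["subject_id", "survey_day", "occasion_seq", "occasion_type",
            "food_code", "amount_g"]
    if len(entries) == 0:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([e.__dict__ for e in entries])[cols]


def _check_entries(df: pd.DataFrame) -> None:
    bad_type = ~df["occasion_type"].isin(OCCASION_TYPES)
    if bad_type.any():
        raise DiaryError(
            f"unknown occasion_type values: "
            f"{sorted(df.loc[bad_type, 'occasion_type'].unique())}"
        )
    if (df["amount_g"] <= 0).any():
        offending = df.loc[df["amount_g"] <= 0, _ENTRY_KEY].iloc[0].tolist()
        raise DiaryError(f"non-positive amount_g at entry {offending}")
    dup = df.duplicated(subset=_ENTRY_KEY)
    if dup.any():
        key = df.loc[dup, _ENTRY_KEY].iloc[0].tolist()
        raise DiaryError(f"duplicate diary key {key}")
    # occasion_type is a property of the occasion, not of the entry
    occ = df.groupby(["subject_id", "survey_day", "occasion_seq"])["occasion_type"]
    conflicted = occ.nunique() > 1
    if conflicted.any():
        raise DiaryError(
            f"conflicting occasion_type within occasions: "
            f"{list(conflicted[conflicted].index[:5])}"
        )


def load_diary(path: str | Path) -> list[DiaryEntry]:
    """Load a diary CSV (header row required) into validated entries."""
    df = pd.read_csv(path, dtype={"subject_id": str, "food_code": str})
    df["survey_day"] = df["survey_day"].astype(int)
    df["occasion_seq"] = df["occasion_seq"].astype(int)
    df["amount_g"] = df["amount_g"].astype(float)
    _check_entries(df)
    return [
        DiaryEntry(
            subject_id=r.subject_id,
            survey_day=int(r.survey_day),
            occasion_seq=int(r.occasion_seq),
            occasion_type=r.occasion_type,
            food_code=r.food_code,
            amount_g=float(r.amount_g),
        )
        for r in df.itertuples(index=False)
    ]


def load_subjects(path: str | Path) -> list[Subject]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    return [
        Subject(
            subject_id=r.subject_id,
            sex=r.sex,
            age_months=int(r.age_months),
            weight_kg=float(r.weight_kg),
            height_cm=float(r.height_cm),
        )
        for r in df.itertuples(index=False)
    ]


#: Columns of the consumptions DataFrame produced by :func:`join_nutrients`.
CONSUMPTION_COLUMNS = [
    "subject_id", "survey_day", "occasion_seq", "occasion_type", "food_code",
    "amount_g", "group", "ts_g", "fs_g", "energy_MJ",
]


def join_nutrients(
    entries: Sequence[DiaryEntry] | pd.DataFrame,
    foods: Sequence[FoodItem],
    fs: Sequence[FSAssignment],
) -> pd.DataFrame:
    """Join per-100 g composition and FS assignments onto diary entries.

    Derived columns are exact products: ``ts_g = amount_g * TS/100`` and
    likewise for ``fs_g`` and ``energy_MJ`` (missing energy propagates as NaN).
    Row count and order are preserved.

    Returns a DataFrame with :data:`CONSUMPTION_COLUMNS` plus a ``covered``
    column left unset (filled by the SFQ coverage classifier).
    """
    df = entries if isinstance(entries, pd.DataFrame) else entries_to_frame(entries)
    df = df.copy()
    if len(df):
        _check_entries(df)
    food_codes = set(df["food_code"]) if len(df) else set()
    missing = sorted(food_codes - {f.food_code for f in foods})
    if missing:
        raise DiaryError(f"diary food codes absent from food table: {missing}")
    missing_fs = sorted(food_codes - {a.food_code for a in fs})
    if missing_fs:
        raise DiaryError(f"diary food codes without FS assignment: {missing_fs}")

    comp = pd.DataFrame(
        {
            "food_code": [f.food_code for f in foods],
            "group": [f.group.value for f in foods],
            "_ts100": [f.total_sugar_per100g for f in foods],
            "_en100": [f.energy_per100g for f in foods],
        }
    )
    fs_df = pd.DataFrame(
        {"food_code": [a.food_code for a in fs],
         "_fs100": [a.fs_per100g for a in fs]}
    )
    out = df.merge(comp, on="food_code", how="left", sort=False)
    out = out.merge(fs_df, on="food_code", how="left", sort=False)
    out["ts_g"] = out["amount_g"] * out["_ts100"] / 100.0
    out["fs_g"] = out["amount_g"] * out["_fs100"] / 100.0
    out["energy_MJ"] = out["amount_g"] * out["_en100"] / 100.0
    out["covered"] = pd.Series(pd.NA, index=out.index, dtype="boolean")
    return out.drop(columns=["_ts100", "_en100", "_fs100"])[
        CONSUMPTION_COLUMNS + ["covered"]
    ]


def enumerate_occasions(
    entries: Sequence[DiaryEntry] | pd.DataFrame,
) -> pd.DataFrame:
    """One row per distinct eating occasion with its entry count.

    Columns: subject_id, survey_day, occasion_seq, occasion_type, n_entries.
    Conflicting occasion types within one occasion are a data error.
    """
    df = entries if isinstance(entries, pd.DataFrame) else entries_to_frame(entries)
    if len(df) == 0:
        return pd.DataFrame(
            columns=["subject_id", "survey_day", "occasion_seq",
                     "occasion_type", "n_entries"]
        )
    _check_entries(df)
    grouped = (
        df.groupby(["subject_id", "survey_day", "occasion_seq"], sort=True)
        .agg(occasion_type=("occasion_type", "first"),
             n_entries=("food_code", "size"))
        .reset_index()
    )
    return grouped
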