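"""Goldberg-type under-reporting screen for dietary energy intake.

Food diaries under-record true intake, children's parent-reported diaries
included.  A standard plausibility screen predicts each child's basal
metabolic rate (BMR) from sex, age, weight and height with the Schofield
weight-and-height equations, then flags subjects whose reported mean daily
energy intake falls below ``cutoff × BMR``.  For 4-day records the customary
cutoff is 1.28 — roughly the minimum energy a surviving, weight-stable child
could expend.  Flagged children are *retained* in all statistics; the flag is
descriptive, not an exclusion rule.

Coefficient sets ship as JSON (``data/schofield_wh.json``) and any alternative
file with the same shape can be substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .diary import Subject

__all__ = [
    "BMRBand",
    "BMRCoefficientSet",
    "BMRResult",
    "UnderReportingError",
    "load_bmr_coefficients",
    "predict_bmr",
    "flag_under_reporters",
    "DEFAULT_CUTOFF",
]

#: Goldberg-type minimum plausible energy-intake-to-BMR ratio for 4-day records.
DEFAULT_CUTOFF = 1.28


class UnderReportingError(ValueError):
    pass


@dataclass(frozen=True)
class BMRBand:
    """One sex × age band of a weight-and-height BMR equation (MJ/day)."""

    sex: str
    age_min_months: int
    age_max_months: int
    a: float  # per kg body weight
    b: float  # per metre height
    c: float  # intercept
    label: str

    def matches(self, subject: Subject) -> bool:
        return (
            subject.sex == self.sex
            and self.age_min_months <= subject.age_months <= self.age_max_months
        )


@dataclass(frozen=True)
class BMRCoefficientSet:
    bands: tuple[BMRBand, ...]

    def band_for(self, subject: Subject) -> BMRBand:
        for band in self.bands:
            if band.matches(subject):
                return band
        raise UnderReportingError(
            f"no BMR band for subject {subject.subject_id} "
            f"(sex={subject.sex}, age_months={subject.age_months})"
        )


@dataclass(frozen=True)
class BMRResult:
    subject_id: str
    bmr_MJ_day: float
    equation_band: str
    ei_bmr_ratio: float | None = None
    under_reporter: bool | None = None


def load_bmr_coefficients(path: str | Path | None = None) -> BMRCoefficientSet:
    """Load a BMR coefficient JSON; default is the shipped Schofield W&H set."""
    if path is None:
        text = (
            resources.files("freesugar.data")
            .joinpath("schofield_wh.json")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = json.loads(text)
    return BMRCoefficientSet(
        bands=tuple(BMRBand(**band) for band in raw["bands"])
    )


def predict_bmr(
    subject: Subject,
    coefficients: BMRCoefficientSet | None = None,
) -> BMRResult:
    """Predict basal metabolic rate (MJ/day) from weight and height.

    ``bmr = a × weight_kg + b × height_m + c`` for the subject's sex × age
    band.  Height is stored in cm on the subject and converted here.
    """
    coefficients = coefficients or load_bmr_coefficients()
    if subject.weight_kg <= 0 or subject.height_cm <= 0:
        raise UnderReportingError(
            f"subject {subject.subject_id}: non-positive anthropometry"
        )
    band = coefficients.band_for(subject)
    bmr = band.a * subject.weight_kg + band.b * (subject.height_cm / 100.0) + band.c
    if bmr <= 0:
        raise UnderReportingError(
            f"subject {subject.subject_id}: predicted BMR {bmr:.3f} MJ/day "
            f"is not positive (band {band.label})"
        )
    return BMRResult(
        subject_id=subject.subject_id,
        bmr_MJ_day=bmr,
        equation_band=band.label,
    )


def flag_under_reporters(
    summaries: pd.DataFrame,
    bmr_results: Sequence[BMRResult],
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[BMRResult], float]:
    """Flag subjects whose mean energy intake falls below ``cutoff × BMR``.

    ``summaries`` must carry ``subject_id`` and ``mean_energy_MJ_day`` (the
    multi-day mean).  The comparison is strict: a ratio exactly equal to the
    cutoff is *not* flagged.  Returns the completed per-subject results and
    the cohort prevalence of under-reporting in percent.
    """
    bmr_by_id = {r.subject_id: r for r in bmr_results}
    missing = sorted(set(summaries["subject_id"]) - bmr_by_id.keys())
    if missing:
        raise UnderReportingError(f"subjects without BMR prediction: {missing}")
    completed: list[BMRResult] = []
    for row in summaries.itertuples(index=False):
        base = bmr_by_id[row.subject_id]
        ratio = float(row.mean_energy_MJ_day) / base.bmr_MJ_day
        completed.append(
            BMRResult(
                subject_id=base.subject_id,
                bmr_MJ_day=base.bmr_MJ_day,
                equation_band=base.equation_band,
                ei_bmr_ratio=ratio,
                under_reporter=ratio < cutoff,
            )
        )
    n = len(completed)
    prevalence = 100.0 * sum(r.under_reporter for r in completed) / n if n else 0.0
    return completed, prevalence
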