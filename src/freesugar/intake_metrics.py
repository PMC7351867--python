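"""Cohort aggregation: daily intakes, WHO compliance, food-group contributions.

From the per-entry consumptions table this module builds, in order:

1. per subject-day totals and eating-occasion frequencies (``daily_intakes``);
2. per-subject multi-day means, sugar energy as %TEI and the WHO free-sugar
   category (``subject_summaries``);
3. cohort distribution statistics — mean, SD, quartiles, share of children
   above the WHO 10 %TEI maximum and below the 5 %TEI conditional threshold
   (``cohort_table``);
4. per-food-group contributions: percent consumers, mean daily grams and %TEI
   over *all* subjects, frequency, and snack-vs-main-meal probabilities
   (``group_contributions``, ``snack_meal_probability``).

Sugar energy uses 0.017 MJ per gram of sugar.  %TEI is, by default, the ratio
of the multi-day mean sugar energy to the multi-day mean energy intake
(ratio of means); mean-of-daily-ratios is available behind a switch.
Frequencies count eating *occasions* containing at least one sugar-positive
food, not individual diary entries.  Quartiles interpolate linearly between
order statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .food_composition import FoodGroup

__all__ = [
    "ENERGY_MJ_PER_G_SUGAR",
    "WHO_CUTOFFS",
    "MetricsError",
    "who_category",
    "daily_intakes",
    "subject_summaries",
    "cohort_table",
    "group_contributions",
    "snack_meal_probability",
    "CohortReport",
]

#: Energy density of sugar used for %TEI conversion (MJ per gram).
ENERGY_MJ_PER_G_SUGAR = 0.017

#: WHO free-sugar thresholds as % of total energy intake: conditional, maximum.
WHO_CUTOFFS = (5.0, 10.0)

_OCC_KEY = ["subject_id", "survey_day", "occasion_seq"]


class MetricsError(ValueError):
    pass


def who_category(
    pct_tei_fs: float | np.ndarray | pd.Series,
    cutoffs: tuple[float, float] = WHO_CUTOFFS,
) -> np.ndarray | str:
    """Classify free-sugar %TEI against the WHO thresholds.

    ``below_5`` means strictly below the conditional threshold; ``above_10``
    strictly above the maximum; values exactly on a boundary fall in
    ``between_5_and_10``.
    """
    lo, hi = cutoffs
    if not lo < hi:
        raise MetricsError(f"cutoffs must be ordered, got {cutoffs}")
    arr = np.asarray(pct_tei_fs, dtype=float)
    out = np.where(arr < lo, "below_5",
                   np.where(arr > hi, "above_10", "between_5_and_10"))
    return out.item() if np.isscalar(pct_tei_fs) or arr.ndim == 0 else out


def daily_intakes(consumptions: pd.DataFrame) -> pd.DataFrame:
    """Aggregate consumptions to subject-day totals and occasion frequencies.

    Returns one row per (subject_id, survey_day) with columns ``ts_g_day``,
    ``fs_g_day``, ``energy_MJ_day``, ``freq_ts``, ``freq_fs`` and
    ``n_occasions``.  An occasion counts toward ``freq_fs`` when its summed
    free sugar is positive, however many entries it holds — entry multiplicity
    never inflates frequency.
    """
    cols = ["subject_id", "survey_day", "ts_g_day", "fs_g_day", "energy_MJ_day",
            "freq_ts", "freq_fs", "n_occasions"]
    if len(consumptions) == 0:
        return pd.DataFrame(columns=cols)
    occ = (
        consumptions.groupby(_OCC_KEY, sort=True)
        .agg(ts_g=("ts_g", "sum"), fs_g=("fs_g", "sum"),
             energy_MJ=("energy_MJ", "sum"))
        .reset_index()
    )
    day = (
        occ.groupby(["subject_id", "survey_day"], sort=True)
        .agg(
            ts_g_day=("ts_g", "sum"),
            fs_g_day=("fs_g", "sum"),
            energy_MJ_day=("energy_MJ", "sum"),
            freq_ts=("ts_g", lambda s: int((s > 0).sum())),
            freq_fs=("fs_g", lambda s: int((s > 0).sum())),
            n_occasions=("ts_g", "size"),
        )
        .reset_index()
    )
    return day[cols]


def subject_summaries(
    dailies: pd.DataFrame,
    cutoffs: tuple[float, float] = WHO_CUTOFFS,
    *,
    energy_factor: float = ENERGY_MJ_PER_G_SUGAR,
    pct_tei_method: Literal["ratio_of_means", "mean_of_ratios"] = "ratio_of_means",
) -> pd.DataFrame:
    """Per-subject means over survey days, %TEI and WHO category.

    Raises when any subject's mean energy intake is zero or missing — %TEI is
    undefined there and silently dropping children would bias the cohort.
    """
    if len(dailies) == 0:
        raise MetricsError("subject_summaries requires at least one subject-day")
    g = dailies.groupby("subject_id", sort=True)
    out = g.agg(
        mean_ts_g_day=("ts_g_day", "mean"),
        mean_fs_g_day=("fs_g_day", "mean"),
        mean_energy_MJ_day=("energy_MJ_day", "mean"),
        mean_freq_ts=("freq_ts", "mean"),
        mean_freq_fs=("freq_fs", "mean"),
        n_days=("survey_day", "nunique"),
    ).reset_index()
    bad = out["mean_energy_MJ_day"].isna() | (out["mean_energy_MJ_day"] <= 0)
    if bad.any():
        raise MetricsError(
            f"zero or missing energy intake for subjects: "
            f"{out.loc[bad, 'subject_id'].tolist()}"
        )
    if pct_tei_method == "ratio_of_means":
        out["pct_tei_ts"] = (
            100.0 * out["mean_ts_g_day"] * energy_factor / out["mean_energy_MJ_day"]
        )
        out["pct_tei_fs"] = (
            100.0 * out["mean_fs_g_day"] * energy_factor / out["mean_energy_MJ_day"]
        )
    elif pct_tei_method == "mean_of_ratios":
        d = dailies.copy()
        if (d["energy_MJ_day"] <= 0).any():
            raise MetricsError("mean_of_ratios requires positive energy every day")
        d["_r_ts"] = 100.0 * d["ts_g_day"] * energy_factor / d["energy_MJ_day"]
        d["_r_fs"] = 100.0 * d["fs_g_day"] * energy_factor / d["energy_MJ_day"]
        ratios = d.groupby("subject_id", sort=True)[["_r_ts", "_r_fs"]].mean()
        out["pct_tei_ts"] = ratios["_r_ts"].to_numpy()
        out["pct_tei_fs"] = ratios["_r_fs"].to_numpy()
    else:
        raise MetricsError(f"unknown pct_tei_method {pct_tei_method!r}")
    out["who_category"] = who_category(out["pct_tei_fs"], cutoffs)
    return out


_TABLE_MEASURES = {
    "ts_g_day": "mean_ts_g_day",
    "fs_g_day": "mean_fs_g_day",
    "pct_tei_ts": "pct_tei_ts",
    "pct_tei_fs": "pct_tei_fs",
    "freq_ts": "mean_freq_ts",
    "freq_fs": "mean_freq_fs",
}


@dataclass
class CohortReport:
    """Cohort distribution table plus WHO shares and group contributions."""

    n_subjects: int
    stats: pd.DataFrame  # index: measure; columns: mean, sd, p25, p50, p75
    pct_above_10: float
    pct_below_5: float
    group_contributions: pd.DataFrame | None = None
    schema_version: str = field(default="1", repr=False)

    def to_dict(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "n_subjects": self.n_subjects,
            "pct_above_10": self.pct_above_10,
            "pct_below_5": self.pct_below_5,
            "stats": {
                m: {k: float(v) for k, v in row.items()}
                for m, row in self.stats.to_dict(orient="index").items()
            },
        }
        if self.group_contributions is not None:
            d["group_contributions"] = json.loads(
                self.group_contributions.to_json(orient="records")
            )
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )


def cohort_table(
    summaries: pd.DataFrame,
    *,
    quantile_method: str = "linear",
) -> CohortReport:
    """Distribution statistics over subjects for the six headline measures.

    Mean, sample SD (n − 1), and linearly interpolated quartiles for TS/FS
    grams per day, %TEI and daily frequency; plus the percentage of subjects
    in each outer WHO category.
    """
    if len(summaries) == 0:
        raise MetricsError("cohort_table requires at least one subject")
    rows = {}
    for measure, col in _TABLE_MEASURES.items():
        x = summaries[col].to_numpy(dtype=float)
        p25, p50, p75 = np.percentile(x, [25, 50, 75], method=quantile_method)
        rows[measure] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            "p25": float(p25),
            "p50": float(p50),
            "p75": float(p75),
        }
    n = len(summaries)
    cat = summaries["who_category"]
    return CohortReport(
        n_subjects=n,
        stats=pd.DataFrame.from_dict(rows, orient="index")[
            ["mean", "sd", "p25", "p50", "p75"]
        ],
        pct_above_10=100.0 * float((cat == "above_10").sum()) / n,
        pct_below_5=100.0 * float((cat == "below_5").sum()) / n,
    )


def snack_meal_probability(consumptions: pd.DataFrame) -> pd.DataFrame:
    """Per-group probability (%) that a consumption happens at a snack vs a meal.

    Counts every consumption over the full survey window; for each group
    present, ``prob_snack + prob_meal = 100`` exactly.  Groups with no
    consumptions simply do not appear (no 0/0 rows).
    """
    if len(consumptions) == 0:
        return pd.DataFrame(
            columns=["group", "n_snack", "n_meal", "prob_snack", "prob_meal"]
        )
    counts = (
        consumptions.groupby("group", sort=True)["occasion_type"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["snack", "main_meal"], fill_value=0)
        .reset_index()
        .rename(columns={"snack": "n_snack", "main_meal": "n_meal"})
    )
    total = counts["n_snack"] + counts["n_meal"]
    counts["prob_snack"] = 100.0 * counts["n_snack"] / total
    counts["prob_meal"] = 100.0 * counts["n_meal"] / total
    counts.columns.name = None
    return counts


def group_contributions(
    consumptions: pd.DataFrame,
    summaries: pd.DataFrame,
    *,
    energy_factor: float = ENERGY_MJ_PER_G_SUGAR,
    groups: Sequence[FoodGroup | str] | None = None,
) -> pd.DataFrame:
    """Per-food-group contribution to cohort sugar intake.

    Means are taken over *all* subjects in ``summaries`` — non-consumers
    contribute zeros — so the per-group means partition the cohort means
    exactly.  Percent consumers counts subjects with at least one consumption
    of the group in the survey window, any amount.  Frequency counts distinct
    occasions containing the group, per observed day.

    Columns: group, pct_consumers, mean_ts_g_day, mean_fs_g_day,
    mean_pct_tei_ts, mean_pct_tei_fs, mean_freq, prob_snack, prob_meal.
    """
    if groups is None:
        groups = [g.value for g in FoodGroup]
    groups = [g.value if isinstance(g, FoodGroup) else str(g) for g in groups]
    subjects = summaries.set_index("subject_id")
    n = len(subjects)
    if n == 0:
        raise MetricsError("group_contributions requires at least one subject")

    # per-subject observed-day count (days with any consumption)
    n_days = consumptions.groupby("subject_id")["survey_day"].nunique()
    n_days = n_days.reindex(subjects.index)
    if n_days.isna().any():
        raise MetricsError(
            f"subjects without consumptions: "
            f"{n_days[n_days.isna()].index.tolist()}"
        )

    sums = (
        consumptions.groupby(["subject_id", "group"], sort=True)[["ts_g", "fs_g"]]
        .sum()
        .unstack(fill_value=0.0)
    )
    freq = (
        consumptions.drop_duplicates(subset=_OCC_KEY + ["group"])
        .groupby(["subject_id", "group"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    probs = snack_meal_probability(consumptions).set_index("group")

    rows = []
    for g in groups:
        ts = sums.get(("ts_g", g), pd.Series(0.0, index=sums.index)).reindex(
            subjects.index, fill_value=0.0
        )
        fs = sums.get(("fs_g", g), pd.Series(0.0, index=sums.index)).reindex(
            subjects.index, fill_value=0.0
        )
        f = (
            freq[g].reindex(subjects.index, fill_value=0)
            if g in freq.columns
            else pd.Series(0, index=subjects.index)
        )
        consumers = (ts > 0) | (fs > 0) | (f > 0)
        ts_day = ts / n_days
        fs_day = fs / n_days
        rows.append(
            {
                "group": g,
                "pct_consumers": 100.0 * float(consumers.sum()) / n,
                "mean_ts_g_day": float(ts_day.mean()),
                "mean_fs_g_day": float(fs_day.mean()),
                "mean_pct_tei_ts": float(
                    (100.0 * ts_day * energy_factor
                     / subjects["mean_energy_MJ_day"]).mean()
                ),
                "mean_pct_tei_fs": float(
                    (100.0 * fs_day * energy_factor
                     / subjects["mean_energy_MJ_day"]).mean()
                ),
                "mean_freq": float((f / n_days).mean()),
                "prob_snack": (
                    float(probs.loc[g, "prob_snack"]) if g in probs.index else np.nan
                ),
                "prob_meal": (
                    float(probs.loc[g, "prob_meal"]) if g in probs.index else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
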