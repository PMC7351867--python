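import numpy as np
import pandas as pd
import pytest

from freesugar.intake_metrics import (
    MetricsError,
    cohort_table,
    daily_intakes,
    group_contributions,
    snack_meal_probability,
    subject_summaries,
    who_category,
)


def cons_frame(rows):
    """rows: (subject, day, occ_seq, occ_type, group, ts, fs, energy)"""
    return pd.DataFrame(
        rows,
        columns=["subject_id", "survey_day", "occasion_seq", "occasion_type",
                 "group", "ts_g", "fs_g", "energy_MJ"],
    ).assign(food_code="F", amount_g=100.0)


class TestDailyIntakes:
    def test_two_fs_positive_occasions(self):
        d = daily_intakes(cons_frame([
            ("S1", 1, 1, "main_meal", "dairy_products", 5, 2, 0.5),
            ("S1", 1, 2, "snack", "soft_drinks_non_diet", 8, 8, 0.3),
        ]))
        assert d.iloc[0]["freq_fs"] == 2
        assert d.iloc[0]["ts_g_day"] == pytest.approx(13.0)

    def test_entry_multiplicity_does_not_inflate_frequency(self):
        # two FS-positive entries in the SAME occasion count once
        d = daily_intakes(cons_frame([
            ("S1", 1, 1, "main_meal", "dairy_products", 5, 2, 0.5),
            ("S1", 1, 1, "main_meal", "cakes_and_biscuits", 4, 4, 0.4),
        ]))
        assert d.iloc[0]["freq_fs"] == 1
        assert d.iloc[0]["n_occasions"] == 1

    def test_sugar_free_day(self):
        d = daily_intakes(cons_frame([
            ("S1", 1, 1, "main_meal", "dairy_products", 4.8, 0.0, 0.5),
            ("S1", 1, 2, "snack", "other", 0.0, 0.0, 0.2),
        ]))
        assert d.iloc[0]["freq_fs"] == 0
        assert d.iloc[0]["fs_g_day"] == 0.0
        assert d.iloc[0]["freq_ts"] == 1


class TestSubjectSummaries:
    def test_pct_tei_formula(self):
        # 40 g/day FS at 4.8 MJ/day: 100*40*0.017/4.8 = 14.17 -> above_10
        d = daily_intakes(cons_frame([
            ("S1", 1, 1, "main_meal", "dairy_products", 50, 40, 4.8),
        ]))
        s = subject_summaries(d)
        assert s.iloc[0]["pct_tei_fs"] == pytest.approx(14.1666, abs=1e-3)
        assert s.iloc[0]["who_category"] == "above_10"

    @pytest.mark.parametrize(
        "pct, expected",
        [(4.99, "below_5"), (5.0, "between_5_and_10"), (10.0, "between_5_and_10"),
         (10.01, "above_10"), (0.0, "below_5")],
    )
    def test_who_boundaries(self, pct, expected):
        assert who_category(pct) == expected

    def test_zero_energy_subject_is_error(self):
        d = pd.DataFrame({
            "subject_id": ["S1"], "survey_day": [1], "ts_g_day": [1.0],
            "fs_g_day": [0.5], "energy_MJ_day": [0.0], "freq_ts": [1],
            "freq_fs": [1], "n_occasions": [1],
        })
        with pytest.raises(MetricsError, match="S1"):
            subject_summaries(d)

    def test_ratio_of_means_vs_mean_of_ratios(self):
        d = pd.DataFrame({
            "subject_id": ["S1"] * 2, "survey_day": [1, 2],
            "ts_g_day": [10.0, 30.0], "fs_g_day": [10.0, 30.0],
            "energy_MJ_day": [2.0, 6.0], "freq_ts": [1, 1], "freq_fs": [1, 1],
            "n_occasions": [2, 2],
        })
        rom = subject_summaries(d).iloc[0]["pct_tei_fs"]
        mor = subject_summaries(d, pct_tei_method="mean_of_ratios").iloc[0]["pct_tei_fs"]
        assert rom == pytest.approx(100 * 20 * 0.017 / 4.0)
        assert mor == pytest.approx(100 * 0.017 * (10 / 2 + 30 / 6) / 2)


class TestCohortTable:
    def test_who_shares_brute_force(self):
        d = pd.DataFrame({
            "subject_id": ["A", "B", "C", "D"], "survey_day": 1,
            "ts_g_day": 10.0, "fs_g_day": [4, 8, 12, 16],
            "energy_MJ_day": 1.7, "freq_ts": 1, "freq_fs": 1, "n_occasions": 1,
        })
        # %TEI = fs since 100*0.017/1.7 = 1
        r = cohort_table(subject_summaries(d))
        assert r.pct_above_10 == pytest.approx(50.0)
        assert r.pct_below_5 == pytest.approx(25.0)

    def test_identical_subjects_degenerate_spread(self):
        d = pd.DataFrame({
            "subject_id": list("ABC"), "survey_day": 1, "ts_g_day": 10.0,
            "fs_g_day": 5.0, "energy_MJ_day": 2.0, "freq_ts": 2, "freq_fs": 1,
            "n_occasions": 3,
        })
        r = cohort_table(subject_summaries(d))
        row = r.stats.loc["fs_g_day"]
        assert row["sd"] == 0.0
        assert row["p25"] == row["p50"] == row["p75"] == 5.0

    def test_linear_interpolation_quartiles(self):
        d = pd.DataFrame({
            "subject_id": list("ABCDE"), "survey_day": 1, "ts_g_day": 10.0,
            "fs_g_day": [1.0, 2.0, 3.0, 4.0, 5.0], "energy_MJ_day": 2.0,
            "freq_ts": 1, "freq_fs": 1, "n_occasions": 1,
        })
        row = cohort_table(subject_summaries(d)).stats.loc["fs_g_day"]
        assert (row["p25"], row["p50"], row["p75"]) == (2.0, 3.0, 4.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(MetricsError):
            cohort_table(pd.DataFrame(columns=["pct_tei_fs"]))


class TestGroupContributions:
    @pytest.fixture
    def four_subject_world(self):
        rows = []
        for i, sid in enumerate(["A", "B", "C", "D"]):
            rows.append((sid, 1, 1, "main_meal", "dairy_products", 20.0, 8.0, 2.0))
            if sid != "D":  # three of four eat breakfast cereal
                rows.append((sid, 1, 2, "main_meal", "rtebc", 3.0, 3.0, 0.5))
        cons = cons_frame(rows)
        summaries = subject_summaries(daily_intakes(cons))
        return cons, summaries

    def test_pct_consumers(self, four_subject_world):
        cons, summaries = four_subject_world
        g = group_contributions(cons, summaries).set_index("group")
        assert g.loc["rtebc", "pct_consumers"] == pytest.approx(75.0)
        assert g.loc["dairy_products", "pct_consumers"] == pytest.approx(100.0)

    def test_nonconsumed_group_is_zero(self, four_subject_world):
        cons, summaries = four_subject_world
        g = group_contributions(cons, summaries).set_index("group")
        assert g.loc["soft_drinks_diet", "mean_fs_g_day"] == 0.0
        assert g.loc["soft_drinks_diet", "pct_consumers"] == 0.0
        assert np.isnan(g.loc["soft_drinks_diet", "prob_snack"])

    def test_partition_identity(self, four_subject_world):
        """Per-group means over all subjects sum to the cohort means."""
        cons, summaries = four_subject_world
        g = group_contributions(cons, summaries)
        r = cohort_table(summaries)
        assert g["mean_ts_g_day"].sum() == pytest.approx(
            r.stats.loc["ts_g_day", "mean"], rel=1e-9)
        assert g["mean_fs_g_day"].sum() == pytest.approx(
            r.stats.loc["fs_g_day", "mean"], rel=1e-9)
        assert g["mean_pct_tei_fs"].sum() == pytest.approx(
            r.stats.loc["pct_tei_fs", "mean"], rel=1e-9)


class TestSnackMealProbability:
    def test_published_chocolate_ratio(self):
        rows = (
            [("S1", 1, i + 1, "snack", "chocolate_confectionary", 5, 5, 0.2)
             for i in range(146)]
            + [("S1", 2, i + 1, "main_meal", "chocolate_confectionary", 5, 5, 0.2)
               for i in range(54)]
        )
        p = snack_meal_probability(cons_frame(rows)).set_index("group")
        assert p.loc["chocolate_confectionary", "prob_snack"] == pytest.approx(73.0)
        assert p.loc["chocolate_confectionary", "prob_meal"] == pytest.approx(27.0)

    def test_all_meals(self):
        p = snack_meal_probability(cons_frame(
            [("S1", 1, 1, "main_meal", "rtebc", 3, 3, 0.5)] * 1
        )).set_index("group")
        assert p.loc["rtebc", "prob_snack"] == 0.0
        assert p.loc["rtebc", "prob_meal"] == 100.0

    def test_even_split(self):
        p = snack_meal_probability(cons_frame([
            ("S1", 1, 1, "snack", "other", 1, 1, 0.1),
            ("S1", 1, 2, "main_meal", "other", 1, 1, 0.1),
        ])).set_index("group")
        assert p.loc["other", "prob_snack"] == pytest.approx(50.0)


class TestScalingInvariance:
    def test_doubling_amounts(self, small_cohort_consumptions):
        cons = small_cohort_consumptions
        doubled = cons.assign(
            amount_g=cons.amount_g * 2, ts_g=cons.ts_g * 2, fs_g=cons.fs_g * 2,
            energy_MJ=cons.energy_MJ * 2,
        )
        s1 = subject_summaries(daily_intakes(cons))
        s2 = subject_summaries(daily_intakes(doubled))
        assert np.allclose(s2.mean_fs_g_day, 2 * s1.mean_fs_g_day)
        assert np.allclose(s2.mean_freq_fs, s1.mean_freq_fs)
        # energy doubled too, so %TEI is unchanged
        assert np.allclose(s2.pct_tei_fs, s1.pct_tei_fs)

    def test_freq_fs_never_exceeds_freq_ts(self, small_cohort_consumptions):
        d = daily_intakes(small_cohort_consumptions)
        assert (d.freq_fs <= d.freq_ts).all()
        assert (d.freq_ts <= d.n_occasions).all()


def test_aggregates_match_bruteforce_on_five_subjects(small_cohort_consumptions):
    """Row-by-row recomputation with plain dicts equals the pandas aggregation."""
    cons = small_cohort_consumptions
    subjects = sorted(cons.subject_id.unique())[:5]
    cons = cons[cons.subject_id.isin(subjects)]

    daily = {}
    occ_sugar = {}
    for row in cons.itertuples(index=False):
        k = (row.subject_id, row.survey_day)
        d = daily.setdefault(k, {"ts": 0.0, "fs": 0.0, "en": 0.0})
        d["ts"] += row.ts_g
        d["fs"] += row.fs_g
        d["en"] += row.energy_MJ
        o = occ_sugar.setdefault((k, row.occasion_seq), {"ts": 0.0, "fs": 0.0})
        o["ts"] += row.ts_g
        o["fs"] += row.fs_g
    freq = {}
    for (k, _), o in occ_sugar.items():
        f = freq.setdefault(k, {"ts": 0, "fs": 0, "n": 0})
        f["n"] += 1
        f["ts"] += o["ts"] > 0
        f["fs"] += o["fs"] > 0

    got = daily_intakes(cons).set_index(["subject_id", "survey_day"])
    assert len(got) == len(daily)
    for k, d in daily.items():
        row = got.loc[k]
        assert row["ts_g_day"] == pytest.approx(d["ts"])
        assert row["fs_g_day"] == pytest.approx(d["fs"])
        assert row["energy_MJ_day"] == pytest.approx(d["en"])
        assert row["freq_fs"] == freq[k]["fs"]
        assert row["freq_ts"] == freq[k]["ts"]
        assert row["n_occasions"] == freq[k]["n"]

    # subject means and %TEI
    s = subject_summaries(daily_intakes(cons)).set_index("subject_id")
    for sid in subjects:
        days = [d for k, d in daily.items() if k[0] == sid]
        mean_fs = sum(d["fs"] for d in days) / len(days)
        mean_en = sum(d["en"] for d in days) / len(days)
        assert s.loc[sid, "mean_fs_g_day"] == pytest.approx(mean_fs)
        assert s.loc[sid, "pct_tei_fs"] == pytest.approx(
            100 * mean_fs * 0.017 / mean_en)
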