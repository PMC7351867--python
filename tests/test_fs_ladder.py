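import difflib
from collections import Counter
from statistics import median

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freesugar.fs_ladder import (
    FSAssignment,
    LadderConfig,
    LadderError,
    apply_ladder,
    assign_fs,
    compare_distributions,
    reconcile,
)

from conftest import make_food

# ---------------------------------------------------------------------------
# independent oracle: straight-line re-evaluation of the rung predicates
# ---------------------------------------------------------------------------


def oracle_ladder(items, borrow_similarity=0.6):
    """Brute-force rung evaluation, independent of the implementation."""
    by_code = {f.food_code: f for f in items}

    def objective(f):
        ts = f.total_sugar_per100g
        if f.flags.is_unprocessed_whole_food:
            return 0.0, 1
        if f.flags.is_fruit_juice:
            return ts, 2
        if f.flags.is_pure_sugar_product and not f.flags.is_diet_beverage:
            return ts, 3
        if not f.flags.has_unsweetened_equivalent and f.lactose_per100g is not None:
            return min(max(ts - f.lactose_per100g, 0.0), ts), 4
        if (
            f.flags.has_unsweetened_equivalent
            and f.flags.unsweetened_equivalent_code in by_code
        ):
            eq = by_code[f.flags.unsweetened_equivalent_code]
            return min(max(ts - eq.total_sugar_per100g, 0.0), ts), 5
        if f.flags.recipe_fraction_free is not None:
            return min(f.flags.recipe_fraction_free * ts, ts), 6
        return None

    pool = {f.food_code: objective(f) for f in items}
    pool = {c: v for c, v in pool.items() if v is not None}
    out = {}
    for f in items:
        if f.food_code in pool:
            out[f.food_code] = pool[f.food_code]
            continue
        ts = f.total_sugar_per100g
        # rung 7: most similar objectively-assigned food in the same group
        best = None
        for code, (fs, _) in pool.items():
            other = by_code[code]
            if other.group is not f.group:
                continue
            s = difflib.SequenceMatcher(
                None, f.description.lower(), other.description.lower()
            ).ratio()
            if s >= borrow_similarity and (best is None or s > best[0]):
                best = (s, fs)
        if best is not None:
            out[f.food_code] = (min(max(best[1], 0.0), ts), 7)
            continue
        ratios = [
            fs / by_code[c].total_sugar_per100g
            for c, (fs, _) in pool.items()
            if by_code[c].group is f.group and by_code[c].total_sugar_per100g > 0
        ]
        if ratios:
            out[f.food_code] = (min(median(ratios) * ts, ts), 8)
        else:
            out[f.food_code] = (0.5 * ts, 9)
    return out


# ---------------------------------------------------------------------------
# single-item rung behaviour
# ---------------------------------------------------------------------------


class TestAssignFS:
    def test_fruit_juice_all_sugar_free(self):
        juice = make_food("J", "orange juice", group="fruit_juice_and_smoothies",
                          ts=10.4, is_fruit_juice=True)
        a = assign_fs(juice, [juice])
        assert (a.fs_per100g, a.step, a.objective) == (10.4, 2, True)

    def test_plain_milk_intrinsic_only(self):
        milk = make_food("M", "milk", group="dairy_products", ts=4.8, lactose=4.8,
                         is_unprocessed_whole_food=True)
        a = assign_fs(milk, [milk])
        assert (a.fs_per100g, a.step) == (0.0, 1)

    def test_sweetened_yoghurt_ts_minus_lactose(self):
        yog = make_food("Y", "yoghurt", group="dairy_products", ts=12.0, lactose=4.0)
        a = assign_fs(yog, [yog])
        assert (a.fs_per100g, a.step) == (8.0, 4)

    def test_unsweetened_equivalent_subtraction(self):
        sweet = make_food("SW", "sweetened muesli", group="rtebc", ts=25.0,
                          has_unsweetened_equivalent=True,
                          unsweetened_equivalent_code="PL")
        plain = make_food("PL", "plain muesli", group="rtebc", ts=16.0,
                          is_unprocessed_whole_food=True)
        a = assign_fs(sweet, [sweet, plain])
        assert (a.fs_per100g, a.step) == (9.0, 5)

    def test_missing_equivalent_falls_through_with_warning(self, caplog):
        sweet = make_food("SW", "sweetened muesli", group="rtebc", ts=25.0,
                          has_unsweetened_equivalent=True,
                          unsweetened_equivalent_code="GONE",
                          recipe_fraction_free=0.4)
        with caplog.at_level("WARNING"):
            a = assign_fs(sweet, [sweet])
        assert (a.fs_per100g, a.step) == (10.0, 6)
        assert "GONE" in caplog.text

    def test_fifty_percent_fallback_when_nothing_known(self):
        mystery = make_food("X", "mystery dish", group="other", ts=6.0)
        a = assign_fs(mystery, [mystery])
        assert (a.fs_per100g, a.step, a.objective) == (3.0, 9, False)

    def test_borrow_from_similar_food_in_group(self):
        known = make_food("A", "chocolate chip biscuit", group="cakes_and_biscuits",
                          ts=24.0, recipe_fraction_free=0.85)
        unknown = make_food("B", "chocolate chip cookie", group="cakes_and_biscuits",
                            ts=26.0)
        a = assign_fs(unknown, [known, unknown])
        assert a.step == 7
        assert a.fs_per100g == pytest.approx(24.0 * 0.85)

    def test_group_median_ratio_fallback(self):
        objective = [
            make_food("A", "frosted flakes", group="rtebc", ts=35.0,
                      recipe_fraction_free=0.9),
            make_food("B", "honey hoops", group="rtebc", ts=30.0,
                      recipe_fraction_free=0.5),
        ]
        unknown = make_food("C", "unbranded cereal", group="rtebc", ts=10.0)
        a = assign_fs(unknown, objective + [unknown], LadderConfig())
        assert a.step == 8
        assert a.fs_per100g == pytest.approx(10.0 * median([0.9, 0.5]))

    def test_diet_beverage_not_pure_sugar(self):
        diet = make_food("D", "diet cola", group="soft_drinks_diet", ts=0.0,
                         is_diet_beverage=True, is_pure_sugar_product=True)
        a = assign_fs(diet, [diet])
        assert a.fs_per100g == 0.0  # clipped to TS regardless of rung

    def test_negative_intermediate_floored_at_zero(self):
        noisy = make_food("N", "noisy", group="dairy_products", ts=4.0, lactose=6.0)
        a = assign_fs(noisy, [noisy])
        assert (a.fs_per100g, a.step) == (0.0, 4)


class TestApplyLadder:
    def test_step_histogram_on_mixed_table(self):
        table = (
            [make_food(f"U{i}", f"plain food {i}", group="fruit_and_vegetables",
                       ts=5.0, is_unprocessed_whole_food=True) for i in range(3)]
            + [make_food(f"J{i}", f"juice {i}", group="fruit_juice_and_smoothies",
                         ts=10.0, is_fruit_juice=True) for i in range(2)]
            + [make_food(f"L{i}", f"dairy {i}", group="dairy_products",
                         ts=12.0, lactose=4.0) for i in range(3)]
            + [make_food(f"P{i}", f"opaque product {i}", group="other",
                         ts=6.0) for i in range(2)]
        )
        assignments = apply_ladder(table)
        assert len(assignments) == len(table)
        assert Counter(a.step for a in assignments) == {1: 3, 2: 2, 4: 3, 9: 2}

    def test_all_unprocessed_gives_zero(self):
        table = [make_food(f"U{i}", ts=float(i + 1),
                           is_unprocessed_whole_food=True) for i in range(4)]
        assert all(a.fs_per100g == 0.0 for a in apply_ladder(table))

    def test_empty_table(self):
        assert apply_ladder([]) == []

    def test_deterministic(self, toy_foods):
        assert apply_ladder(toy_foods) == apply_ladder(toy_foods)


# ---------------------------------------------------------------------------
# properties on randomized tables
# ---------------------------------------------------------------------------

GROUPS = ["dairy_products", "rtebc", "cakes_and_biscuits", "other"]


@st.composite
def food_tables(draw, max_size=20):
    n = draw(st.integers(1, max_size))
    items = []
    for i in range(n):
        ts = draw(st.floats(0.0, 100.0, allow_nan=False))
        kind = draw(st.integers(0, 5))
        kwargs = {}
        lactose = None
        if kind == 0:
            kwargs["is_unprocessed_whole_food"] = True
        elif kind == 1:
            kwargs["is_fruit_juice"] = True
        elif kind == 2:
            kwargs["is_pure_sugar_product"] = True
        elif kind == 3:
            lactose = draw(st.floats(0.0, 120.0, allow_nan=False))
        elif kind == 4:
            kwargs["recipe_fraction_free"] = draw(st.floats(0.0, 1.0,
                                                            allow_nan=False))
        items.append(
            make_food(f"F{i}", f"food number {i}",
                      group=draw(st.sampled_from(GROUPS)),
                      ts=ts, lactose=lactose, **kwargs)
        )
    return items


@given(food_tables())
@settings(max_examples=75, deadline=None)
def test_fs_clipped_between_zero_and_ts(table):
    """Every assignment respects 0 <= FS <= TS whatever the table looks like."""
    by_code = {f.food_code: f for f in table}
    for a in apply_ladder(table):
        assert 0.0 <= a.fs_per100g <= by_code[a.food_code].total_sugar_per100g


@given(food_tables())
@settings(max_examples=40, deadline=None)
def test_ladder_matches_bruteforce_oracle(table):
    """On small tables the ladder equals independent per-item rung evaluation."""
    expected = oracle_ladder(table)
    for a in apply_ladder(table):
        fs, step = expected[a.food_code]
        assert a.step == step
        assert a.fs_per100g == pytest.approx(fs, abs=1e-12)


@given(st.floats(0.0, 12.0, allow_nan=False), st.floats(0.0, 12.0, allow_nan=False))
@settings(max_examples=50, deadline=None)
def test_rung4_monotone_in_lactose(l1, l2):
    """More analytical lactose never raises the free-sugar estimate."""
    lo, hi = sorted([l1, l2])
    f_lo = make_food("A", ts=12.0, lactose=lo)
    f_hi = make_food("A", ts=12.0, lactose=hi)
    assert assign_fs(f_hi, [f_hi]).fs_per100g <= assign_fs(f_lo, [f_lo]).fs_per100g


# ---------------------------------------------------------------------------
# reconciliation and distribution comparison
# ---------------------------------------------------------------------------


def _assignments(values):
    return [FSAssignment(code, v, 9, "", False) for code, v in values.items()]


class TestReconcile:
    def test_identical_sets_no_discrepancies(self):
        a = _assignments({"F1": 5.0, "F2": 8.0})
        assert reconcile(a, a) == []

    def test_difference_above_tolerance_flagged(self):
        a = _assignments({"F1": 5.0, "F2": 8.0})
        b = _assignments({"F1": 7.0, "F2": 8.0})
        records = reconcile(a, b, tolerance=0.5)
        assert len(records) == 1
        assert records[0].food_code == "F1"
        assert records[0].absolute_difference == pytest.approx(2.0)
        assert records[0].resolved_value is None

    def test_difference_equal_to_tolerance_not_flagged(self):
        a = _assignments({"F1": 5.0})
        b = _assignments({"F1": 5.5})
        assert reconcile(a, b, tolerance=0.5) == []

    def test_mismatched_code_sets_error(self):
        with pytest.raises(LadderError, match="F2"):
            reconcile(_assignments({"F1": 1.0}), _assignments({"F2": 1.0}))


class TestCompareDistributions:
    def test_identical_vectors(self):
        r = compare_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic_D == 0.0
        assert not r.significant

    def test_disjoint_supports(self):
        r = compare_distributions([0.0] * 50, [10.0] * 50)
        assert r.statistic_D == 1.0
        assert r.significant

    def test_empty_vector_rejected(self):
        with pytest.raises(LadderError):
            compare_distributions([], [1.0])

    def test_null_rarely_rejected_at_one_percent(self):
        """Same-distribution samples stay non-significant in >=95% of replicates."""
        not_sig = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a, b = rng.lognormal(1.0, 0.5, 200), rng.lognormal(1.0, 0.5, 200)
            not_sig += not compare_distributions(a, b, alpha=0.01).significant
        assert not_sig >= 95
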