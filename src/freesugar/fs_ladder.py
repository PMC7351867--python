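"""Stepwise free-sugar (FS) estimation ladder.

Analytical food composition data report *total* sugar (TS); free sugar — all
added sugar plus the sugar naturally present in honey, syrups and fruit juice —
cannot be measured chemically and must be estimated.  This module implements a
ten-rung decision ladder in the tradition of stepwise added-sugar protocols,
modified so that fruit-juice sugars count as free: rungs 1–6 are objective
(flags, analytical lactose, unsweetened equivalents, recipe data), rungs 7–10
are subjective fallbacks (borrowed values, group ratios, fixed fractions).
The first applicable rung wins and every assignment records its rung and a
one-line rationale, so the provenance of each FS value is auditable.

Two independent estimate sets can be reconciled (:func:`reconcile`) and whole
FS distributions compared with a two-sample Kolmogorov–Smirnov test
(:func:`compare_distributions`).
"""

from __future__ import annotations

import difflib
import logging
from collections import Counter
from dataclasses import dataclass, field
from statistics import median
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .food_composition import FoodItem

__all__ = [
    "FSAssignment",
    "DiscrepancyRecord",
    "KSResult",
    "LadderConfig",
    "LadderError",
    "assign_fs",
    "apply_ladder",
    "reconcile",
    "compare_distributions",
    "OBJECTIVE_STEPS",
]

logger = logging.getLogger(__name__)

#: Rungs whose outcome rests on analytical data or ingredients, not judgement.
OBJECTIVE_STEPS = frozenset({1, 2, 3, 4, 5, 6})


class LadderError(ValueError):
    pass


@dataclass(frozen=True)
class FSAssignment:
    """Free-sugar value for one food, with rung provenance."""

    food_code: str
    fs_per100g: float
    step: int
    rationale: str
    objective: bool

    def __post_init__(self) -> None:
        if not 1 <= self.step <= 10:
            raise LadderError(f"step must be in 1..10, got {self.step}")
        if self.fs_per100g < 0:
            raise LadderError(f"fs_per100g must be >= 0, got {self.fs_per100g}")


@dataclass(frozen=True)
class DiscrepancyRecord:
    """One food whose two independent FS estimates disagree beyond tolerance."""

    food_code: str
    estimate_a: float
    estimate_b: float
    absolute_difference: float
    resolved_value: float | None = None  # adjudication is an input, never computed


@dataclass(frozen=True)
class KSResult:
    statistic_D: float
    p_value: float
    significant_at: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.significant_at


@dataclass(frozen=True)
class LadderConfig:
    """Ladder tunables.

    ``step_order`` lets alternative ladders be swapped in; the default is the
    canonical 1..10 order with first-match-wins semantics.  ``borrow_similarity``
    is the minimum description similarity (normalized in [0, 1]) for rung 7 to
    borrow a value from the most similar objectively-assigned food in the same
    coarse group.
    """

    step_order: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
    borrow_similarity: float = 0.6
    reconcile_tolerance: float = 0.1  # g/100 g; strictly-greater flags

    def __post_init__(self) -> None:
        if sorted(self.step_order) != sorted(set(self.step_order)):
            raise LadderError("step_order must not repeat rungs")
        if any(not 1 <= s <= 10 for s in self.step_order):
            raise LadderError("step_order entries must be in 1..10")


def _clip(fs: float, ts: float) -> float:
    """FS can never be negative nor exceed the food's total sugar."""
    return min(max(fs, 0.0), ts)


# Each rung: (item, context) -> (fs, rationale) or None when not applicable.
_RungFn = Callable[["_RungContext", FoodItem], "tuple[float, str] | None"]


@dataclass
class _RungContext:
    by_code: dict[str, FoodItem]
    config: LadderConfig
    # objective assignments of other foods, for rungs 7-8; filled lazily
    objective_by_code: dict[str, FSAssignment] = field(default_factory=dict)


def _rung_1(ctx: _RungContext, item: FoodItem):
    if item.flags.is_unprocessed_whole_food:
        return 0.0, "unprocessed whole food: intrinsic sugars only"
    return None


def _rung_2(ctx: _RungContext, item: FoodItem):
    if item.flags.is_fruit_juice:
        return item.total_sugar_per100g, "fruit juice/smoothie: all sugar free"
    return None


def _rung_3(ctx: _RungContext, item: FoodItem):
    # diet beverages are excluded; with TS ~ 0 they resolve to FS = 0 anyway
    if item.flags.is_pure_sugar_product and not item.flags.is_diet_beverage:
        return item.total_sugar_per100g, "pure-sugar product: FS = TS"
    return None


def _rung_4(ctx: _RungContext, item: FoodItem):
    if (
        not item.flags.has_unsweetened_equivalent
        and item.lactose_per100g is not None
    ):
        fs = item.total_sugar_per100g - item.lactose_per100g
        return fs, "no unsweetened equivalent; FS = TS - lactose"
    return None


def _rung_5(ctx: _RungContext, item: FoodItem):
    if not item.flags.has_unsweetened_equivalent:
        return None
    code = item.flags.unsweetened_equivalent_code
    if code is None or code not in ctx.by_code:
        logger.warning(
            "food %s: unsweetened equivalent %r absent from table; "
            "falling through to next rung",
            item.food_code,
            code,
        )
        return None
    fs = item.total_sugar_per100g - ctx.by_code[code].total_sugar_per100g
    return fs, f"FS = TS - TS(unsweetened equivalent {code})"


def _rung_6(ctx: _RungContext, item: FoodItem):
    f = item.flags.recipe_fraction_free
    if f is not None:
        return f * item.total_sugar_per100g, f"recipe data: {f:.0%} of TS free"
    return None


def _rung_7(ctx: _RungContext, item: FoodItem):
    best: tuple[float, FSAssignment] | None = None
    for code, assignment in ctx.objective_by_code.items():
        other = ctx.by_code[code]
        if other.group is not item.group or code == item.food_code:
            continue
        score = difflib.SequenceMatcher(
            None, item.description.lower(), other.description.lower()
        ).ratio()
        if score >= ctx.config.borrow_similarity and (
            best is None or score > best[0]
        ):
            best = (score, assignment)
    if best is None:
        return None
    score, assignment = best
    return (
        assignment.fs_per100g,
        f"borrowed from most similar food {assignment.food_code} "
        f"(similarity {score:.2f})",
    )


def _rung_8(ctx: _RungContext, item: FoodItem):
    ratios = [
        a.fs_per100g / ctx.by_code[c].total_sugar_per100g
        for c, a in ctx.objective_by_code.items()
        if ctx.by_code[c].group is item.group
        and c != item.food_code
        and ctx.by_code[c].total_sugar_per100g > 0
    ]
    if not ratios:
        return None
    ratio = median(ratios)
    return (
        ratio * item.total_sugar_per100g,
        f"group-median FS/TS ratio {ratio:.3f}",
    )


def _rung_9(ctx: _RungContext, item: FoodItem):
    return 0.5 * item.total_sugar_per100g, "assumed 50% of TS free"


def _rung_10(ctx: _RungContext, item: FoodItem):
    return item.total_sugar_per100g, "assumed 100% of TS free"


_RUNGS: dict[int, _RungFn] = {
    1: _rung_1,
    2: _rung_2,
    3: _rung_3,
    4: _rung_4,
    5: _rung_5,
    6: _rung_6,
    7: _rung_7,
    8: _rung_8,
    9: _rung_9,
    10: _rung_10,
}


def _evaluate(ctx: _RungContext, item: FoodItem, steps: Sequence[int]) -> FSAssignment | None:
    if item.total_sugar_per100g is None:
        raise LadderError(f"food {item.food_code}: total sugar missing")
    for step in steps:
        result = _RUNGS[step](ctx, item)
        if result is None:
            continue
        fs, rationale = result
        return FSAssignment(
            food_code=item.food_code,
            fs_per100g=_clip(fs, item.total_sugar_per100g),
            step=step,
            rationale=rationale,
            objective=step in OBJECTIVE_STEPS,
        )
    return None


def _build_context(table: Sequence[FoodItem], config: LadderConfig) -> _RungContext:
    ctx = _RungContext(by_code={it.food_code: it for it in table}, config=config)
    objective_steps = [s for s in config.step_order if s in OBJECTIVE_STEPS]
    for it in table:
        a = _evaluate(ctx, it, objective_steps)
        if a is not None:
            ctx.objective_by_code[it.food_code] = a
    return ctx


def assign_fs(
    item: FoodItem,
    table: Sequence[FoodItem],
    config: LadderConfig | None = None,
) -> FSAssignment:
    """Assign free sugar to a single food via the first applicable rung.

    ``table`` supplies the context the reference rungs need: unsweetened
    equivalents (rung 5) and the objectively-assigned same-group foods that
    rungs 7–8 borrow from.  The result is clipped to ``[0, TS]``.
    """
    config = config or LadderConfig()
    ctx = _build_context(table, config)
    a = _evaluate(ctx, item, config.step_order)
    if a is None:
        raise LadderError(
            f"food {item.food_code}: no ladder rung applicable "
            f"(step_order={config.step_order})"
        )
    return a


def apply_ladder(
    items: Sequence[FoodItem],
    config: LadderConfig | None = None,
) -> list[FSAssignment]:
    """Assign free sugar to every food in a table.

    Two passes: objective rungs first for all items (building the pool that
    the subjective borrow/ratio rungs draw on), then the full rung order for
    the remainder.  Deterministic for a fixed table and config.  A per-step
    histogram is logged for audit.
    """
    config = config or LadderConfig()
    ctx = _build_context(items, config)
    assignments: list[FSAssignment] = []
    for it in items:
        a = ctx.objective_by_code.get(it.food_code)
        if a is None:
            a = _evaluate(ctx, it, config.step_order)
        if a is None:
            raise LadderError(f"food {it.food_code}: no ladder rung applicable")
        assignments.append(a)
    histogram = Counter(a.step for a in assignments)
    logger.info("ladder step histogram: %s", dict(sorted(histogram.items())))
    return assignments


def reconcile(
    a: Sequence[FSAssignment],
    b: Sequence[FSAssignment],
    tolerance: float = 0.1,
) -> list[DiscrepancyRecord]:
    """Flag foods where two independent estimate sets differ by more than ``tolerance``.

    Mirrors dual-researcher estimation with third-party adjudication: the
    discrepancy list is what goes to the adjudicator; ``resolved_value`` stays
    unset here.  A difference exactly equal to the tolerance is *not* flagged
    (strict inequality).
    """
    map_a = {x.food_code: x.fs_per100g for x in a}
    map_b = {x.food_code: x.fs_per100g for x in b}
    if map_a.keys() != map_b.keys():
        diff = sorted(map_a.keys() ^ map_b.keys())
        raise LadderError(f"estimate sets cover different foods: {diff}")
    records = []
    for code in map_a:
        delta = abs(map_a[code] - map_b[code])
        if delta > tolerance:
            records.append(
                DiscrepancyRecord(
                    food_code=code,
                    estimate_a=map_a[code],
                    estimate_b=map_b[code],
                    absolute_difference=delta,
                )
            )
    return records


def compare_distributions(
    fs_a: Sequence[float] | np.ndarray,
    fs_b: Sequence[float] | np.ndarray,
    alpha: float = 0.01,
) -> KSResult:
    """Two-sample Kolmogorov–Smirnov comparison of two FS distributions."""
    fs_a = np.asarray(fs_a, dtype=float)
    fs_b = np.asarray(fs_b, dtype=float)
    if fs_a.size == 0 or fs_b.size == 0:
        raise LadderError("compare_distributions requires non-empty samples")
    result = stats.ks_2samp(fs_a, fs_b)
    return KSResult(
        statistic_D=float(result.statistic),
        p_value=float(result.pvalue),
        significant_at=alpha,
    )
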