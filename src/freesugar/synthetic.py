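"""Seeded synthetic preschool cohort: food table, subjects and 4-day diaries.

The real survey data behind this kind of analysis (national cohort and
nutrition surveys) are access-restricted, so the pipeline is exercised on a
generated stand-in calibrated to published cohort-level parameters for Irish
3-year-olds: 126 children (52% girls), 4 diary days, free-sugar %TEI
right-skewed with arithmetic mean 14.1 and SD 5.81 (drawn lognormal — a
normal law is incompatible with <4% of children below 5 %TEI at that
mean/SD), energy intake around 4.8 MJ/day, and per-food-group consumer
percentages, free-sugar contributions, frequencies and snack probabilities
taken from the published group table.

Generation is target-driven: each child draws a free-sugar %TEI and an
energy intake, and food amounts are back-solved from the ladder-assigned
free-sugar content of each food (then jittered ±10%), so running the full
pipeline over a generated cohort recovers the configured parameters.  A
filler/staple stream tops every day's energy up to the child's drawn intake.
Everything is reproducible: (config, seed) determines the output exactly.

The synthetic food table is fixed (not seed-dependent) and constructed so the
estimation ladder exercises its objective rungs 1–6 and the subjective
borrow/group-ratio rungs; the shipped synthetic SFQ definitions deliberately
omit breakfast cereals, fruit juices and sugars/syrups so that roughly one
third of free-sugar intake is non-covered, mirroring the published coverage
finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diary import DiaryEntry, Subject, entries_to_frame
from .food_composition import FoodGroup, FoodItem, LadderFlags
from .fs_ladder import LadderConfig, apply_ladder
from .sfq_mapping import SFQGroup, load_sfq_groups

__all__ = [
    "GroupProfile",
    "GeneratorConfig",
    "generate_food_db",
    "generate_subjects",
    "generate_diaries",
    "generate_cohort",
    "sample_fs_pct_tei",
    "lognormal_params_from_moments",
    "default_sfq_groups",
    "write_cohort_csvs",
]


@dataclass(frozen=True)
class GroupProfile:
    """Calibration surface for one coarse food group.

    ``fs_g_day`` is the group's mean free-sugar contribution over *all*
    subjects (consumers and non-consumers alike); ``entry_rate`` the mean
    number of sugar-bearing diary entries per day for a consumer of the group;
    ``snack_probability`` the chance any entry of the group happens at a snack
    rather than a main meal.
    """

    consumer_probability: float
    fs_g_day: float
    entry_rate: float
    snack_probability: float

    def __post_init__(self) -> None:
        for p in (self.consumer_probability, self.snack_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must be in [0,1], got {p}")


# Published cohort group table (percent consumers, mean FS g/day over all
# subjects, sugar-entry frequency, probability-as-snack), restated as the
# generator's stated world.
DEFAULT_GROUP_PROFILES: dict[str, GroupProfile] = {
    "fruit_juice_and_smoothies": GroupProfile(0.730, 8.4, 0.7, 0.27),
    "dairy_products": GroupProfile(1.000, 8.2, 1.0, 0.26),
    "soft_drinks_non_diet": GroupProfile(0.714, 4.8, 0.9, 0.30),
    "chocolate_confectionary": GroupProfile(0.595, 3.1, 0.3, 0.73),
    "cakes_and_biscuits": GroupProfile(0.897, 4.4, 0.8, 0.69),
    "non_chocolate_confectionary": GroupProfile(0.452, 2.2, 0.2, 0.66),
    "sugar_and_syrups": GroupProfile(0.563, 2.5, 0.4, 0.18),
    "desserts_and_puddings": GroupProfile(0.254, 0.9, 0.15, 0.37),
    "rtebc": GroupProfile(0.921, 3.1, 0.9, 0.05),
    "other": GroupProfile(1.000, 1.3, 0.3, 0.21),
    "bread_and_cereals": GroupProfile(1.000, 0.7, 0.5, 0.19),
    "fruit_and_vegetables": GroupProfile(1.000, 0.4, 0.15, 0.33),
    "soft_drinks_diet": GroupProfile(0.100, 0.0, 0.3, 0.50),
}

#: Groups the synthetic SFQ cannot see; their consumptions are non-covered.
DEFAULT_NONCOVERED_GROUPS = frozenset(
    {"rtebc", "fruit_juice_and_smoothies", "sugar_and_syrups"}
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated-world parameters of the synthetic cohort."""

    n_subjects: int = 126
    n_days: int = 4
    girl_probability: float = 0.52
    # energy intake, MJ/day: mean backed out of the published g/day vs %TEI
    # figures; SD a realistic ~19% CV for this age
    tei_mean: float = 4.8
    tei_sd: float = 0.9
    # free-sugar %TEI, lognormal by arithmetic mean/SD
    fs_pct_mean: float = 14.1
    fs_pct_sd: float = 5.81
    # stated daily sugar-bearing eating-occasion rates (Poisson means):
    # free-sugar occasions and total-sugar occasions; the diary machinery
    # approximates these through the per-group entry rates
    fs_occasion_rate: float = 3.9
    ts_occasion_rate: float = 5.2
    amount_jitter: float = 0.10
    # anthropometry at age 3 (normal, clipped to plausible ranges)
    weight_mean_kg: float = 15.1
    weight_sd_kg: float = 1.8
    height_mean_cm: float = 96.0
    height_sd_cm: float = 4.0
    group_profiles: dict[str, GroupProfile] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROFILES)
    )
    noncovered_groups: frozenset[str] = DEFAULT_NONCOVERED_GROUPS


def config_from_mapping(overrides: dict) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a plain mapping (e.g. parsed YAML).

    Scalar keys override the corresponding config fields; the optional
    ``group_profiles`` key maps group names to
    ``{consumer_probability, fs_g_day, entry_rate, snack_probability}`` and
    is merged over the defaults.
    """
    overrides = dict(overrides)
    profiles = dict(DEFAULT_GROUP_PROFILES)
    for name, spec in overrides.pop("group_profiles", {}).items():
        if name not in profiles:
            raise ValueError(f"unknown food group in config: {name!r}")
        profiles[name] = GroupProfile(**spec)
    unknown = set(overrides) - {f.name for f in fields(GeneratorConfig)}
    if unknown:
        raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
    if "noncovered_groups" in overrides:
        overrides["noncovered_groups"] = frozenset(overrides["noncovered_groups"])
    return GeneratorConfig(group_profiles=profiles, **overrides)


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given *arithmetic* mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def sample_fs_pct_tei(
    n: int,
    rng: np.random.Generator,
    mean: float = 14.1,
    sd: float = 5.81,
) -> np.ndarray:
    """Draw free-sugar %TEI values, lognormal at the configured moments."""
    mu, sigma = lognormal_params_from_moments(mean, sd)
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def _f(code, desc, src, group, ts, lactose=None, energy=None, **flags) -> FoodItem:
    return FoodItem(
        food_code=code,
        description=desc,
        source_group=src,
        group=FoodGroup(group),
        total_sugar_per100g=ts,
        lactose_per100g=lactose,
        energy_per100g=energy,
        flags=LadderFlags(**flags),
    )


def generate_food_db(
    config: GeneratorConfig | None = None, seed: int = 0
) -> list[FoodItem]:
    """The synthetic food composition table (fixed; seed accepted for API symmetry).

    Covers all 13 coarse groups with at least three foods each and flag
    combinations that exercise ladder rungs 1–6 plus the subjective
    borrow (7) and group-ratio (8) fallbacks.
    """
    del config, seed  # table is a fixed stated world
    items = [
        # fruit juice & smoothies -> rung 2 (all sugar free)
        _f("JUI1", "pressed orange juice", "Fruit juices", "fruit_juice_and_smoothies",
           10.4, energy=0.19, is_fruit_juice=True),
        _f("JUI2", "pure pressed juice blend", "Fruit juices", "fruit_juice_and_smoothies",
           11.0, energy=0.20, is_fruit_juice=True),
        _f("JUI3", "berry smoothie drink", "Smoothies", "fruit_juice_and_smoothies",
           12.5, energy=0.25, is_fruit_juice=True),
        # dairy: plain milk rung 1; sweetened products rung 4 (TS - lactose)
        _f("DAI1", "whole milk plain", "Milk", "dairy_products",
           4.8, lactose=4.8, energy=0.27, is_unprocessed_whole_food=True),
        _f("DAI2", "yoghurt strawberry sweetened", "Yoghurt", "dairy_products",
           12.0, lactose=4.0, energy=0.41),
        _f("DAI3", "vanilla ice cream", "Ice cream", "dairy_products",
           21.0, lactose=6.0, energy=0.80),
        _f("DAI4", "fromage frais fruit sweetened", "Yoghurt", "dairy_products",
           13.0, lactose=4.5, energy=0.50),
        # soft drinks -> rung 3 (pure sugar, no milk); diet variant rung 6 at 0
        _f("SDR1", "cola carbonated", "Carbonated beverage", "soft_drinks_non_diet",
           10.6, energy=0.19, is_pure_sugar_product=True),
        _f("SDR2", "lemonade carbonated", "Carbonated beverage", "soft_drinks_non_diet",
           9.0, energy=0.16, is_pure_sugar_product=True),
        _f("SDR3", "squash diluted to drink", "Squash", "soft_drinks_non_diet",
           5.5, energy=0.10, is_pure_sugar_product=True),
        _f("SDD1", "diet cola carbonated", "Carbonated beverage", "soft_drinks_diet",
           0.0, energy=0.002, is_diet_beverage=True, recipe_fraction_free=0.0),
        _f("SDD2", "sugar free lemonade", "Carbonated beverage", "soft_drinks_diet",
           0.1, energy=0.004, is_diet_beverage=True, recipe_fraction_free=0.0),
        _f("SDD3", "no added sugar squash diluted", "Squash", "soft_drinks_diet",
           0.3, energy=0.006, is_diet_beverage=True, recipe_fraction_free=0.0),
        # chocolate: milk solids -> rung 4; dark with unsweetened equivalent -> rung 5
        _f("CHO1", "milk chocolate bar", "Chocolate", "chocolate_confectionary",
           52.0, lactose=8.0, energy=2.20),
        _f("CHO2", "chocolate buttons", "Chocolate", "chocolate_confectionary",
           55.0, lactose=9.0, energy=2.30),
        _f("CHO3", "dark chocolate bar", "Chocolate", "chocolate_confectionary",
           28.0, energy=2.40, has_unsweetened_equivalent=True,
           unsweetened_equivalent_code="OTH1"),
        # cakes & biscuits: recipe data rung 6; two judgement foods for rungs 7/8
        _f("CAK1", "digestive biscuit", "Biscuits", "cakes_and_biscuits",
           16.0, energy=2.00, recipe_fraction_free=0.90),
        _f("CAK2", "sponge cake", "Cakes", "cakes_and_biscuits",
           35.0, energy=1.60, recipe_fraction_free=0.95),
        _f("CAK3", "chocolate chip biscuit", "Biscuits", "cakes_and_biscuits",
           24.0, energy=2.10, recipe_fraction_free=0.85),
        _f("CAK4", "chocolate chip cookie", "Biscuits", "cakes_and_biscuits",
           26.0, energy=2.15),  # rung 7: borrows from CAK3
        _f("CAK5", "plain scone", "Cakes", "cakes_and_biscuits",
           8.0, energy=1.45),  # rung 8: group-median FS/TS ratio
        _f("CAK6", "iced fairy cake", "Cakes", "cakes_and_biscuits",
           54.0, energy=1.70, recipe_fraction_free=0.96),
        # non-chocolate confectionery -> rung 3
        _f("NCC1", "jelly sweets", "Sweets", "non_chocolate_confectionary",
           60.0, energy=1.40, is_pure_sugar_product=True),
        _f("NCC2", "boiled sweets", "Sweets", "non_chocolate_confectionary",
           87.0, energy=1.50, is_pure_sugar_product=True),
        _f("NCC3", "marshmallow", "Sweets", "non_chocolate_confectionary",
           65.0, energy=1.40, is_pure_sugar_product=True),
        # sugar & syrups -> rung 3
        _f("SUG1", "granulated white sugar", "Sugars", "sugar_and_syrups",
           100.0, energy=1.70, is_pure_sugar_product=True),
        _f("SUG2", "runny honey", "Sugars", "sugar_and_syrups",
           76.0, energy=1.30, is_pure_sugar_product=True),
        _f("SUG3", "golden syrup", "Syrups", "sugar_and_syrups",
           79.0, energy=1.35, is_pure_sugar_product=True),
        # desserts -> rungs 4 and 6
        _f("DES1", "custard made up", "Puddings", "desserts_and_puddings",
           11.0, lactose=4.0, energy=0.40),
        _f("DES2", "rice pudding", "Puddings", "desserts_and_puddings",
           10.0, lactose=3.5, energy=0.37),
        _f("DES3", "jelly dessert made up", "Puddings", "desserts_and_puddings",
           14.0, energy=0.25, recipe_fraction_free=1.0),
        # ready-to-eat breakfast cereals -> rung 6
        _f("RTE1", "frosted flakes", "RTEBC", "rtebc",
           35.0, energy=1.60, recipe_fraction_free=0.93),
        _f("RTE2", "honey hoops", "RTEBC", "rtebc",
           29.0, energy=1.55, recipe_fraction_free=0.90),
        _f("RTE3", "wheat biscuit breakfast", "RTEBC", "rtebc",
           4.4, energy=1.50, recipe_fraction_free=0.45),
        # other: unsweetened equivalent target, a sauce, and two fillers
        _f("OTH1", "cocoa powder unsweetened", "Miscellaneous", "other",
           2.0, energy=1.40, recipe_fraction_free=0.0),
        _f("OTH2", "tomato ketchup", "Sauces", "other",
           23.0, energy=0.45, recipe_fraction_free=1.0),
        _f("OTH3", "pasta cooked plain", "Starchy staples", "other",
           1.0, energy=0.55, recipe_fraction_free=0.0),
        _f("OTH4", "chicken casserole dish", "Composite dishes", "other",
           1.6, energy=0.60, recipe_fraction_free=0.25),
        # bread & cereals -> rung 6 / rung 1
        _f("BRE1", "white bread sliced", "Breads", "bread_and_cereals",
           3.0, energy=1.00, recipe_fraction_free=0.50),
        _f("BRE2", "wholemeal bread sliced", "Breads", "bread_and_cereals",
           2.8, energy=0.95, recipe_fraction_free=0.30),
        _f("BRE3", "porridge oats plain boiled", "Cereal dishes", "bread_and_cereals",
           1.1, energy=0.49, is_unprocessed_whole_food=True),
        _f("BRE4", "malt loaf sliced", "Breads", "bread_and_cereals",
           30.0, energy=1.25, recipe_fraction_free=0.65),
        # fruit & vegetables -> rung 1 (intrinsic); one sweetened dish rung 6
        _f("FRU1", "apple raw whole", "Fruit", "fruit_and_vegetables",
           11.8, energy=0.21, is_unprocessed_whole_food=True),
        _f("FRU2", "banana raw whole", "Fruit", "fruit_and_vegetables",
           20.9, energy=0.40, is_unprocessed_whole_food=True),
        _f("FRU3", "carrot boiled", "Vegetables", "fruit_and_vegetables",
           4.6, energy=0.15, is_unprocessed_whole_food=True),
        _f("FRU4", "stewed apple with sugar", "Fruit dishes", "fruit_and_vegetables",
           15.0, energy=0.30, recipe_fraction_free=0.35),
    ]
    return items


def generate_subjects(
    config: GeneratorConfig | None = None, seed: int = 0
) -> list[Subject]:
    """Draw the cohort roster: sex, age in months (36–47) and anthropometry."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    girls = rng.random(n) < config.girl_probability
    ages = rng.integers(36, 48, size=n)
    weights = np.clip(
        rng.normal(config.weight_mean_kg, config.weight_sd_kg, size=n), 9.0, 25.0
    )
    heights = np.clip(
        rng.normal(config.height_mean_cm, config.height_sd_cm, size=n), 80.0, 112.0
    )
    return [
        Subject(
            subject_id=f"S{i + 1:05d}",
            sex="female" if girls[i] else "male",
            age_months=int(ages[i]),
            weight_kg=round(float(weights[i]), 1),
            height_cm=round(float(heights[i]), 1),
        )
        for i in range(n)
    ]


# Sugar-bearing foods drawn by the free-sugar stream, per group.  Amounts are
# back-solved from free-sugar targets, so foods whose FS per 100 g is tiny for
# their group (RTE3, BRE2, CAK5) are excluded here — back-solving through them
# would imply implausible portions and blow the day's energy budget.  They
# remain in the table and keep exercising the ladder.
_SUGAR_FOODS: dict[str, tuple[str, ...]] = {
    "fruit_juice_and_smoothies": ("JUI1", "JUI2", "JUI3"),
    "dairy_products": ("DAI2", "DAI3", "DAI4"),
    "soft_drinks_non_diet": ("SDR1", "SDR2", "SDR3"),
    "chocolate_confectionary": ("CHO1", "CHO2"),
    "cakes_and_biscuits": ("CAK2", "CAK6"),
    "non_chocolate_confectionary": ("NCC1", "NCC2", "NCC3"),
    "sugar_and_syrups": ("SUG1", "SUG2", "SUG3"),
    "desserts_and_puddings": ("DES1", "DES2", "DES3"),
    "rtebc": ("RTE1", "RTE2"),
    "other": ("OTH2",),
    "bread_and_cereals": ("BRE4",),
    "fruit_and_vegetables": ("FRU4",),
}

# zero-free-sugar staples: (food_code, baseline grams/day, group); these add
# total sugar and energy without perturbing the subject's free-sugar target
_STAPLES: tuple[tuple[str, float, str], ...] = (
    ("DAI1", 280.0, "dairy_products"),  # plain milk
    ("FRU1", 90.0, "fruit_and_vegetables"),
    ("FRU3", 50.0, "fruit_and_vegetables"),
    ("BRE3", 60.0, "bread_and_cereals"),  # plain porridge
)
_FILLER_CODE = "OTH3"  # pasta: tops the day's energy up to the drawn intake
_MIN_STAPLE_SCALE = 0.15

_MEAL_SLOTS = ("m1", "m2", "m3")
_SNACK_SLOTS = ("s1", "s2", "s3")


def generate_diaries(
    subjects: Sequence[Subject],
    foods: Sequence[FoodItem],
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> list[DiaryEntry]:
    """Generate 4-day diaries whose pipeline aggregates recover the configured world."""
    frame = generate_diary_frame(subjects, foods, config, seed)
    return [
        DiaryEntry(
            subject_id=r.subject_id,
            survey_day=int(r.survey_day),
            occasion_seq=int(r.occasion_seq),
            occasion_type=r.occasion_type,
            food_code=r.food_code,
            amount_g=float(r.amount_g),
        )
        for r in frame.itertuples(index=False)
    ]


def generate_diary_frame(
    subjects: Sequence[Subject],
    foods: Sequence[FoodItem],
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """DataFrame twin of :func:`generate_diaries` (faster for large cohorts)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    fs100 = {
        a.food_code: a.fs_per100g for a in apply_ladder(list(foods), LadderConfig())
    }
    en100 = {f.food_code: (f.energy_per100g or 0.0) for f in foods}

    profiles = config.group_profiles
    fs_groups = [g for g in _SUGAR_FOODS if g in profiles and profiles[g].fs_g_day > 0]
    n_days = config.n_days
    jitter = config.amount_jitter
    filler_en = en100[_FILLER_CODE] / 100.0

    rows: list[tuple] = []  # subject_id, day, slot, food_code, amount_g
    drawn_targets: list[tuple[str, float, float]] = []  # id, tei, fs %TEI

    for subj in subjects:
        tei = max(float(rng.normal(config.tei_mean, config.tei_sd)), 2.0)
        pct = float(
            sample_fs_pct_tei(1, rng, config.fs_pct_mean, config.fs_pct_sd)[0]
        )
        fs_target_day = pct / 100.0 * tei / 0.017  # g/day
        drawn_targets.append((subj.subject_id, tei, pct))

        consumed = [
            g for g in fs_groups if rng.random() < profiles[g].consumer_probability
        ]
        diet_drinker = rng.random() < profiles["soft_drinks_diet"].consumer_probability

        weights = np.array([profiles[g].fs_g_day for g in consumed])
        total_w = weights.sum()
        day_energy_sugar = np.zeros(n_days)
        day_rows: list[list[tuple]] = [[] for _ in range(n_days)]
        # (slot, food) pairs taken on each day; the snack/meal draw happens
        # FIRST and the food is then chosen among codes free in that slot, so
        # slot-collision merging cannot bias the snack probabilities
        used: list[set[tuple[str, str]]] = [set() for _ in range(n_days)]

        def pick_slot_and_food(d: int, snack_p: float, codes: tuple[str, ...]):
            slot = (
                _SNACK_SLOTS[rng.integers(3)]
                if rng.random() < snack_p
                else _MEAL_SLOTS[rng.integers(3)]
            )
            free = [c for c in codes if (slot, c) not in used[d]]
            code = (
                free[rng.integers(len(free))]
                if free
                else codes[rng.integers(len(codes))]
            )
            used[d].add((slot, code))
            return slot, code

        for g, w in zip(consumed, weights):
            counts = rng.poisson(profiles[g].entry_rate, size=n_days)
            if counts.sum() == 0:
                counts[rng.integers(n_days)] = 1
            group_fs_total = fs_target_day * n_days * w / total_w
            n_entries = int(counts.sum())
            snack_p = profiles[g].snack_probability
            for d in range(n_days):
                for _ in range(int(counts[d])):
                    slot, code = pick_slot_and_food(d, snack_p, _SUGAR_FOODS[g])
                    fs_g = (
                        group_fs_total
                        / n_entries
                        * (1.0 + jitter * (2.0 * rng.random() - 1.0))
                    )
                    amount = fs_g / (fs100[code] / 100.0)
                    day_rows[d].append((slot, code, amount))
                    day_energy_sugar[d] += amount * en100[code] / 100.0

        if diet_drinker:
            counts = rng.poisson(profiles["soft_drinks_diet"].entry_rate, size=n_days)
            if counts.sum() == 0:
                counts[rng.integers(n_days)] = 1
            snack_p = profiles["soft_drinks_diet"].snack_probability
            for d in range(n_days):
                for _ in range(int(counts[d])):
                    slot, code = pick_slot_and_food(
                        d, snack_p, ("SDD1", "SDD2", "SDD3")
                    )
                    amount = 150.0 * (1.0 + jitter * (2.0 * rng.random() - 1.0))
                    day_rows[d].append((slot, code, amount))
                    day_energy_sugar[d] += amount * en100[code] / 100.0

        # Staples + filler close the energy budget at the *subject* level:
        # %TEI aggregates as the ratio of 4-day totals, so only total energy
        # must hit n_days x TEI.  Heavy-sugar days simply get less filler,
        # which also keeps high-intake subjects from overshooting the budget.
        staple_base_energy = sum(g * en100[c] / 100.0 for c, g, _ in _STAPLES)
        budget = tei * n_days - day_energy_sugar.sum()
        scale = (
            1.0
            if budget >= n_days * staple_base_energy
            else max(budget / (n_days * staple_base_energy), _MIN_STAPLE_SCALE)
        )
        staple_energy_total = 0.0
        for d in range(n_days):
            for i, (code, grams, grp) in enumerate(_STAPLES):
                amount = grams * scale * (1.0 + jitter * (2.0 * rng.random() - 1.0))
                snack_p = profiles[grp].snack_probability
                slot = (
                    _SNACK_SLOTS[rng.integers(3)]
                    if rng.random() < snack_p
                    else _MEAL_SLOTS[i % 3]
                )
                day_rows[d].append((slot, code, amount))
                staple_energy_total += amount * en100[code] / 100.0
        filler_total = budget - staple_energy_total
        if filler_total > 0.02 * n_days:
            # spread filler towards the lighter days
            deficits = np.maximum(
                tei - day_energy_sugar - staple_energy_total / n_days, 0.0
            )
            shares = (
                deficits / deficits.sum()
                if deficits.sum() > 0
                else np.full(n_days, 1.0 / n_days)
            )
            filler_snack_p = profiles["other"].snack_probability
            for d in range(n_days):
                fe = filler_total * shares[d]
                if fe > 0.02:
                    slot = (
                        _SNACK_SLOTS[rng.integers(3)]
                        if rng.random() < filler_snack_p
                        else _MEAL_SLOTS[2]
                    )
                    day_rows[d].append((slot, _FILLER_CODE, fe / filler_en))

        for d in range(n_days):
            # merge duplicate (slot, food) pairs; renumber non-empty slots
            merged: dict[tuple[str, str], float] = {}
            for slot, code, amount in day_rows[d]:
                merged[(slot, code)] = merged.get((slot, code), 0.0) + amount
            slots_present = sorted({slot for slot, _ in merged})
            seq_of = {slot: i + 1 for i, slot in enumerate(slots_present)}
            for (slot, code), amount in sorted(merged.items()):
                rows.append(
                    (
                        subj.subject_id,
                        d + 1,
                        seq_of[slot],
                        "snack" if slot.startswith("s") else "main_meal",
                        code,
                        round(max(amount, 0.1), 2),
                    )
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "survey_day", "occasion_seq", "occasion_type",
            "food_code", "amount_g",
        ],
    )
    # drawn per-subject targets, kept for diagnostics/recovery checks
    frame.attrs["subject_targets"] = pd.DataFrame(
        drawn_targets, columns=["subject_id", "tei_MJ_day", "fs_pct_tei"]
    )
    return frame


def default_sfq_groups() -> list[SFQGroup]:
    """The shipped synthetic SFQ definitions (coarse questionnaire stand-in)."""
    with resources.as_file(
        resources.files("freesugar.data").joinpath("sfq_groups_synthetic.json")
    ) as p:
        return load_sfq_groups(p)


@dataclass
class SyntheticCohort:
    foods: list[FoodItem]
    subjects: list[Subject]
    diary: pd.DataFrame
    sfq_groups: list[SFQGroup]
    config: GeneratorConfig
    seed: int


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int = 0
) -> SyntheticCohort:
    """Generate the full bundle: food table, subjects, diaries, SFQ groups.

    Sub-seeds for the three stages are derived from ``seed`` so the stages
    stay independently reproducible.
    """
    config = config or GeneratorConfig()
    ss = np.random.SeedSequence(seed).spawn(3)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    foods = generate_food_db(config, sub_seeds[0])
    subjects = generate_subjects(config, sub_seeds[1])
    diary = generate_diary_frame(subjects, foods, config, sub_seeds[2])
    return SyntheticCohort(
        foods=foods,
        subjects=subjects,
        diary=diary,
        sfq_groups=default_sfq_groups(),
        config=config,
        seed=seed,
    )


def write_cohort_csvs(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write foods/subjects/diary CSVs plus the SFQ-group JSON to a directory."""
    from .food_composition import write_food_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "foods": outdir / "foods.csv",
        "subjects": outdir / "subjects.csv",
        "diary": outdir / "diary.csv",
        "sfq_groups": outdir / "sfq_groups.json",
    }
    write_food_table(cohort.foods, paths["foods"])
    pd.DataFrame([s.__dict__ for s in cohort.subjects]).to_csv(
        paths["subjects"], index=False
    )
    cohort.diary.to_csv(paths["diary"], index=False)
    import json as _json

    _json.dump(
        [
            {
                "group_id": g.group_id,
                "name": g.name,
                "keywords": list(g.keywords),
                "exemplars": list(g.exemplar_descriptions),
            }
            for g in cohort.sfq_groups
        ],
        paths["sfq_groups"].open("w", encoding="utf-8"),
        indent=2,
    )
    return paths
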