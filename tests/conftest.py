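import numpy as np
import pandas as pd
import pytest

from freesugar.diary import DiaryEntry, Subject, entries_to_frame, join_nutrients
from freesugar.food_composition import FoodGroup, FoodItem, LadderFlags
from freesugar.fs_ladder import FSAssignment, apply_ladder
from freesugar.synthetic import GeneratorConfig, generate_cohort


def make_food(code, desc="food", src="src", group="other", ts=10.0,
              lactose=None, energy=None, **flags):
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


@pytest.fixture(scope="session")
def toy_foods():
    """Small hand-built table spanning the main ladder rungs."""
    return [
        make_food("MILK", "whole milk plain", "Milk", "dairy_products",
                  ts=4.8, lactose=4.8, energy=0.27, is_unprocessed_whole_food=True),
        make_food("YOG", "yoghurt strawberry", "Yoghurt", "dairy_products",
                  ts=12.0, lactose=4.0, energy=0.41),
        make_food("JUICE", "orange juice", "Fruit juices",
                  "fruit_juice_and_smoothies", ts=10.4, energy=0.19,
                  is_fruit_juice=True),
        make_food("COLA", "cola drink", "Carbonated beverage",
                  "soft_drinks_non_diet", ts=10.6, energy=0.19,
                  is_pure_sugar_product=True),
        make_food("APPLE", "apple raw", "Fruit", "fruit_and_vegetables",
                  ts=11.8, energy=0.21, is_unprocessed_whole_food=True),
        make_food("BISC", "digestive biscuit", "Biscuits", "cakes_and_biscuits",
                  ts=16.0, energy=2.0, recipe_fraction_free=0.9),
    ]


@pytest.fixture(scope="session")
def toy_assignments(toy_foods):
    return apply_ladder(toy_foods)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-sized synthetic cohort (126 children), fixed seed."""
    return generate_cohort(GeneratorConfig(), seed=11)


@pytest.fixture(scope="session")
def small_cohort_consumptions(small_cohort):
    assignments = apply_ladder(small_cohort.foods)
    return join_nutrients(small_cohort.diary, small_cohort.foods, assignments)


@pytest.fixture
def toy_entries():
    return [
        DiaryEntry("S1", 1, 1, "main_meal", "MILK", 200.0),
        DiaryEntry("S1", 1, 1, "main_meal", "YOG", 125.0),
        DiaryEntry("S1", 1, 2, "snack", "JUICE", 150.0),
        DiaryEntry("S1", 2, 1, "main_meal", "APPLE", 100.0),
        DiaryEntry("S2", 1, 1, "snack", "COLA", 330.0),
        DiaryEntry("S2", 1, 2, "main_meal", "BISC", 30.0),
    ]


@pytest.fixture
def toy_subjects():
    return [
        Subject("S1", "male", 40, 15.0, 95.0),
        Subject("S2", "female", 38, 14.2, 93.5),
    ]
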