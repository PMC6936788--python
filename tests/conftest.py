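"""Shared fixtures: scoring-input factory and a small simulated study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pnnskit as pk
from pnnskit.intake import OrganicProfile, ScoringInput


#: A profile in which every scored component sits in a 0-point band of the
#: 2017 score (3 fruit/veg servings, organics "never", 0 nuts/legumes/whole
#: grain, 0.3 dairy servings, 400 g/wk red meat, 100 g/wk processed meat,
#: 1 fish serving/wk, 20% added fat with ratios 0.6/0.4, 8% sugary energy,
#: 0 ml sweet beverages, 10 g/day ethanol, 7 g/day salt).
ZERO_GS2_PROFILE = dict(
    participant_id=1,
    sex="female",
    age_years=40.0,
    fruit_veg_servings_per_day=3.0,
    nuts_handfuls_per_day=0.0,
    legume_servings_per_week=0.0,
    wholegrain_servings_per_day=0.0,
    dairy_servings_per_day=0.3,
    red_meat_g_per_week=400.0,
    processed_meat_g_per_week=100.0,
    white_ham_ratio=0.0,
    fish_servings_per_week=1.0,
    fatty_fish_servings_per_week=0.0,
    added_fat_pct_eiwa=20.0,
    vegetal_fat_ratio=0.6,
    ala_olive_ratio=0.4,
    sugary_pct_eiwa=8.0,
    sweet_beverage_ml_per_day=0.0,
    water_l_per_day=1.2,
    soda_ml_per_day=100.0,
    ethanol_g_per_day=10.0,
    alcohol_regular=True,
    salt_g_per_day=7.0,
    eiwa_kcal_per_day=2000.0,
)


@pytest.fixture
def make_input():
    """Factory: ScoringInput seeded from the all-zero profile, overridable."""

    def _make(organic: OrganicProfile | None = None, **overrides) -> ScoringInput:
        kw = dict(ZERO_GS2_PROFILE)
        kw.update(overrides)
        if organic is not None:
            kw["organic"] = organic
        return ScoringInput(**kw)

    return _make


@pytest.fixture(scope="session")
def small_study() -> pk.SyntheticStudy:
    """A 300-participant cohort shared by read-only tests."""
    return pk.generate_cohort(pk.SimulationConfig(n_participants=300, seed=42))


@pytest.fixture(scope="session")
def definitions():
    return pk.load_definitions()


def random_scoring_input(rng: np.random.Generator) -> ScoringInput:
    """A random but valid ScoringInput covering all band domains."""
    levels = ("most_of_the_time", "occasionally", "never")
    organic = OrganicProfile(
        fruits=rng.choice(levels), vegetables=rng.choice(levels),
        bread=rng.choice(levels), rice_pasta=rng.choice(levels),
        legumes=rng.choice(levels),
        rice_pasta_consumed=bool(rng.random() < 0.8),
        legumes_consumed=bool(rng.random() < 0.8),
    )
    return ScoringInput(
        participant_id=int(rng.integers(1e6)),
        sex=rng.choice(["female", "male"]),
        age_years=float(rng.uniform(18, 85)),
        fruit_veg_servings_per_day=float(rng.uniform(0, 12)),
        nuts_handfuls_per_day=float(rng.uniform(0, 3)),
        legume_servings_per_week=float(rng.uniform(0, 8)),
        wholegrain_servings_per_day=float(rng.uniform(0, 4)),
        dairy_servings_per_day=float(rng.uniform(0, 6)),
        red_meat_g_per_week=float(rng.uniform(0, 1500)),
        processed_meat_g_per_week=float(rng.uniform(0, 600)),
        white_ham_ratio=float(rng.uniform(0, 1)),
        fish_servings_per_week=float(rng.uniform(0, 6)),
        fatty_fish_servings_per_week=float(rng.uniform(0, 3)),
        added_fat_pct_eiwa=float(rng.uniform(0, 35)),
        vegetal_fat_ratio=float(rng.uniform(0, 1)),
        ala_olive_ratio=float(rng.uniform(0, 1)),
        sugary_pct_eiwa=float(rng.uniform(0, 30)),
        sweet_beverage_ml_per_day=float(rng.uniform(0, 1200)),
        water_l_per_day=float(rng.uniform(0, 3)),
        soda_ml_per_day=float(rng.uniform(0, 600)),
        ethanol_g_per_day=float(rng.uniform(0, 250)),
        alcohol_regular=bool(rng.random() < 0.6),
        salt_g_per_day=float(rng.uniform(0, 16)),
        eiwa_kcal_per_day=float(rng.uniform(1200, 3200)),
        starchy_servings_per_day=float(rng.uniform(0, 8)),
        wholegrain_ratio=float(rng.uniform(0, 1)),
        meat_fish_egg_servings_per_day=float(rng.uniform(0, 4)),
        organic=organic,
    )
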