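"""Usual-diet construction from repeated 24-hour dietary records.

A participant's usual diet is the weekday/weekend-weighted mean of their
24-hour records, converted into the units the guideline scores are written
in (servings/day, g/week, % of energy intake without alcohol).  The module
also implements energy-intake plausibility screening (Goldberg cut-off with
Schofield basal metabolic rates, i.e. the Black method).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ETHANOL_KCAL_PER_G = 7.0

#: Food-group columns of a records table, g/day or ml/day.
FOOD_COLUMNS = [
    "fruits", "vegetables", "fruit_juice", "dried_fruit", "nuts", "legumes",
    "whole_grains", "refined_grains", "dairy", "red_meat", "processed_meat",
    "white_ham", "fish", "fatty_fish", "added_fat_animal", "added_fat_vegetal",
    "added_fat_olive_ala", "sugary_foods", "sweet_beverages",
    "artificial_beverages", "water", "ethanol",
]
#: Energy / nutrient columns of a records table.
ENERGY_COLUMNS = ["energy_total", "salt", "energy_added_fat", "energy_sugary"]

ORGANIC_LEVELS = ("most_of_the_time", "occasionally", "never")


@dataclass
class OrganicProfile:
    """Reported frequency of organic consumption for five food groups."""

    fruits: str = "never"
    vegetables: str = "never"
    bread: str = "never"
    rice_pasta: str = "never"
    legumes: str = "never"
    rice_pasta_consumed: bool = True
    legumes_consumed: bool = True

    def __post_init__(self) -> None:
        for item in ("fruits", "vegetables", "bread", "rice_pasta", "legumes"):
            if getattr(self, item) not in ORGANIC_LEVELS:
                raise ValueError(
                    f"organic frequency for {item!r} must be one of "
                    f"{ORGANIC_LEVELS}, got {getattr(self, item)!r}"
                )


@dataclass
class ScoringInput:
    """Per-participant usual diet in the units the score criteria use.

    Rates are per day unless the field name says otherwise.  The two
    beverage dialects coexist: ``sweet_beverage_ml_per_day`` pools sweet,
    artificially sweetened, and juice beverages (2017-score definition),
    while ``water_l_per_day``/``soda_ml_per_day`` feed the 2001-score
    water-versus-soda rule.
    """

    participant_id: object
    sex: str
    age_years: float
    fruit_veg_servings_per_day: float
    nuts_handfuls_per_day: float
    legume_servings_per_week: float
    wholegrain_servings_per_day: float
    dairy_servings_per_day: float
    red_meat_g_per_week: float
    processed_meat_g_per_week: float
    white_ham_ratio: float
    fish_servings_per_week: float
    fatty_fish_servings_per_week: float
    added_fat_pct_eiwa: float
    vegetal_fat_ratio: float
    ala_olive_ratio: float
    sugary_pct_eiwa: float
    sweet_beverage_ml_per_day: float
    water_l_per_day: float
    soda_ml_per_day: float
    ethanol_g_per_day: float
    alcohol_regular: bool
    salt_g_per_day: float
    eiwa_kcal_per_day: float
    # 2001-dialect extras
    starchy_servings_per_day: float = 0.0
    wholegrain_ratio: float = 0.0
    meat_fish_egg_servings_per_day: float = 0.0
    # AHEI-2010 extras
    vegetable_servings_per_day: float = 0.0
    fruit_servings_per_day: float = 0.0
    wholegrain_g_per_day: float = 0.0
    nuts_legumes_servings_per_day: float = 0.0
    red_processed_meat_servings_per_day: float = 0.0
    ssb_juice_servings_per_day: float = 0.0
    epa_dha_mg_per_day: float = 0.0
    pufa_pct_eiwa: float = 0.0
    sodium_g_per_day: float = 0.0
    alcohol_drinks_per_day: float = 0.0
    organic: OrganicProfile = field(default_factory=OrganicProfile)

    _RATIO_FIELDS = ("white_ham_ratio", "vegetal_fat_ratio", "ala_olive_ratio",
                     "wholegrain_ratio")

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not self.eiwa_kcal_per_day > 0:
            raise ValueError("eiwa_kcal_per_day must be positive")
        for f in dc_fields(self):
            if f.name in ("participant_id", "sex", "organic", "alcohol_regular"):
                continue
            v = float(getattr(self, f.name))
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
        for name in self._RATIO_FIELDS:
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ServingSizes:
    """Gram/millilitre equivalents used to convert intakes to servings."""

    fruit_veg_g: float = 80.0
    dried_fruit_g: float = 30.0
    nuts_handful_g: float = 30.0
    legumes_g: float = 60.0
    whole_grain_g: float = 50.0
    refined_grain_g: float = 50.0
    dairy_g: float = 150.0
    fish_g: float = 100.0
    meat_g: float = 100.0
    beverage_glass_ml: float = 240.0
    ethanol_per_drink_g: float = 10.0
    epa_dha_mg_per_g_fatty_fish: float = 15.0
    sodium_fraction_of_salt: float = 0.393
    pufa_fraction_of_vegetal_fat_energy: float = 0.5


@dataclass
class BlackParams:
    """Goldberg cut-off parameters for the Black under-reporting screen.

    The lower confidence limit of the energy-intake:BMR ratio is
    ``pal * exp(-z * s / 100)`` with
    ``s = sqrt(cv_ei**2 / n_days + cv_bmr**2 + cv_pal**2)``.
    Defaults follow the conventional values (within-subject CV of energy
    intake 23%, CV of BMR estimation 8.5%, CV of energy requirement 15%,
    PAL 1.55, 2-SD limits).
    """

    pal: float = 1.55
    cv_ei: float = 23.0
    cv_bmr: float = 8.5
    cv_pal: float = 15.0
    z: float = 2.0


def aggregate_usual_diet(records: pd.DataFrame) -> pd.Series:
    """Average repeated 24-hour records into a usual daily diet.

    Weekday records receive weight 5/7 and weekend records 2/7, matching a
    sampling design of 2 weekdays + 1 weekend day per record triplet.  When
    one stratum is empty the unweighted mean is used and a warning logged.

    Parameters
    ----------
    records : DataFrame
        One participant's records with an ``is_weekend`` flag and the
        `FOOD_COLUMNS` / `ENERGY_COLUMNS` amount columns.

    Returns
    -------
    Series of usual amounts (g, ml or kcal per day).
    """
    if len(records) == 0:
        raise ValueError("cannot aggregate an empty set of dietary records")
    cols = [c for c in FOOD_COLUMNS + ENERGY_COLUMNS if c in records.columns]
    weekend = records["is_weekend"].astype(bool)
    wk, we = records.loc[~weekend, cols], records.loc[weekend, cols]
    if len(wk) == 0 or len(we) == 0:
        logger.warning(
            "participant has no %s record; falling back to unweighted mean",
            "weekday" if len(wk) == 0 else "weekend",
        )
        return records[cols].mean()
    return (5.0 * wk.mean() + 2.0 * we.mean()) / 7.0


def compute_eiwa(usual: Mapping) -> float:
    """Energy intake without alcohol: total energy minus 7 kcal/g ethanol.

    Floored at zero (with a warning) if recorded ethanol energy exceeds
    total energy.
    """
    try:
        energy = float(usual["energy_total"])
        ethanol = float(usual["ethanol"])
    except KeyError as exc:
        raise ValueError(f"missing field for EIWA computation: {exc}") from exc
    eiwa = energy - ETHANOL_KCAL_PER_G * ethanol
    if eiwa < 0:
        logger.warning("ethanol energy exceeds total energy; flooring EIWA at 0")
        return 0.0
    return eiwa


def _ratio(num: float, den: float) -> float:
    return float(num) / float(den) if den > 0 else 0.0


def build_scoring_input(
    usual: Mapping,
    organic: OrganicProfile,
    participant_id: object,
    sex: str,
    age_years: float,
    serving_sizes: ServingSizes | None = None,
    alcohol_regular: bool | None = None,
    drinking_day_fraction: float | None = None,
) -> ScoringInput:
    """Convert a usual diet (g/ml per day) into score-criterion units.

    Juice and dried-fruit servings are each capped at 1/day before entering
    the fruit-and-vegetable total; weekly criteria are daily amounts times 7;
    energy shares are percentages of energy intake without alcohol (EIWA).
    Organic frequencies for rice/pasta and legumes are nullified downstream
    via the profile's ``*_consumed`` flags.

    ``alcohol_regular`` (drinks at least once a week) may be given directly
    or derived from ``drinking_day_fraction`` (fraction of record days with
    any ethanol; regular when >= 1/7).
    """
    ss = serving_sizes or ServingSizes()
    for col in FOOD_COLUMNS:
        if float(usual[col]) < 0:
            raise ValueError(f"negative usual amount for {col!r}")
    eiwa = compute_eiwa(usual)
    if eiwa <= 0:
        raise ValueError("EIWA must be positive to build a scoring input")

    fruit_serv = float(usual["fruits"]) / ss.fruit_veg_g
    veg_serv = float(usual["vegetables"]) / ss.fruit_veg_g
    juice_serv = min(float(usual["fruit_juice"]) / ss.fruit_veg_g, 1.0)
    dried_serv = min(float(usual["dried_fruit"]) / ss.dried_fruit_g, 1.0)

    whole_serv = float(usual["whole_grains"]) / ss.whole_grain_g
    refined_serv = float(usual["refined_grains"]) / ss.refined_grain_g
    legume_serv = float(usual["legumes"]) / ss.legumes_g

    fat_animal = float(usual["added_fat_animal"])
    fat_veg = float(usual["added_fat_vegetal"])
    fat_ala = float(usual["added_fat_olive_ala"])
    fat_total = fat_animal + fat_veg + fat_ala
    vegetal_ratio = _ratio(fat_veg + fat_ala, fat_total)

    if alcohol_regular is None:
        if drinking_day_fraction is None:
            alcohol_regular = float(usual["ethanol"]) > 0
        else:
            alcohol_regular = drinking_day_fraction >= 1.0 / 7.0

    added_fat_pct = 100.0 * float(usual["energy_added_fat"]) / eiwa
    return ScoringInput(
        participant_id=participant_id,
        sex=sex,
        age_years=float(age_years),
        fruit_veg_servings_per_day=fruit_serv + veg_serv + juice_serv + dried_serv,
        nuts_handfuls_per_day=float(usual["nuts"]) / ss.nuts_handful_g,
        legume_servings_per_week=legume_serv * 7.0,
        wholegrain_servings_per_day=whole_serv,
        dairy_servings_per_day=float(usual["dairy"]) / ss.dairy_g,
        red_meat_g_per_week=float(usual["red_meat"]) * 7.0,
        processed_meat_g_per_week=float(usual["processed_meat"]) * 7.0,
        white_ham_ratio=min(_ratio(usual["white_ham"], usual["processed_meat"]), 1.0),
        fish_servings_per_week=float(usual["fish"]) / ss.fish_g * 7.0,
        fatty_fish_servings_per_week=float(usual["fatty_fish"]) / ss.fish_g * 7.0,
        added_fat_pct_eiwa=added_fat_pct,
        vegetal_fat_ratio=vegetal_ratio,
        ala_olive_ratio=_ratio(fat_ala, fat_veg + fat_ala),
        sugary_pct_eiwa=100.0 * float(usual["energy_sugary"]) / eiwa,
        sweet_beverage_ml_per_day=(
            float(usual["sweet_beverages"])
            + float(usual["artificial_beverages"])
            + float(usual["fruit_juice"])
        ),
        water_l_per_day=float(usual["water"]) / 1000.0,
        soda_ml_per_day=float(usual["sweet_beverages"]),
        ethanol_g_per_day=float(usual["ethanol"]),
        alcohol_regular=bool(alcohol_regular),
        salt_g_per_day=float(usual["salt"]),
        eiwa_kcal_per_day=eiwa,
        starchy_servings_per_day=whole_serv + refined_serv + legume_serv,
        wholegrain_ratio=_ratio(whole_serv, whole_serv + refined_serv),
        meat_fish_egg_servings_per_day=(
            (float(usual["red_meat"]) + float(usual["processed_meat"])) / ss.meat_g
            + float(usual["fish"]) / ss.fish_g
        ),
        vegetable_servings_per_day=veg_serv,
        fruit_servings_per_day=fruit_serv + dried_serv,
        wholegrain_g_per_day=float(usual["whole_grains"]),
        nuts_legumes_servings_per_day=(
            float(usual["nuts"]) / ss.nuts_handful_g + legume_serv
        ),
        red_processed_meat_servings_per_day=(
            (float(usual["red_meat"]) + float(usual["processed_meat"])) / ss.meat_g
        ),
        ssb_juice_servings_per_day=(
            (float(usual["sweet_beverages"]) + float(usual["fruit_juice"]))
            / ss.beverage_glass_ml
        ),
        epa_dha_mg_per_day=float(usual["fatty_fish"]) * ss.epa_dha_mg_per_g_fatty_fish,
        pufa_pct_eiwa=(
            added_fat_pct * vegetal_ratio * ss.pufa_fraction_of_vegetal_fat_energy
        ),
        sodium_g_per_day=float(usual["salt"]) * ss.sodium_fraction_of_salt,
        alcohol_drinks_per_day=float(usual["ethanol"]) / ss.ethanol_per_drink_g,
        organic=organic,
    )


def schofield_bmr(sex: str, age_years: float, weight_kg: float) -> float:
    """Basal metabolic rate (kcal/day) from the Schofield weight equations."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if sex == "male":
        if age_years < 30:
            return 15.057 * weight_kg + 692.2
        if age_years < 60:
            return 11.472 * weight_kg + 873.1
        return 11.711 * weight_kg + 587.7
    if age_years < 30:
        return 14.818 * weight_kg + 486.6
    if age_years < 60:
        return 8.126 * weight_kg + 845.6
    return 9.082 * weight_kg + 658.5


def goldberg_cutoff(n_days: int, params: BlackParams | None = None) -> float:
    """Lower Goldberg confidence limit for the EI:BMR ratio over ``n_days``."""
    p = params or BlackParams()
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    s = math.sqrt(p.cv_ei**2 / n_days + p.cv_bmr**2 + p.cv_pal**2)
    return p.pal * math.exp(-p.z * s / 100.0)


def flag_underreporting(
    energy_total: float,
    sex: str,
    age_years: float,
    weight_kg: float,
    height_cm: float,
    n_days: int,
    params: BlackParams | None = None,
) -> tuple[bool, dict]:
    """Flag implausibly low reported energy intake (Black method).

    Returns ``(flagged, diagnostics)`` where the flag is True when the
    EI:BMR ratio falls strictly below the Goldberg lower cut-off.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    bmr = schofield_bmr(sex, age_years, weight_kg)
    ratio = float(energy_total) / bmr
    cutoff = goldberg_cutoff(n_days, params)
    return ratio < cutoff, {"ei_bmr_ratio": ratio, "cutoff": cutoff, "bmr": bmr}


def organic_profile_from_row(row: Mapping) -> OrganicProfile:
    """Build an `OrganicProfile` from one row of an organic table."""
    return OrganicProfile(
        fruits=row["fruits"],
        vegetables=row["vegetables"],
        bread=row["bread"],
        rice_pasta=row["rice_pasta"],
        legumes=row["legumes"],
        rice_pasta_consumed=bool(row["rice_pasta_consumed"]),
        legumes_consumed=bool(row["legumes_consumed"]),
    )


def build_scoring_inputs(
    records: pd.DataFrame,
    organic: pd.DataFrame,
    participants: pd.DataFrame,
    serving_sizes: ServingSizes | None = None,
) -> list[ScoringInput]:
    """Per-participant scoring inputs for whole tables (synthetic layout).

    ``records`` carries one row per record day, ``organic`` and
    ``participants`` one row per participant (indexed by
    ``participant_id`` column).  Organic rice/pasta and legume flags are
    nullified when the participant never reported the food in any record.
    """
    org = organic.set_index("participant_id")
    parts = participants.set_index("participant_id")
    out: list[ScoringInput] = []
    for pid, grp in records.groupby("participant_id", sort=True):
        usual = aggregate_usual_diet(grp)
        row = org.loc[pid].to_dict()
        row["rice_pasta_consumed"] = bool(
            (grp["whole_grains"] + grp["refined_grains"]).gt(0).any()
        )
        row["legumes_consumed"] = bool(grp["legumes"].gt(0).any())
        profile = organic_profile_from_row(row)
        p = parts.loc[pid]
        out.append(
            build_scoring_input(
                usual,
                profile,
                participant_id=pid,
                sex=p["sex"],
                age_years=float(p["age_at_inclusion"]),
                serving_sizes=serving_sizes,
                drinking_day_fraction=float(grp["ethanol"].gt(0).mean()),
            )
        )
    return out


def scoring_inputs_to_frame(inputs: Iterable[ScoringInput]) -> pd.DataFrame:
    """Tabulate scoring inputs (one row per participant) for scoring_input.csv."""
    rows = []
    for inp in inputs:
        d = {f.name: getattr(inp, f.name) for f in dc_fields(inp)
             if f.name != "organic"}
        for item in ("fruits", "vegetables", "bread", "rice_pasta", "legumes"):
            d[f"organic_{item}"] = getattr(inp.organic, item)
        d["organic_rice_pasta_consumed"] = inp.organic.rice_pasta_consumed
        d["organic_legumes_consumed"] = inp.organic.legumes_consumed
        rows.append(d)
    return pd.DataFrame(rows)
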