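"""Scoring engine: printed band cells, aggregation rules, and invariants."""

from __future__ import annotations

import numpy as np
import pytest

from pnnskit import scoring
from pnnskit.intake import OrganicProfile

from conftest import random_scoring_input

# --------------------------------------------------------------------------
# Golden cells: every scoring band of both guideline indices, keyed by the
# component input that lands in it.  Expected values are the printed points.
# --------------------------------------------------------------------------

GS2_CELLS = [
    ("fruits_vegetables", {"fruit_veg_servings_per_day": v}, p)
    for v, p in [(0, 0), (3.4, 0), (3.5, 0.5), (4.9, 0.5), (5, 1), (6, 1),
                 (7.4, 1), (7.5, 2), (11, 2)]
] + [
    ("nuts", {"nuts_handfuls_per_day": v}, p)
    for v, p in [(0, 0), (0.3, 0.5), (0.5, 1), (1.4, 1), (1.5, 0), (1.6, 0)]
] + [
    ("legumes", {"legume_servings_per_week": v}, p)
    for v, p in [(0, 0), (1, 0.5), (2, 1), (6, 1)]
] + [
    ("whole_grain", {"wholegrain_servings_per_day": v}, p)
    for v, p in [(0, 0), (0.5, 0.5), (1, 1), (1.9, 1), (2, 1.5), (4, 1.5)]
] + [
    ("dairy", {"dairy_servings_per_day": v}, p)
    for v, p in [(0, 0), (0.4, 0), (0.5, 0.5), (1.4, 0.5), (1.5, 1),
                 (2.4, 1), (2.5, 0)]
] + [
    ("red_meat", {"red_meat_g_per_week": v}, p)
    for v, p in [(0, 0), (499, 0), (500, -1), (749, -1), (750, -2), (900, -2)]
] + [
    ("processed_meat", {"processed_meat_g_per_week": v}, p)
    for v, p in [(0, 0), (149, 0), (150, -1), (299, -1), (300, -2)]
] + [
    ("fish_seafood", {"fish_servings_per_week": v}, p)
    for v, p in [(0, 0), (1.4, 0), (1.5, 1), (2, 1), (2.4, 1), (2.5, 0.5),
                 (3.4, 0.5), (3.5, 0)]
] + [
    ("added_fat", {"added_fat_pct_eiwa": v}, p)
    for v, p in [(10, 1.5), (16, 1.5), (16.1, 0), (25, 0)]
] + [
    ("sugary_foods", {"sugary_pct_eiwa": v}, p)
    for v, p in [(0, 0), (9.9, 0), (10, -1), (14.9, -1), (15, -2), (25, -2)]
] + [
    ("sweet_beverages", {"sweet_beverage_ml_per_day": v}, p)
    for v, p in [(0, 0), (100, -0.5), (249, -0.5), (250, -1), (749, -1),
                 (750, -2)]
] + [
    ("alcohol", {"ethanol_g_per_day": v}, p)
    for v, p in [(0, 0.5), (5, 0), (100, 0), (100.1, -1), (200, -1),
                 (200.1, -2)]
] + [
    ("salt", {"salt_g_per_day": v}, p)
    for v, p in [(0, 1), (6, 1), (6.1, 0), (8, 0), (8.1, -0.5), (10, -0.5),
                 (10.1, -1), (12, -1), (12.1, -2)]
]

GS1_CELLS = [
    ("fruits_vegetables", {"fruit_veg_servings_per_day": v}, p)
    for v, p in [(0, 0), (3.5, 0.5), (5, 1), (7.5, 2)]
] + [
    ("starchy_foods", {"starchy_servings_per_day": v}, p)
    for v, p in [(0.9, 0), (1, 0.5), (2.9, 0.5), (3, 1), (5.9, 1), (6, 0.5)]
] + [
    ("whole_grain", {"wholegrain_ratio": v}, p)
    for v, p in [(0.2, 0), (0.34, 0.5), (0.5, 0.5), (0.67, 1), (1.0, 1)]
] + [
    ("dairy", {"dairy_servings_per_day": v, "age_years": 40}, p)
    for v, p in [(0.9, 0), (1, 0.5), (2.4, 0.5), (2.5, 1), (3, 1), (3.5, 1),
                 (3.6, 0)]
] + [
    ("dairy", {"dairy_servings_per_day": v, "age_years": 60}, p)
    for v, p in [(3.6, 1), (4.5, 1), (4.6, 0)]
] + [
    ("meat_fish_eggs", {"meat_fish_egg_servings_per_day": v}, p)
    for v, p in [(0, 0), (0.5, 0.5), (1, 1), (2, 1), (2.1, 0)]
] + [
    ("fish_seafood", {"fish_servings_per_week": v}, p)
    for v, p in [(0, 0), (1.9, 0), (2, 1), (5, 1)]
] + [
    ("added_fat_limit", {"added_fat_pct_eiwa": v}, p)
    for v, p in [(16, 1), (16.1, 0)]
] + [
    ("vegetal_fat_preference", {"vegetal_fat_ratio": v}, p)
    for v, p in [(0.5, 1), (0.51, 0)]
] + [
    ("sugary_foods", {"sugary_pct_eiwa": v}, p)
    for v, p in [(9, 1), (10, 0), (14.9, 0), (15, -0.5)]
] + [
    ("sweet_beverages", {"water_l_per_day": w, "soda_ml_per_day": s}, p)
    for w, s, p in [(1.2, 100, 1), (1.0, 250, 1), (0.8, 100, 0.75),
                    (1.2, 300, 0.5), (0.8, 300, 0)]
] + [
    ("salt", {"salt_g_per_day": v}, p)
    for v, p in [(5, 1.5), (6, 1.5), (7, 1), (8, 1), (9, 0.5), (10, 0.5),
                 (11, 0), (12, 0), (13, -0.5)]
]

GS1_ALCOHOL_CELLS = [
    ({"sex": "female", "ethanol_g_per_day": 15, "alcohol_regular": True}, 0.8),
    ({"sex": "female", "ethanol_g_per_day": 20, "alcohol_regular": True}, 0.8),
    ({"sex": "female", "ethanol_g_per_day": 21, "alcohol_regular": True}, 0),
    ({"sex": "male", "ethanol_g_per_day": 30, "alcohol_regular": True}, 0.8),
    ({"sex": "male", "ethanol_g_per_day": 31, "alcohol_regular": True}, 0),
    ({"ethanol_g_per_day": 0, "alcohol_regular": False}, 1),       # abstainer
    ({"ethanol_g_per_day": 5, "alcohol_regular": False}, 1),       # irregular
]


@pytest.mark.parametrize("component,overrides,expected", GS2_CELLS)
def test_gs2_band_cells(make_input, component, overrides, expected):
    res = scoring.score_pnns_gs2(make_input(**overrides))
    assert res["components"][component].raw_points == expected


@pytest.mark.parametrize("component,overrides,expected", GS1_CELLS)
def test_gs1_band_cells(make_input, component, overrides, expected):
    res = scoring.score_mpnns_gs1(make_input(**overrides))
    assert res["components"][component].raw_points == expected


@pytest.mark.parametrize("overrides,expected", GS1_ALCOHOL_CELLS)
def test_gs1_alcohol_cells(make_input, overrides, expected):
    res = scoring.score_mpnns_gs1(make_input(**overrides))
    assert res["components"]["alcohol"].raw_points == expected


# --------------------------------------------------------------------------
# Sub-items, bonuses and gates
# --------------------------------------------------------------------------

def test_organic_bonus_levels():
    assert scoring.organic_bonus("most_of_the_time") == 0.5
    assert scoring.organic_bonus("occasionally") == 0.25
    assert scoring.organic_bonus("never") == 0.0
    assert scoring.organic_bonus("most_of_the_time", consumed=False) == 0.0
    with pytest.raises(ValueError):
        scoring.organic_bonus("sometimes")


def test_organic_nullification_for_unconsumed_items(make_input):
    organic = OrganicProfile(legumes="most_of_the_time", legumes_consumed=False,
                             rice_pasta="occasionally", rice_pasta_consumed=False)
    res = scoring.score_pnns_gs2(make_input(organic=organic))
    assert res["components"]["legumes"].sub_item_points == 0.0
    assert res["components"]["whole_grain"].sub_item_points == 0.0
    organic2 = OrganicProfile(legumes="most_of_the_time", legumes_consumed=True)
    res2 = scoring.score_pnns_gs2(make_input(organic=organic2))
    assert res2["components"]["legumes"].sub_item_points == 0.5


@pytest.mark.parametrize("processed,ratio,expected", [
    (100.0, 0.9, 0.0),    # gate closed at <= 150 g/week
    (151.0, 0.9, 0.5),
    (200.0, 0.4, 0.0),    # gate open but ratio below 50%
    (200.0, 0.5, 0.5),
])
def test_white_ham_bonus_gate(make_input, processed, ratio, expected):
    res = scoring.score_pnns_gs2(make_input(
        processed_meat_g_per_week=processed, white_ham_ratio=ratio))
    assert res["components"]["processed_meat"].sub_item_points == expected


def test_fatty_fish_sub_item(make_input):
    for v, p in [(0, 0), (0.5, 1), (1.4, 1), (1.5, 0)]:
        res = scoring.score_pnns_gs2(make_input(fatty_fish_servings_per_week=v))
        assert res["components"]["fish_seafood"].sub_item_points == p


# --------------------------------------------------------------------------
# Totals and aggregation
# --------------------------------------------------------------------------

def test_all_zero_profile_scores_zero(make_input):
    assert scoring.score_pnns_gs2(make_input())["total"] == 0.0
    assert scoring.score_spnns_gs2(make_input())["total"] == 0.0


def test_abstainer_gains_weighted_half_point(make_input):
    res = scoring.score_pnns_gs2(make_input(ethanol_g_per_day=0.0))
    assert res["total"] == pytest.approx(3 * 0.5)


def test_simplified_score_drops_bonuses(make_input):
    organic = OrganicProfile(fruits="most_of_the_time",
                             vegetables="most_of_the_time",
                             bread="most_of_the_time",
                             rice_pasta="most_of_the_time",
                             legumes="most_of_the_time")
    inp = make_input(organic=organic)
    assert scoring.score_spnns_gs2(inp)["total"] == 0.0
    assert scoring.score_pnns_gs2(inp)["total"] > 0.0


def test_decomposition_identity_random_inputs():
    rng = np.random.default_rng(7)
    for _ in range(50):
        inp = random_scoring_input(rng)
        full = scoring.score_pnns_gs2(inp)
        simple = scoring.score_spnns_gs2(inp)
        secondary = sum(
            cs.weight * cs.sub_item_points
            for cs in full["components"].values()
        )
        assert full["total"] - simple["total"] == pytest.approx(secondary)


def test_component_counts(definitions):
    assert len(definitions.gs2) == 13
    assert len(definitions.gs1) == 12
    assert len(definitions.ahei) == 10
    kinds2 = [c.kind for c in definitions.gs2]
    assert kinds2.count("adequacy") == 6 and kinds2.count("moderation") == 7


def test_shared_cells_agree_between_indices(definitions):
    """Cells printed identically in both indices use identical band tables."""
    gs1 = {c.name: c for c in definitions.gs1}
    gs2 = {c.name: c for c in definitions.gs2}
    assert gs1["fruits_vegetables"].bands == gs2["fruits_vegetables"].bands


# --------------------------------------------------------------------------
# AHEI-2010
# --------------------------------------------------------------------------

def test_ahei_extremes_and_midpoint(make_input):
    best = make_input(
        vegetable_servings_per_day=5, fruit_servings_per_day=4,
        wholegrain_g_per_day=80, ssb_juice_servings_per_day=0,
        nuts_legumes_servings_per_day=1, red_processed_meat_servings_per_day=0,
        epa_dha_mg_per_day=250, pufa_pct_eiwa=10, sodium_g_per_day=1.1,
        alcohol_drinks_per_day=1.0,
    )
    assert scoring.score_ahei2010(best)["total"] == pytest.approx(100.0)
    worst = make_input(
        vegetable_servings_per_day=0, fruit_servings_per_day=0,
        wholegrain_g_per_day=0, ssb_juice_servings_per_day=2,
        nuts_legumes_servings_per_day=0, red_processed_meat_servings_per_day=2,
        epa_dha_mg_per_day=0, pufa_pct_eiwa=1, sodium_g_per_day=4,
        alcohol_drinks_per_day=4.0,
    )
    assert scoring.score_ahei2010(worst)["total"] == pytest.approx(0.0)
    mid = make_input(vegetable_servings_per_day=2.5)
    assert scoring.score_ahei2010(mid)["components"]["vegetables"].raw_points \
        == pytest.approx(5.0)


# --------------------------------------------------------------------------
# Standardization
# --------------------------------------------------------------------------

def test_standardize_panel_unit_sd_fixed_point():
    import pandas as pd
    panel = pd.DataFrame({"pnns_gs2": [1.0, 2.0, 3.0]})
    out = scoring.standardize_panel(panel, index_columns=["pnns_gs2"])
    np.testing.assert_allclose(out["pnns_gs2_std"], [1.0, 2.0, 3.0])
    scaled = scoring.standardize_panel(panel * 10, index_columns=["pnns_gs2"])
    np.testing.assert_allclose(scaled["pnns_gs2_std"], out["pnns_gs2_std"])
    with pytest.raises(ValueError):
        scoring.standardize_panel(pd.DataFrame({"pnns_gs2": [2.0, 2.0, 2.0]}),
                                  index_columns=["pnns_gs2"])


# --------------------------------------------------------------------------
# Properties
# --------------------------------------------------------------------------

def _all_band_sets(definitions):
    out = []
    for comp in definitions.gs2 + definitions.gs1:
        out.extend(comp.band_sets())
    return out


def test_band_coverage_random_values(definitions):
    rng = np.random.default_rng(11)
    for label, bands, domain in _all_band_sets(definitions):
        lo, hi = domain
        span = 2000.0 if not np.isfinite(hi) else hi
        values = np.concatenate([
            rng.uniform(lo, span, 500),
            np.array([b.lower for b in bands if np.isfinite(b.lower)]),
            np.array([b.upper for b in bands if np.isfinite(b.upper)]),
        ])
        for v in values:
            hits = [b for b in bands if b.contains(float(v))]
            assert len(hits) == 1, f"{label}: value {v} hit {len(hits)} bands"


def test_component_points_within_printed_extrema(definitions):
    rng = np.random.default_rng(23)
    for _ in range(100):
        inp = random_scoring_input(rng)
        for comp in definitions.gs2:
            pts = comp.base_points(inp)
            printed = [b.points for bs in comp.band_sets()[:1] for b in bs[1]] \
                or [0.0]
            assert min(printed) <= pts <= max(printed)


def test_adequacy_and_moderation_monotonicity(make_input):
    grids = {
        "fruit_veg_servings_per_day": (1, "fruits_vegetables"),
        "legume_servings_per_week": (1, "legumes"),
        "wholegrain_servings_per_day": (1, "whole_grain"),
        "red_meat_g_per_week": (-1, "red_meat"),
        "processed_meat_g_per_week": (-1, "processed_meat"),
        "sugary_pct_eiwa": (-1, "sugary_foods"),
        "sweet_beverage_ml_per_day": (-1, "sweet_beverages"),
        "salt_g_per_day": (-1, "salt"),
        "ethanol_g_per_day": (-1, "alcohol"),
    }
    rng = np.random.default_rng(3)
    for fld, (sign, comp) in grids.items():
        values = np.sort(rng.uniform(0, 900, 80))
        pts = [scoring.score_pnns_gs2(make_input(**{fld: float(v)}))
               ["components"][comp].raw_points for v in values]
        diffs = sign * np.diff(pts)
        assert (diffs >= 0).all(), f"{comp} not monotone"


# --------------------------------------------------------------------------
# Independent brute-force oracle over the printed table
# --------------------------------------------------------------------------

def _pick(value, rows):
    """Linear scan of (upper_bound, upper_inclusive, points) rows."""
    for hi, inclusive, pts in rows:
        if value < hi or (inclusive and value == hi):
            return pts
    raise AssertionError("value escaped the table")


def gs2_total_oracle(inp) -> float:
    org = inp.organic
    bonus = {"most_of_the_time": 0.5, "occasionally": 0.25, "never": 0.0}
    fv = _pick(inp.fruit_veg_servings_per_day,
               [(3.5, False, 0), (5, False, 0.5), (7.5, False, 1),
                (np.inf, False, 2)])
    fv += bonus[org.fruits] + bonus[org.vegetables]
    nuts = (0 if inp.nuts_handfuls_per_day == 0 else
            _pick(inp.nuts_handfuls_per_day,
                  [(0.5, False, 0.5), (1.5, False, 1), (np.inf, False, 0)]))
    leg = (0 if inp.legume_servings_per_week == 0 else
           _pick(inp.legume_servings_per_week,
                 [(2, False, 0.5), (np.inf, False, 1)]))
    leg += bonus[org.legumes] if org.legumes_consumed else 0.0
    wg = (0 if inp.wholegrain_servings_per_day == 0 else
          _pick(inp.wholegrain_servings_per_day,
                [(1, False, 0.5), (2, False, 1), (np.inf, False, 1.5)]))
    wg += bonus[org.bread]
    wg += bonus[org.rice_pasta] if org.rice_pasta_consumed else 0.0
    dairy = _pick(inp.dairy_servings_per_day,
                  [(0.5, False, 0), (1.5, False, 0.5), (2.5, False, 1),
                   (np.inf, False, 0)])
    red = _pick(inp.red_meat_g_per_week,
                [(500, False, 0), (750, False, -1), (np.inf, False, -2)])
    proc = _pick(inp.processed_meat_g_per_week,
                 [(150, False, 0), (300, False, -1), (np.inf, False, -2)])
    if inp.processed_meat_g_per_week > 150 and inp.white_ham_ratio >= 0.5:
        proc += 0.5
    fish = _pick(inp.fish_servings_per_week,
                 [(1.5, False, 0), (2.5, False, 1), (3.5, False, 0.5),
                  (np.inf, False, 0)])
    fish += _pick(inp.fatty_fish_servings_per_week,
                  [(0.5, False, 0), (1.5, False, 1), (np.inf, False, 0)])
    fat = 1.5 if inp.added_fat_pct_eiwa <= 16 else 0.0
    fat += 1 if inp.vegetal_fat_ratio <= 0.5 else 0
    fat += 1 if inp.ala_olive_ratio >= 0.5 else 0
    sugar = _pick(inp.sugary_pct_eiwa,
                  [(10, False, 0), (15, False, -1), (np.inf, False, -2)])
    bev = (0 if inp.sweet_beverage_ml_per_day == 0 else
           _pick(inp.sweet_beverage_ml_per_day,
                 [(250, False, -0.5), (750, False, -1), (np.inf, False, -2)]))
    alc = (0.5 if inp.ethanol_g_per_day == 0 else
           _pick(inp.ethanol_g_per_day,
                 [(100, True, 0), (200, True, -1), (np.inf, False, -2)]))
    salt = _pick(inp.salt_g_per_day,
                 [(6, True, 1), (8, True, 0), (10, True, -0.5),
                  (12, True, -1), (np.inf, False, -2)])
    return (3 * fv + 1 * nuts + 1 * leg + 2 * wg + 1 * dairy + 2 * red
            + 3 * proc + 2 * fish + 2 * fat + 3 * sugar + 3 * bev
            + 3 * alc + 3 * salt)


def gs1_total_oracle(inp) -> float:
    fv = _pick(inp.fruit_veg_servings_per_day,
               [(3.5, False, 0), (5, False, 0.5), (7.5, False, 1),
                (np.inf, False, 2)])
    starchy = _pick(inp.starchy_servings_per_day,
                    [(1, False, 0), (3, False, 0.5), (6, False, 1),
                     (np.inf, False, 0.5)])
    wg = _pick(inp.wholegrain_ratio,
               [(1 / 3, False, 0), (2 / 3, False, 0.5), (np.inf, False, 1)])
    hi = 4.5 if inp.age_years >= 55 else 3.5
    dairy = _pick(inp.dairy_servings_per_day,
                  [(1, False, 0), (2.5, False, 0.5), (hi, True, 1),
                   (np.inf, False, 0)])
    mfe = (0 if inp.meat_fish_egg_servings_per_day == 0 else
           _pick(inp.meat_fish_egg_servings_per_day,
                 [(1, False, 0.5), (2, True, 1), (np.inf, False, 0)]))
    fish = 1 if inp.fish_servings_per_week >= 2 else 0
    fat = 1 if inp.added_fat_pct_eiwa <= 16 else 0
    veg_pref = 1 if inp.vegetal_fat_ratio <= 0.5 else 0
    sugar = _pick(inp.sugary_pct_eiwa,
                  [(10, False, 1), (15, False, 0), (np.inf, False, -0.5)])
    water_ok = inp.water_l_per_day >= 1
    soda_ok = inp.soda_ml_per_day <= 250
    bev = {(True, True): 1, (True, False): 0.5, (False, True): 0.75,
           (False, False): 0}[(water_ok, soda_ok)]
    if not inp.alcohol_regular:
        alc = 1
    else:
        limit = 20 if inp.sex == "female" else 30
        alc = 0.8 if inp.ethanol_g_per_day <= limit else 0
    salt = _pick(inp.salt_g_per_day,
                 [(6, True, 1.5), (8, True, 1), (10, True, 0.5),
                  (12, True, 0), (np.inf, False, -0.5)])
    return (fv + starchy + wg + dairy + mfe + fish + fat + veg_pref + sugar
            + bev + alc + salt)


def test_totals_match_brute_force_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        inp = random_scoring_input(rng)
        assert scoring.score_pnns_gs2(inp)["total"] == pytest.approx(
            gs2_total_oracle(inp)), vars(inp)
        assert scoring.score_mpnns_gs1(inp)["total"] == pytest.approx(
            gs1_total_oracle(inp)), vars(inp)
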