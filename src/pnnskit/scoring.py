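"""Guideline-adherence scoring engines.

Four diet-quality indices are computed from a `ScoringInput`:

* ``pnns_gs2`` — adherence to the 2017 French food-based dietary guidelines:
  13 components (6 adequacy, 7 moderation), each a banded score plus optional
  sub-items (organic bonuses, ratio preferences), aggregated as a weighted
  sum ``sum_c w_c * (band points + sub-item points)``.
* ``spnns_gs2`` — the simplified variant: the same weighted engine restricted
  to the principal recommendation of each component (no sub-items).
* ``mpnns_gs1`` — adherence to the 2001 guidelines minus physical activity:
  12 components, unweighted sum, with sex-specific alcohol bands,
  age-conditional dairy bands and a water-versus-soda beverage rule.
* ``ahei2010`` — the Alternate Healthy Eating Index 2010 without the
  trans-fat component: 10 components linearly interpolated between 0- and
  10-point cutoffs, total on 0-100.

All thresholds are data, shipped in ``data/score_definitions.yaml`` and
validated (band tiling, weights) at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intake import ORGANIC_LEVELS, ScoringInput

ORGANIC_POINTS = {"most_of_the_time": 0.5, "occasionally": 0.25, "never": 0.0}

#: Organic items whose bonus is nullified when the food was never consumed.
NULLIFIABLE_ORGANIC_ITEMS = ("rice_pasta", "legumes")


# ---------------------------------------------------------------------------
# Band machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """Half-open/closed scoring interval with its points value."""

    lower: float
    upper: float
    lower_inclusive: bool
    upper_inclusive: bool
    points: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("band lower bound exceeds upper bound")
        if self.lower == self.upper and not (
            self.lower_inclusive and self.upper_inclusive
        ):
            raise ValueError("a point band must be inclusive on both sides")

    def contains(self, value: float) -> bool:
        above = value > self.lower or (self.lower_inclusive and value == self.lower)
        below = value < self.upper or (self.upper_inclusive and value == self.upper)
        return above and below


def _parse_bands(raw: Sequence[Mapping]) -> tuple[Band, ...]:
    return tuple(
        Band(float(b["lo"]), float(b["hi"]), bool(b["lo_inc"]), bool(b["hi_inc"]),
             float(b["pts"]))
        for b in raw
    )


def _validate_tiling(bands: Sequence[Band], domain: tuple[float, float]) -> None:
    """Bands must partition the domain with no gap or overlap."""
    lo, hi = domain
    if not bands:
        raise ValueError("component has no bands")
    srt = sorted(bands, key=lambda b: (b.lower, b.upper))
    if srt[0].lower != lo or not srt[0].lower_inclusive:
        raise ValueError("bands do not start at the domain lower bound")
    for a, b in zip(srt, srt[1:]):
        if a.upper != b.lower:
            raise ValueError(f"gap or overlap between bands at {a.upper}")
        if a.upper_inclusive == b.lower_inclusive:
            raise ValueError(f"endpoint {a.upper} covered twice or never")
    last = srt[-1]
    if math.isfinite(hi):
        if last.upper != hi or not last.upper_inclusive:
            raise ValueError("bands do not close the domain upper bound")
    elif math.isfinite(last.upper):
        raise ValueError("bands do not extend to +inf")


def band_score(value: float, bands: Sequence[Band]) -> float:
    """Points of the unique band containing ``value``."""
    if not math.isfinite(value):
        raise ValueError(f"cannot band-score non-finite value {value}")
    for b in bands:
        if b.contains(value):
            return b.points
    raise RuntimeError(f"value {value} matched no band (non-covering band set)")


def organic_bonus(frequency: str, consumed: bool = True) -> float:
    """Organic-consumption bonus: 0.5 / 0.25 / 0, nullified if not consumed."""
    if frequency not in ORGANIC_LEVELS:
        raise ValueError(f"unknown organic frequency {frequency!r}")
    if not consumed:
        return 0.0
    return ORGANIC_POINTS[frequency]


# ---------------------------------------------------------------------------
# Component definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubItem:
    name: str
    rule: str                      # "organic" | "bands"
    item: str | None = None        # organic item name
    field_name: str | None = None
    bands: tuple[Band, ...] = ()
    domain: tuple[float, float] = (0.0, math.inf)
    gate_field: str | None = None
    gate_above: float | None = None

    def evaluate(self, inp: ScoringInput) -> float:
        if self.rule == "organic":
            consumed = True
            if self.item in NULLIFIABLE_ORGANIC_ITEMS:
                consumed = getattr(inp.organic, f"{self.item}_consumed")
            return organic_bonus(getattr(inp.organic, self.item), consumed)
        if self.gate_field is not None:
            if not getattr(inp, self.gate_field) > self.gate_above:
                return 0.0
        return band_score(getattr(inp, self.field_name), self.bands)


@dataclass(frozen=True)
class ComponentDefinition:
    """One score component: banded rule, weight, and optional sub-items."""

    name: str
    rule: str
    kind: str
    weight: float = 1.0
    principal: bool = False
    field_name: str | None = None
    bands: tuple[Band, ...] = ()
    domain: tuple[float, float] = (0.0, math.inf)
    sub_items: tuple[SubItem, ...] = ()
    extra: dict = field(default_factory=dict)

    def base_points(self, inp: ScoringInput) -> float:
        """Points of the principal (banded) part of the component."""
        if self.rule == "bands":
            return band_score(getattr(inp, self.field_name), self.bands)
        if self.rule == "bands_by_age":
            key = ("bands_old" if inp.age_years >= self.extra["age_threshold"]
                   else "bands_young")
            return band_score(getattr(inp, self.field_name), self.extra[key])
        if self.rule == "alcohol_gs1":
            if not inp.alcohol_regular:
                return float(self.extra["abstainer_pts"])
            key = "bands_female" if inp.sex == "female" else "bands_male"
            return band_score(getattr(inp, self.field_name), self.extra[key])
        if self.rule == "water_soda":
            high_water = inp.water_l_per_day >= self.extra["water_threshold"]
            low_soda = inp.soda_ml_per_day <= self.extra["soda_threshold"]
            key = (("high" if high_water else "low") + "_water_"
                   + ("low" if low_soda else "high") + "_soda")
            return float(self.extra["points"][key])
        raise ValueError(f"unknown component rule {self.rule!r}")

    def sub_points(self, inp: ScoringInput) -> float:
        return sum(s.evaluate(inp) for s in self.sub_items)

    def band_sets(self) -> list[tuple[str, tuple[Band, ...], tuple[float, float]]]:
        """All (label, bands, domain) triples for coverage checks."""
        out = []
        if self.rule == "bands":
            out.append((self.name, self.bands, self.domain))
        elif self.rule == "bands_by_age":
            out.append((f"{self.name}[young]", self.extra["bands_young"], self.domain))
            out.append((f"{self.name}[old]", self.extra["bands_old"], self.domain))
        elif self.rule == "alcohol_gs1":
            out.append((f"{self.name}[female]", self.extra["bands_female"], self.domain))
            out.append((f"{self.name}[male]", self.extra["bands_male"], self.domain))
        for s in self.sub_items:
            if s.rule == "bands":
                out.append((f"{self.name}.{s.name}", s.bands, s.domain))
        return out


@dataclass(frozen=True)
class AheiComponent:
    """AHEI-2010 component: linear interpolation between cutoffs, or alcohol."""

    name: str
    rule: str = "linear"
    field_name: str | None = None
    c0: float | None = None
    c10: float | None = None
    c10_by_sex: Mapping[str, float] | None = None
    extra: dict = field(default_factory=dict)

    def evaluate(self, inp: ScoringInput) -> float:
        if self.rule == "ahei_alcohol":
            drinks = getattr(inp, self.field_name)
            if drinks == 0:
                return float(self.extra["nondrinker_pts"])
            lo, hi = self.extra["optimum"][inp.sex]
            zero_at = self.extra["zero_at"][inp.sex]
            if lo <= drinks <= hi:
                return 10.0
            if drinks < lo:
                base = float(self.extra["nondrinker_pts"])
                return base + (10.0 - base) * drinks / lo
            return max(0.0, 10.0 * (zero_at - drinks) / (zero_at - hi))
        c10 = (self.c10 if self.c10 is not None
               else float(self.c10_by_sex[inp.sex]))
        value = getattr(inp, self.field_name)
        frac = (value - self.c0) / (c10 - self.c0)
        return 10.0 * min(1.0, max(0.0, frac))


@dataclass(frozen=True)
class ScoreDefinitions:
    gs2: tuple[ComponentDefinition, ...]
    gs1: tuple[ComponentDefinition, ...]
    ahei: tuple[AheiComponent, ...]


def _parse_component(raw: Mapping, weighted: bool) -> ComponentDefinition:
    rule = raw.get("rule", "bands")
    domain = tuple(raw.get("domain", (0.0, math.inf)))
    extra: dict = {}
    bands: tuple[Band, ...] = ()
    if rule == "bands":
        bands = _parse_bands(raw["bands"])
        _validate_tiling(bands, domain)
    elif rule == "bands_by_age":
        extra["age_threshold"] = float(raw["age_threshold"])
        for key in ("bands_young", "bands_old"):
            extra[key] = _parse_bands(raw[key])
            _validate_tiling(extra[key], domain)
    elif rule == "alcohol_gs1":
        extra["abstainer_pts"] = float(raw["abstainer_pts"])
        for key in ("bands_female", "bands_male"):
            extra[key] = _parse_bands(raw[key])
            _validate_tiling(extra[key], domain)
    elif rule == "water_soda":
        extra["water_threshold"] = float(raw["water_threshold"])
        extra["soda_threshold"] = float(raw["soda_threshold"])
        extra["points"] = dict(raw["points"])
    else:
        raise ValueError(f"unknown component rule {rule!r}")

    subs = []
    for s in raw.get("sub_items", ()):
        srule = s.get("rule", "bands")
        if srule == "organic":
            subs.append(SubItem(name=s["name"], rule="organic", item=s["item"]))
        else:
            sdomain = tuple(s.get("domain", (0.0, math.inf)))
            sbands = _parse_bands(s["bands"])
            _validate_tiling(sbands, sdomain)
            gate = s.get("gate")
            subs.append(SubItem(
                name=s["name"], rule="bands", field_name=s["field"],
                bands=sbands, domain=sdomain,
                gate_field=gate["field"] if gate else None,
                gate_above=float(gate["above"]) if gate else None,
            ))

    weight = float(raw.get("weight", 1.0))
    if weighted and weight < 1:
        raise ValueError(f"component {raw['name']!r} has weight < 1")
    if rule == "water_soda":
        fname = None
    else:
        fname = raw.get("field")
    return ComponentDefinition(
        name=raw["name"], rule=rule, kind=raw.get("kind", "adequacy"),
        weight=weight if weighted else 1.0,
        principal=bool(raw.get("principal", False)),
        field_name=fname, bands=bands, domain=domain,
        sub_items=tuple(subs), extra=extra,
    )


def _parse_ahei(raw: Mapping) -> AheiComponent:
    if raw.get("rule") == "ahei_alcohol":
        return AheiComponent(
            name=raw["name"], rule="ahei_alcohol", field_name=raw["field"],
            extra={
                "nondrinker_pts": float(raw["nondrinker_pts"]),
                "optimum": {k: tuple(map(float, v))
                            for k, v in raw["optimum"].items()},
                "zero_at": {k: float(v) for k, v in raw["zero_at"].items()},
            },
        )
    return AheiComponent(
        name=raw["name"], field_name=raw["field"],
        c0=float(raw["c0"]),
        c10=float(raw["c10"]) if "c10" in raw else None,
        c10_by_sex=({k: float(v) for k, v in raw["c10_by_sex"].items()}
                    if "c10_by_sex" in raw else None),
    )


@lru_cache(maxsize=4)
def load_definitions(path: str | None = None) -> ScoreDefinitions:
    """Load and validate the score-definition file (bundled by default)."""
    if path is None:
        text = (resources.files("pnnskit") / "data" / "score_definitions.yaml"
                ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    gs2 = tuple(_parse_component(c, weighted=True) for c in raw["gs2"]["components"])
    gs1 = tuple(_parse_component(c, weighted=False) for c in raw["gs1"]["components"])
    ahei = tuple(_parse_ahei(c) for c in raw["ahei2010"]["components"])
    return ScoreDefinitions(gs2=gs2, gs1=gs1, ahei=ahei)


# ---------------------------------------------------------------------------
# Score evaluation
# ---------------------------------------------------------------------------

@dataclass
class ComponentScore:
    component: str
    raw_points: float
    sub_item_points: float
    weight: float

    @property
    def weighted_points(self) -> float:
        return self.weight * (self.raw_points + self.sub_item_points)


def score_pnns_gs2(
    inp: ScoringInput, definitions: ScoreDefinitions | None = None
) -> dict:
    """2017-guidelines score: weighted sum over 13 components with sub-items."""
    defs = definitions or load_definitions()
    comps = {
        c.name: ComponentScore(c.name, c.base_points(inp), c.sub_points(inp),
                               c.weight)
        for c in defs.gs2
    }
    return {"total": sum(cs.weighted_points for cs in comps.values()),
            "components": comps}


def score_spnns_gs2(
    inp: ScoringInput, definitions: ScoreDefinitions | None = None
) -> dict:
    """Simplified 2017 score: principal recommendations only, same weights."""
    defs = definitions or load_definitions()
    comps = {
        c.name: ComponentScore(c.name, c.base_points(inp), 0.0, c.weight)
        for c in defs.gs2 if c.principal
    }
    return {"total": sum(cs.weighted_points for cs in comps.values()),
            "components": comps}


def score_mpnns_gs1(
    inp: ScoringInput, definitions: ScoreDefinitions | None = None
) -> dict:
    """2001-guidelines score without physical activity: unweighted 12 components."""
    defs = definitions or load_definitions()
    comps = {
        c.name: ComponentScore(c.name, c.base_points(inp), 0.0, 1.0)
        for c in defs.gs1
    }
    return {"total": sum(cs.weighted_points for cs in comps.values()),
            "components": comps}


def score_ahei2010(
    inp: ScoringInput, definitions: ScoreDefinitions | None = None
) -> dict:
    """AHEI-2010 without trans fat: 10 components, each 0-10, total 0-100."""
    defs = definitions or load_definitions()
    comps = {
        c.name: ComponentScore(c.name, c.evaluate(inp), 0.0, 1.0)
        for c in defs.ahei
    }
    return {"total": sum(cs.weighted_points for cs in comps.values()),
            "components": comps}


INDEX_SCORERS = {
    "pnns_gs2": score_pnns_gs2,
    "spnns_gs2": score_spnns_gs2,
    "mpnns_gs1": score_mpnns_gs1,
    "ahei2010": score_ahei2010,
}


def score_panel(
    inputs: Iterable[ScoringInput],
    definitions: ScoreDefinitions | None = None,
) -> pd.DataFrame:
    """Score a collection of participants on all four indices.

    Returns one row per participant with total columns (``pnns_gs2`` ...)
    and per-component audit columns (``pnns_gs2__fruits_vegetables`` ...).
    """
    defs = definitions or load_definitions()
    rows = []
    for inp in inputs:
        row: dict = {"participant_id": inp.participant_id, "sex": inp.sex}
        for index_name, scorer in INDEX_SCORERS.items():
            res = scorer(inp, defs)
            row[index_name] = res["total"]
            for name, cs in res["components"].items():
                row[f"{index_name}__{name}"] = cs.weighted_points
        rows.append(row)
    return pd.DataFrame(rows)


def standardize_panel(
    panel: pd.DataFrame,
    index_columns: Sequence[str] = ("pnns_gs2", "spnns_gs2", "mpnns_gs1",
                                    "ahei2010"),
) -> pd.DataFrame:
    """Add ``<index>_std`` columns: totals divided by their sample SD.

    No centering is applied (scores keep their sign and origin); the SD uses
    the n-1 denominator.  A zero or undefined SD is an error.
    """
    out = panel.copy()
    for col in index_columns:
        sd = out[col].std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(
                f"cannot standardize {col!r}: sample SD is zero or undefined"
            )
        out[f"{col}_std"] = out[col] / sd
    return out
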