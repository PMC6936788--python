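"""Synthetic study generator with known ground truth.

Emulates the inputs of a web-cohort diet/weight study: participants with
sociodemographics, repeated 24-hour dietary records (2 weekdays + 1 weekend
day per triplet, completed within the first 2 years), organic-consumption
profiles, and yearly-or-better anthropometric follow-up.  Log-BMI
trajectories follow the longitudinal model the package fits — participant
random intercept and slope, a score-by-time interaction, and continuous-time
AR(1) residuals — so parameter recovery is testable against a known truth.

A separate piecewise-exponential generator produces left-truncated survival
data with a known per-SD log hazard ratio for exercising the Cox machinery.

One global seed is split into per-stream substreams (participants, records,
organic, anthropometrics) so each stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intake import BlackParams, goldberg_cutoff, schofield_bmr

EPOCH = pd.Timestamp("2010-01-04")  # a Monday; weekday arithmetic below relies on it

#: Mean usual intake (g or ml/day) per food group for the default generator.
DEFAULT_FOOD_MEANS = {
    "fruits": 212.0, "vegetables": 228.0, "fruit_juice": 51.0,
    "dried_fruit": 5.0, "nuts": 8.0, "legumes": 12.0, "whole_grains": 36.0,
    "refined_grains": 141.0, "dairy": 234.0, "red_meat": 55.0,
    "processed_meat": 33.0, "fish": 40.0, "added_fat_animal": 12.0,
    "added_fat_vegetal": 8.0, "added_fat_olive_ala": 5.0,
    "sugary_foods": 100.0, "sweet_beverages": 36.0,
    "artificial_beverages": 15.0, "water": 1100.0,
}

#: Direction in which the latent diet-quality trait scales each group.
HEALTHY_GROUPS = ("fruits", "vegetables", "nuts", "legumes", "whole_grains",
                  "fish", "water", "added_fat_olive_ala")
UNHEALTHY_GROUPS = ("red_meat", "processed_meat", "refined_grains",
                    "sugary_foods", "sweet_beverages", "added_fat_animal")

EDUCATION_LEVELS = ("primary", "secondary", "university")
EDUCATION_PROBS = (0.010, 0.355, 0.635)
OCCUPATIONS = ("farmer_self_employed", "managerial", "employee", "student",
               "manual_worker", "intermediate", "retired", "unemployed")
OCCUPATION_PROBS = (0.019, 0.230, 0.161, 0.059, 0.010, 0.171, 0.238, 0.112)
INCOME_BANDS = ("<=1800", "1800-2700", ">2700")
INCOME_PROBS = (0.433, 0.270, 0.297)
SMOKING_LEVELS = ("non_smoker", "former_smoker", "smoker")
SMOKING_PROBS = (0.499, 0.365, 0.136)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated cohort."""

    n_participants: int = 1000
    seed: int = 0
    records_per_participant: int = 6
    follow_up_years: float = 6.0
    questionnaire_interval_years: float = 0.5
    questionnaire_jitter_years: float = 0.08
    fraction_female: float = 0.761
    age_mean: float = 47.1
    age_sd: float = 14.1
    underreporter_fraction: float = 0.10
    organic_probs: tuple[float, float, float] = (0.20, 0.40, 0.40)
    diet_quality_sd: float = 0.35       # log-scale effect of the latent trait
    day_noise_sd: float = 0.30          # day-to-day lognormal intake noise
    participant_noise_sd: float = 0.35  # between-participant intake noise
    trajectory_score: str = "pnns_gs2_std"

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        for name in ("fraction_female", "underreporter_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.organic_probs) - 1) > 1e-9:
            raise ValueError("organic_probs must sum to 1")
        if not 3 <= self.records_per_participant <= 10:
            raise ValueError("records_per_participant must lie in 3..10")


@dataclass
class TrueParameters:
    """Generating coefficients of the log-BMI trajectory model."""

    beta_score: float = -0.040        # per SD of score, at baseline
    beta_time: float = 0.0027         # per year
    beta_interaction: float = -0.0008  # per SD per year
    random_intercept_sd: float = 0.15
    random_slope_sd: float = 0.004
    residual_sd: float = 0.02
    residual_autocorr_rho: float = 0.5
    cox_log_hr_per_sd: float = -0.29  # piecewise-exponential generator only

    def __post_init__(self) -> None:
        if not 0 < self.residual_autocorr_rho < 1:
            raise ValueError("residual_autocorr_rho must lie in (0, 1)")
        for name in ("random_intercept_sd", "random_slope_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticStudy:
    participants: pd.DataFrame
    records: pd.DataFrame
    organic: pd.DataFrame
    anthro: pd.DataFrame
    panel: pd.DataFrame
    truth: TrueParameters
    config: SimulationConfig


def _streams(seed: int, n: int = 5) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_participants(config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw baseline participants: sex, age, height, anchor BMI, covariates.

    The ``baseline_bmi`` column is the participant's pre-diet anchor; the
    trajectory generator shifts it by the score effect and random effects.
    A latent ``diet_quality`` trait (standard normal) and the planted
    ``is_underreporter`` flag drive the dietary-record generator.
    """
    rng = rng or _streams(config.seed)[0]
    n = config.n_participants
    sex = np.where(rng.random(n) < config.fraction_female, "female", "male")
    age = config.age_mean + config.age_sd * rng.standard_normal(n)
    age = np.clip(age, 18.0, 90.0)
    height = np.where(
        sex == "female",
        163.9 + 6.0 * rng.standard_normal(n),
        176.6 + 6.5 * rng.standard_normal(n),
    )
    log_bmi = np.log(23.3) + 0.16 * rng.standard_normal(n)
    mets = rng.lognormal(mean=7.63, sigma=0.81, size=n)
    df = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "sex": sex,
        "age_at_inclusion": np.round(age, 2),
        "height": np.round(height, 1),
        "baseline_bmi": np.round(np.exp(log_bmi), 3),
        "education": rng.choice(EDUCATION_LEVELS, size=n, p=EDUCATION_PROBS),
        "occupation": rng.choice(OCCUPATIONS, size=n, p=OCCUPATION_PROBS),
        "income": rng.choice(INCOME_BANDS, size=n, p=INCOME_PROBS),
        "smoking": rng.choice(SMOKING_LEVELS, size=n, p=SMOKING_PROBS),
        "cohabiting": rng.random(n) < 0.724,
        "physical_activity": np.round(mets, 0),
        "month_of_inclusion": rng.integers(1, 13, size=n),
        "diet_quality": np.round(rng.standard_normal(n), 4),
        "is_underreporter": rng.random(n) < config.underreporter_fraction,
    })
    df["inclusion_date"] = (
        EPOCH
        + pd.to_timedelta(rng.integers(0, 5, size=n) * 364, unit="D")
        + pd.to_timedelta((df["month_of_inclusion"] - 1) * 28, unit="D")
    )
    return df


def generate_dietary_records(participants: pd.DataFrame,
                             config: SimulationConfig,
                             rng: np.random.Generator | None = None,
                             food_means: dict | None = None) -> pd.DataFrame:
    """24-hour records in weekday/weekend triplets over the first 2 years.

    Records come in triplets of 2 weekdays + 1 weekend day.  Food-group
    amounts are log-normal around `DEFAULT_FOOD_MEANS`, scaled up or down by
    the participant's latent diet-quality trait.  Energy intake is anchored
    to the Schofield BMR so that planted under-reporters fall below the
    Goldberg cut-off while ordinary reporters stay above it.
    """
    rng = rng or _streams(config.seed)[1]
    means = dict(food_means or DEFAULT_FOOD_MEANS)
    cutoff = goldberg_cutoff(config.records_per_participant, BlackParams())
    n_triplets = -(-config.records_per_participant // 3)

    rows = []
    for p in participants.itertuples(index=False):
        q = p.diet_quality
        weight = p.baseline_bmi * (p.height / 100.0) ** 2
        bmr = schofield_bmr(p.sex, p.age_at_inclusion, weight)
        if p.is_underreporter:
            ei_ratio = rng.uniform(0.60, 0.85) * cutoff
        else:
            ei_ratio = max(1.2, rng.normal(1.5, 0.18))
        usual_energy = bmr * ei_ratio

        pf = {}
        for g, m in means.items():
            direction = (1.0 if g in HEALTHY_GROUPS
                         else -1.0 if g in UNHEALTHY_GROUPS else 0.0)
            shift = direction * config.diet_quality_sd * q
            pf[g] = m * np.exp(
                shift + config.participant_noise_sd * rng.standard_normal()
                - config.participant_noise_sd**2 / 2
            )
        white_ham_frac = rng.beta(2, 4)
        fatty_fish_frac = rng.beta(3, 5)
        fat_share = max(4.0, rng.normal(15.5 - 1.0 * q, 3.5))
        sugary_share = max(1.0, rng.normal(10.0 - 1.2 * q, 3.0))
        salt_mean = 7.2 * np.exp(-0.08 * q)
        abstainer = rng.random() < 0.25
        ethanol_mean = 0.0 if abstainer else rng.lognormal(np.log(9.0) - 0.2 * q, 0.8)
        p_drink_day = 0.0 if abstainer else rng.beta(4, 2)

        # triplet start weeks spread over the 2-year window
        starts = np.sort(rng.uniform(0, 700, size=n_triplets))
        offsets = []
        for s in starts:
            week_start = int(s // 7) * 7
            wd = rng.choice(5, size=2, replace=False)       # Mon..Fri
            we = rng.choice([5, 6])                         # Sat/Sun
            offsets.extend([(week_start + d, False) for d in wd])
            offsets.append((week_start + we, True))
        offsets = offsets[: config.records_per_participant]

        for day, is_weekend in offsets:
            noise = lambda: np.exp(
                config.day_noise_sd * rng.standard_normal()
                - config.day_noise_sd**2 / 2
            )
            amounts = {g: pf[g] * noise() for g in means}
            energy = usual_energy * np.exp(0.12 * rng.standard_normal() - 0.0072)
            drinks = rng.random() < p_drink_day
            ethanol = (ethanol_mean / max(p_drink_day, 1e-9)) * noise() if drinks else 0.0
            ethanol = min(ethanol, 0.8 * energy / 7.0)  # ethanol kcal < energy
            eiwa = max(energy - 7.0 * ethanol, 0.0)
            rows.append({
                "participant_id": p.participant_id,
                "date": (p.inclusion_date + pd.Timedelta(days=int(day))).date(),
                "is_weekend": bool(is_weekend),
                **{g: round(v, 2) for g, v in amounts.items()},
                "white_ham": round(amounts["processed_meat"] * white_ham_frac, 2),
                "fatty_fish": round(amounts["fish"] * fatty_fish_frac, 2),
                "ethanol": round(ethanol, 2),
                "energy_total": round(energy, 1),
                "salt": round(salt_mean * noise(), 2),
                "energy_added_fat": round(fat_share / 100.0 * eiwa * noise(), 1),
                "energy_sugary": round(sugary_share / 100.0 * eiwa * noise(), 1),
            })
    return pd.DataFrame(rows)


def generate_organic_profiles(participants: pd.DataFrame,
                              records: pd.DataFrame,
                              config: SimulationConfig,
                              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Organic-consumption frequencies for five items, plus consumed flags."""
    rng = rng or _streams(config.seed)[2]
    n = len(participants)
    levels = ("most_of_the_time", "occasionally", "never")
    df = pd.DataFrame({"participant_id": participants["participant_id"].to_numpy()})
    for item in ("fruits", "vegetables", "bread", "rice_pasta", "legumes"):
        df[item] = rng.choice(levels, size=n, p=config.organic_probs)
    grains = records.groupby("participant_id")[["whole_grains", "refined_grains"]].sum()
    legume = records.groupby("participant_id")["legumes"].sum()
    df["rice_pasta_consumed"] = df["participant_id"].map(
        (grains.sum(axis=1) > 0)).fillna(False).astype(bool)
    df["legumes_consumed"] = df["participant_id"].map(
        (legume > 0)).fillna(False).astype(bool)
    return df


def generate_bmi_trajectories(participants: pd.DataFrame,
                              score_per_participant: pd.Series,
                              truth: TrueParameters,
                              config: SimulationConfig,
                              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate anthropometric follow-up from the log-BMI trajectory model.

    For participant i with standardized score S_i and measurement times t:

        log BMI_i(t) = log(anchor BMI_i) + beta_score * S_i
                       + (beta_time + beta_interaction * S_i + b1_i) * t
                       + b0_i + eps_i(t),
        corr(eps_i(s), eps_i(t)) = rho ** |t - s|.

    Weights are back-transformed through the participant's height.
    """
    rng = rng or _streams(config.seed)[3]
    if (participants["height"] <= 0).any():
        raise ValueError("non-positive height encountered")
    scores = score_per_participant
    rows = []
    for p in participants.itertuples(index=False):
        s = float(scores.loc[p.participant_id])
        b0 = truth.random_intercept_sd * rng.standard_normal()
        b1 = truth.random_slope_sd * rng.standard_normal()
        times = [0.0]
        t = 0.0
        while True:
            t += config.questionnaire_interval_years + (
                config.questionnaire_jitter_years * rng.standard_normal()
            )
            if t > config.follow_up_years:
                break
            times.append(max(t, 1e-3))
        times = np.array(sorted(times))
        gaps = np.abs(times[:, None] - times[None, :])
        cov = truth.residual_sd**2 * truth.residual_autocorr_rho**gaps
        eps = (np.linalg.cholesky(cov + 1e-12 * np.eye(len(times)))
               @ rng.standard_normal(len(times))
               if truth.residual_sd > 0 else np.zeros(len(times)))
        log_bmi = (
            np.log(p.baseline_bmi)
            + truth.beta_score * s + b0
            + (truth.beta_time + truth.beta_interaction * s + b1) * times
            + eps
        )
        bmi = np.exp(log_bmi)
        for t_i, b in zip(times, bmi):
            rows.append({
                "participant_id": p.participant_id,
                "time_years": round(float(t_i), 4),
                "weight": round(float(b) * (p.height / 100.0) ** 2, 2),
                "bmi": round(float(b), 4),
            })
    return pd.DataFrame(rows)


def generate_cohort(config: SimulationConfig,
                    truth: TrueParameters | None = None,
                    out_dir: str | Path | None = None) -> SyntheticStudy:
    """Full synthetic study: participants, records, organic, scores, anthro.

    The standardized guideline score computed by the package's own intake +
    scoring pipeline (column ``config.trajectory_score`` of the panel) drives
    the BMI trajectories, so downstream model fits can recover ``truth``.
    """
    from .scoring import score_panel, standardize_panel
    from .intake import build_scoring_inputs

    truth = truth or TrueParameters()
    rngs = _streams(config.seed)
    participants = generate_participants(config, rngs[0])
    records = generate_dietary_records(participants, config, rngs[1])
    organic = generate_organic_profiles(participants, records, config, rngs[2])
    inputs = build_scoring_inputs(records, organic, participants)
    panel = standardize_panel(score_panel(inputs))
    scores = panel.set_index("participant_id")[config.trajectory_score]
    anthro = generate_bmi_trajectories(participants, scores, truth, config, rngs[3])
    study = SyntheticStudy(participants=participants, records=records,
                           organic=organic, anthro=anthro, panel=panel,
                           truth=truth, config=config)
    if out_dir is not None:
        write_cohort(study, out_dir)
    return study


def write_cohort(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write the on-disk layout: CSVs with ISO dates plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.participants.to_csv(out / "participants.csv", index=False)
    study.records.to_csv(out / "records.csv", index=False)
    study.organic.to_csv(out / "organic.csv", index=False)
    study.anthro.to_csv(out / "anthro.csv", index=False)
    study.panel.to_csv(out / "scores.csv", index=False)
    (out / "truth.json").write_text(
        json.dumps({"truth": asdict(study.truth), "config": asdict(study.config)},
                   indent=2, default=str),
        encoding="utf-8",
    )


def generate_survival_data(n: int,
                           log_hr_per_sd: float,
                           seed: int,
                           baseline_hazard: float = 0.04,
                           entry_age_mean: float = 47.0,
                           entry_age_sd: float = 14.0,
                           max_follow_up_years: float = 8.0,
                           n_covariates: int = 0) -> pd.DataFrame:
    """Left-truncated survival data from a piecewise-exponential model.

    Hazard on the age timescale is ``baseline_hazard * exp(beta * score)``
    (constant in age), with entry at the drawn age and administrative
    censoring after a uniform 2..``max_follow_up_years`` follow-up.  Extra
    null covariates (standard normal) can be appended for calibration runs.
    """
    rng = np.random.default_rng(seed)
    entry = np.clip(entry_age_mean + entry_age_sd * rng.standard_normal(n), 18, 90)
    score = rng.standard_normal(n)
    rate = baseline_hazard * np.exp(log_hr_per_sd * score)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(2.0, max_follow_up_years, size=n)
    observed = np.minimum(event_time, censor_time)
    df = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "entry_age": entry,
        "exit_age": entry + observed,
        "event": event_time <= censor_time,
        "score": score,
    })
    for k in range(n_covariates):
        df[f"x{k}"] = rng.standard_normal(n)
    return df
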