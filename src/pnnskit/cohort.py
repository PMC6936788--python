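"""Study-sample construction: selection rules, baselines, events, quintiles.

Baseline is the midpoint of a participant's first and last dietary record
(the middle of the exposure window).  Overweight/obesity events are timed at
the midpoint between the first questionnaire reporting a BMI at or above the
threshold and the previous one; follow-up is left-truncated at the baseline
age and right-censored at the last questionnaire.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from . import intake

#: Covariate columns required complete for the complete-case analysis.
COVARIATE_COLUMNS = [
    "sex", "age_at_inclusion", "height", "education", "occupation", "income",
    "smoking", "cohabiting", "physical_activity", "month_of_inclusion",
]


@dataclass
class SelectionRules:
    """Configurable exclusion cascade for the working sample."""

    min_records: int = 3
    record_window_years: float = 2.0
    exclude_underreporters: bool = False
    sensitivity: bool = False                 # drop clinical flags + extreme BMI
    extreme_bmi_percentile: float = 1.0
    black_params: intake.BlackParams | None = None


def compute_baseline_date(dates: Sequence) -> pd.Timestamp:
    """Midpoint of the first and last dietary-record dates."""
    ts = pd.to_datetime(pd.Series(list(dates)))
    if len(ts) == 0:
        raise ValueError("no dietary records to define a baseline from")
    first, last = ts.min(), ts.max()
    return first + (last - first) / 2


def baseline_offsets(records: pd.DataFrame,
                     participants: pd.DataFrame) -> pd.Series:
    """Years from inclusion to the baseline date, per participant."""
    inc = participants.set_index("participant_id")["inclusion_date"]
    out = {}
    for pid, grp in records.groupby("participant_id"):
        base = compute_baseline_date(grp["date"])
        out[pid] = (base - pd.Timestamp(inc.loc[pid])).days / 365.25
    return pd.Series(out, name="baseline_offset_years")


def baseline_bmi(anthro: pd.DataFrame, offsets: pd.Series) -> pd.Series:
    """BMI at the measure closest to each participant's baseline date."""
    out = {}
    for pid, grp in anthro.groupby("participant_id"):
        t0 = offsets.get(pid, 0.0)
        idx = (grp["time_years"] - t0).abs().idxmin()
        out[pid] = grp.loc[idx, "bmi"]
    return pd.Series(out, name="baseline_bmi")


def select_working_sample(
    participants: pd.DataFrame,
    records: pd.DataFrame,
    anthro: pd.DataFrame,
    rules: SelectionRules | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the selection cascade; return retained participants + log.

    Cascade (each participant is excluded at the first failing step):
    too few records in the exposure window, no anthropometric follow-up,
    incomplete covariates, (optionally) under-reporting, (optionally, in
    sensitivity mode) cancer / bariatric-surgery / eating-disorder flags and
    BMI below the working sample's first percentile.  The log partitions the
    input exactly: retained + sum of exclusions = input count.
    """
    rules = rules or SelectionRules()
    parts = participants.set_index("participant_id")
    log: dict[str, int] = {"input": len(parts)}
    remaining = parts.index.to_numpy()

    inc = parts["inclusion_date"]
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec["offset_years"] = (
        rec["date"] - rec["participant_id"].map(inc).astype("datetime64[ns]")
    ).dt.days / 365.25
    in_window = rec[rec["offset_years"] <= rules.record_window_years]
    n_rec = in_window.groupby("participant_id").size()
    enough = n_rec.reindex(remaining, fill_value=0) >= rules.min_records
    log["insufficient_records"] = int((~enough).sum())
    remaining = remaining[enough.to_numpy()]

    has_anthro = pd.Index(remaining).isin(anthro["participant_id"].unique())
    log["no_anthropometry"] = int((~has_anthro).sum())
    remaining = remaining[has_anthro]

    cov_cols = [c for c in COVARIATE_COLUMNS if c in parts.columns]
    complete = parts.loc[remaining, cov_cols].notna().all(axis=1)
    log["incomplete_covariates"] = int((~complete).sum())
    remaining = remaining[complete.to_numpy()]

    if rules.exclude_underreporters:
        keep = []
        for pid in remaining:
            grp = records[records["participant_id"] == pid]
            usual = intake.aggregate_usual_diet(grp)
            p = parts.loc[pid]
            weight = p["baseline_bmi"] * (p["height"] / 100.0) ** 2
            flagged, _ = intake.flag_underreporting(
                usual["energy_total"], p["sex"], p["age_at_inclusion"],
                weight, p["height"], n_days=len(grp),
                params=rules.black_params,
            )
            keep.append(not flagged)
        keep = np.asarray(keep, dtype=bool)
        log["under_reporting"] = int((~keep).sum())
        remaining = remaining[keep]

    if rules.sensitivity:
        sub = parts.loc[remaining]
        clinical = np.zeros(len(sub), dtype=bool)
        for col in ("cancer", "bariatric_surgery", "eating_disorder"):
            if col in sub.columns:
                clinical |= sub[col].fillna(False).astype(bool).to_numpy()
        log["clinical_condition"] = int(clinical.sum())
        remaining = remaining[~clinical]
        sub = parts.loc[remaining]
        cut = np.percentile(sub["baseline_bmi"], rules.extreme_bmi_percentile)
        extreme = (sub["baseline_bmi"] < cut).to_numpy()
        log["extreme_bmi"] = int(extreme.sum())
        remaining = remaining[~extreme]

    log["retained"] = len(remaining)
    assert log["input"] == log["retained"] + sum(
        v for k, v in log.items() if k not in ("input", "retained")
    )
    return parts.loc[remaining].reset_index(), log


def derive_survival_record(
    times: Sequence[float],
    bmis: Sequence[float],
    baseline_age: float,
    threshold: float,
    baseline_bmi: float | None = None,
) -> dict:
    """Left-truncated interval on the age timescale for one participant.

    ``times`` are years since baseline (strictly positive) with matching BMI
    values.  The event is timed at the midpoint between the first measure at
    or above ``threshold`` and the previous one (baseline acting as the
    previous measure when the first follow-up already crosses); censoring is
    at the last measure.
    """
    t = np.asarray(times, dtype=float)
    b = np.asarray(bmis, dtype=float)
    if t.size == 0:
        raise ValueError("no post-baseline measures")
    if np.any(t <= 0):
        raise ValueError("post-baseline measure times must be positive")
    order = np.argsort(t)
    t, b = t[order], b[order]
    if baseline_bmi is not None and baseline_bmi >= threshold:
        raise ValueError(
            "baseline BMI at or above threshold: participant should have "
            "been excluded from this analysis"
        )
    crossing = np.nonzero(b >= threshold)[0]
    if crossing.size:
        i = crossing[0]
        prev_t = t[i - 1] if i > 0 else 0.0
        event_time, event = (prev_t + t[i]) / 2.0, True
    else:
        event_time, event = t[-1], False
    return {
        "entry_age": float(baseline_age),
        "exit_age": float(baseline_age + event_time),
        "event": bool(event),
        "threshold": float(threshold),
    }


def build_survival_table(
    anthro: pd.DataFrame,
    participants: pd.DataFrame,
    offsets: pd.Series,
    threshold: float,
) -> tuple[pd.DataFrame, dict]:
    """Survival records for all baseline-eligible participants.

    Participants already at or above ``threshold`` at baseline are excluded
    (counted in the returned log), as are those without post-baseline
    follow-up.
    """
    parts = participants.set_index("participant_id")
    base_bmi = baseline_bmi(anthro, offsets)
    rows, log = [], {"baseline_above_threshold": 0, "no_follow_up": 0}
    for pid, grp in anthro.groupby("participant_id"):
        if pid not in parts.index:
            continue
        t0 = offsets.get(pid, 0.0)
        if base_bmi.loc[pid] >= threshold:
            log["baseline_above_threshold"] += 1
            continue
        post = grp[grp["time_years"] > t0]
        if len(post) == 0:
            log["no_follow_up"] += 1
            continue
        rec = derive_survival_record(
            (post["time_years"] - t0).to_numpy(), post["bmi"].to_numpy(),
            baseline_age=parts.loc[pid, "age_at_inclusion"] + t0,
            threshold=threshold,
            baseline_bmi=float(base_bmi.loc[pid]),
        )
        rec["participant_id"] = pid
        rows.append(rec)
    return pd.DataFrame(rows), log


def assign_quintiles(
    panel: pd.DataFrame,
    score_col: str,
    by_sex: bool = True,
    sex_col: str = "sex",
) -> pd.Series:
    """Quintile labels 1..5, computed within sex by default.

    Ties are broken by stable rank order (participant order in the panel),
    so quintile sizes within each sex differ by at most one.
    """
    def _labels(grp: pd.DataFrame) -> pd.Series:
        if len(grp) < 5:
            raise ValueError("need at least 5 participants per group")
        if grp[score_col].nunique() == 1:
            raise ValueError("degenerate quintile cutpoints: all scores equal")
        order = np.lexsort((grp["participant_id"].to_numpy(),
                            grp[score_col].to_numpy()))
        ranks = np.empty(len(grp), dtype=int)
        ranks[order] = np.arange(len(grp))
        return pd.Series(ranks * 5 // len(grp) + 1, index=grp.index)

    if by_sex:
        out = pd.Series(index=panel.index, dtype=int)
        for _, grp in panel.groupby(sex_col):
            out.loc[grp.index] = _labels(grp)
    else:
        out = _labels(panel)
    return out.rename("quintile")


def quintile_medians(scores: pd.Series, quintiles: pd.Series) -> pd.Series:
    """Median score within each quintile (for the linear trend test)."""
    return scores.groupby(quintiles).median()


def cochran_armitage_trend(table: np.ndarray,
                           scores: Sequence[float] | None = None) -> tuple[float, float]:
    """Cochran-Armitage test for trend in a 2 x k table.

    Rows are the binary outcome, columns the ordered groups.  Returns the
    Z statistic and a two-sided p-value.
    """
    table = np.asarray(table, dtype=float)
    if table.shape[0] != 2:
        raise ValueError("Cochran-Armitage requires a 2 x k table")
    k = table.shape[1]
    s = np.asarray(scores if scores is not None else np.arange(1, k + 1), float)
    n_j = table.sum(axis=0)
    n = n_j.sum()
    r = table[0].sum()
    p_hat = r / n
    t_stat = float(np.sum(s * (table[0] - n_j * p_hat)))
    var = p_hat * (1 - p_hat) * (np.sum(s**2 * n_j) - np.sum(s * n_j) ** 2 / n)
    if var <= 0:
        return 0.0, 1.0
    z = t_stat / np.sqrt(var)
    return z, 2 * st.norm.sf(abs(z))


def descriptive_association_tests(
    table: pd.DataFrame,
    quintile_col: str,
    variables: Mapping[str, str],
) -> pd.DataFrame:
    """Association of baseline variables with score quintiles.

    ``variables`` maps column name to its type: ``"unordered"`` (chi-squared),
    ``"binary"`` (Cochran-Armitage trend), ``"ordered"`` (Spearman), or
    ``"numeric"`` (linear-contrast slope on the quintile index).
    """
    q = table[quintile_col]
    rows = []
    for name, kind in variables.items():
        x = table[name]
        if kind == "unordered":
            ct = pd.crosstab(x, q)
            stat, p, _, _ = st.chi2_contingency(ct)
            test = "chi_squared"
        elif kind == "binary":
            ct = pd.crosstab(x, q)
            if ct.shape[0] != 2:
                raise ValueError(f"{name!r} is not binary")
            stat, p = cochran_armitage_trend(ct.to_numpy(),
                                             scores=ct.columns.to_numpy(float))
            test = "cochran_armitage"
        elif kind == "ordered":
            codes = (x if np.issubdtype(np.asarray(x).dtype, np.number)
                     else pd.Categorical(x).codes)
            stat, p = st.spearmanr(codes, q)
            test = "spearman"
        elif kind == "numeric":
            X = sm.add_constant(q.astype(float))
            fit = sm.OLS(x.astype(float), X).fit()
            stat, p = fit.tvalues.iloc[1], fit.pvalues.iloc[1]
            test = "linear_contrast"
        else:
            raise ValueError(f"variable {name!r} has unknown type {kind!r}")
        rows.append({"variable": name, "test": test,
                     "statistic": float(stat), "p_value": float(p)})
    return pd.DataFrame(rows)


def energy_adjust_residual(intakes: pd.Series, energy: pd.Series,
                           sex: pd.Series) -> pd.Series:
    """Residual-method energy adjustment, stratified by sex.

    Residuals of a within-sex linear regression of intake on energy, shifted
    by the grand mean so units and the overall mean are preserved.
    """
    if energy.nunique() <= 1:
        raise ValueError("energy intake is constant: residual method undefined")
    out = pd.Series(index=intakes.index, dtype=float)
    grand_mean = float(intakes.mean())
    for _, idx in intakes.groupby(sex).groups.items():
        X = sm.add_constant(energy.loc[idx].astype(float))
        fit = sm.OLS(intakes.loc[idx].astype(float), X).fit()
        out.loc[idx] = fit.resid + grand_mean
    return out
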