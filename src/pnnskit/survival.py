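"""Left-truncated Cox proportional-hazards models on the age timescale.

Participants enter the risk set at their baseline age and leave at the event
or censoring age, so calendar inclusion plays no role in the hazard ordering.
Exposure can enter as sex-specific quintile indicators (Q1 reference), per
point, or per standard deviation; continuous adjustment covariates can be
expanded on a 3-knot restricted cubic spline basis.  Estimation delegates to
lifelines (Efron tie handling); diagnostics follow the scaled-Schoenfeld
approach with the Grambsch-Therneau chi-squared statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from lifelines import CoxPHFitter


@dataclass(frozen=True)
class SplineSpec:
    """Restricted cubic spline with knots at quantiles of the covariate."""

    n_knots: int = 3
    quantiles: tuple[float, ...] = (0.10, 0.50, 0.90)

    def __post_init__(self) -> None:
        if self.n_knots != len(self.quantiles):
            raise ValueError("n_knots must match the number of knot quantiles")
        if any(b <= a for a, b in zip(self.quantiles, self.quantiles[1:])):
            raise ValueError("knot quantiles must be strictly increasing")


def rcs_basis(x: np.ndarray, spec: SplineSpec | None = None,
              knots: Sequence[float] | None = None) -> np.ndarray:
    """Natural (restricted) cubic spline basis: k knots -> k-1 columns.

    Column 0 is the covariate itself; the k-2 nonlinear columns use the
    truncated-power construction constrained to be linear beyond the
    boundary knots, scaled by the squared boundary-knot span.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        spec = spec or SplineSpec()
        knots = np.quantile(x, spec.quantiles)
    knots = np.asarray(sorted(knots), dtype=float)
    k = len(knots)
    if len(np.unique(knots)) < k:
        raise ValueError("fewer distinct covariate values than knots")
    scale = (knots[-1] - knots[0]) ** 2

    def d(j: int) -> np.ndarray:
        return np.maximum(x - knots[j], 0.0) ** 3

    cols = [x]
    denom = knots[-1] - knots[-2]
    for j in range(k - 2):
        col = (d(j)
               - d(k - 2) * (knots[-1] - knots[j]) / denom
               + d(k - 1) * (knots[-2] - knots[j]) / denom)
        cols.append(col / scale)
    return np.column_stack(cols)


@dataclass
class CoxFit:
    """Fitted left-truncated Cox model with its covariance and sample sizes."""

    params: pd.Series
    cov: pd.DataFrame
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    tie_method: str
    fitter: CoxPHFitter = field(repr=False)
    design: pd.DataFrame = field(repr=False)

    def wald_p(self, name: str) -> float:
        z = self.params[name] / np.sqrt(self.cov.loc[name, name])
        return float(2 * st.norm.sf(abs(z)))


def _expand_design(df: pd.DataFrame, covariates: Sequence[str],
                   spline_covariates: Sequence[str] = (),
                   spline_spec: SplineSpec | None = None) -> pd.DataFrame:
    """Dummy-code categoricals and spline-expand selected continuous columns."""
    cols = {}
    for c in covariates:
        s = df[c]
        if s.dtype == bool:
            cols[c] = s.astype(float)
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            for dc in dummies.columns:
                cols[dc] = dummies[dc]
        elif c in spline_covariates:
            # z-scale before the cubic expansion so the basis stays well
            # conditioned regardless of the covariate's raw units
            z = (s - s.mean()) / s.std(ddof=1)
            basis = rcs_basis(z.to_numpy(), spline_spec)
            cols[c] = pd.Series(basis[:, 0], index=df.index)
            for j in range(1, basis.shape[1]):
                cols[f"{c}_rcs{j}"] = pd.Series(basis[:, j], index=df.index)
        else:
            cols[c] = s.astype(float)
    out = pd.DataFrame(cols, index=df.index)
    constant = [c for c in out.columns if out[c].nunique() <= 1]
    if constant:
        raise ValueError(f"non-identifiable constant covariate(s): {constant}")
    return out


def fit_cox_left_truncated(
    records: pd.DataFrame,
    covariates: Sequence[str],
    entry_col: str = "entry_age",
    duration_col: str = "exit_age",
    event_col: str = "event",
    spline_covariates: Sequence[str] = (),
    spline_spec: SplineSpec | None = None,
) -> CoxFit:
    """Fit the Cox model with delayed entry (left truncation).

    Risk sets at time t contain subjects with ``entry < t <= exit``; ties are
    handled with the Efron correction.
    """
    if not records[event_col].astype(bool).any():
        raise ValueError("no events: the partial likelihood is undefined")
    if (records[entry_col] >= records[duration_col]).any():
        raise ValueError("every subject needs entry_age < exit_age")
    X = _expand_design(records, covariates, spline_covariates, spline_spec)
    data = pd.concat(
        [records[[entry_col, duration_col]],
         records[event_col].astype(bool), X], axis=1,
    )
    cph = CoxPHFitter()
    cph.fit(data, duration_col=duration_col, event_col=event_col,
            entry_col=entry_col, fit_options={"precision": 1e-9})
    ci = cph.confidence_intervals_
    return CoxFit(
        params=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        hazard_ratios=np.exp(cph.params_),
        ci_lower=np.exp(ci.iloc[:, 0]).rename("hr_lower_95"),
        ci_upper=np.exp(ci.iloc[:, 1]).rename("hr_upper_95"),
        log_likelihood=float(cph.log_likelihood_),
        n=len(data),
        n_events=int(data[event_col].sum()),
        tie_method="efron",
        fitter=cph,
        design=data,
    )


def quintile_trend_test(
    records: pd.DataFrame,
    quintile_col: str,
    score_col: str,
    covariates: Sequence[str],
    **fit_kwargs,
) -> tuple[float, CoxFit]:
    """Linear trend across quintiles via the quintile-median covariate.

    Each quintile is assigned its median score, which re-enters the model as
    a continuous variable; the returned p-value is the Wald p of that term.
    """
    med = records.groupby(quintile_col)[score_col].median()
    if med.nunique() == 1:
        raise ValueError("quintile medians are constant: trend unidentifiable")
    df = records.copy()
    df["quintile_median"] = df[quintile_col].map(med)
    fit = fit_cox_left_truncated(df, ["quintile_median", *covariates],
                                 **fit_kwargs)
    return fit.wald_p("quintile_median"), fit


def schoenfeld_residuals(fit: CoxFit) -> pd.DataFrame:
    """Schoenfeld residuals honouring left truncation.

    For each event at time t the residual is ``x_event - xbar(beta, t)``
    with the risk-weighted mean taken over subjects with
    ``entry < t <= exit``.  Tied events share the same risk-set mean.
    Rows are indexed by event time, ascending.
    """
    cols = list(fit.params.index)
    data = fit.design
    X = data[cols].to_numpy(dtype=float)
    entry = data.iloc[:, 0].to_numpy(dtype=float)   # entry col is first
    exit_t = data.iloc[:, 1].to_numpy(dtype=float)
    event = data.iloc[:, 2].to_numpy(dtype=bool)
    w = np.exp(X @ fit.params.to_numpy())

    def _suffix(keys: np.ndarray):
        order = np.argsort(keys, kind="stable")
        sk = keys[order]
        sw = np.concatenate([np.cumsum(w[order][::-1])[::-1], [0.0]])
        swx = np.vstack([
            np.cumsum((w[order, None] * X[order])[::-1], axis=0)[::-1],
            np.zeros((1, X.shape[1])),
        ])
        return sk, sw, swx

    ek, ew, ewx = _suffix(exit_t)    # sums over exit >= t
    nk, nw, nwx = _suffix(entry)     # sums over entry >= t
    times = exit_t[event]
    order = np.argsort(times, kind="stable")
    times = times[order]
    xe = X[event][order]
    ie = np.searchsorted(ek, times, side="left")
    ii = np.searchsorted(nk, times, side="left")
    s0 = ew[ie] - nw[ii]
    s1 = ewx[ie] - nwx[ii]
    resid = xe - s1 / s0[:, None]
    return pd.DataFrame(resid, index=pd.Index(times, name="event_time"),
                        columns=cols)


def proportional_hazards_test(fit: CoxFit,
                              transform: str = "rank") -> pd.DataFrame:
    """Grambsch-Therneau test on scaled Schoenfeld residuals.

    Regresses the Schoenfeld residuals on transformed event time; returns a
    per-covariate chi-squared (1 df) plus a global statistic (p df).  The
    ``transform`` is ``"rank"`` or ``"identity"``.
    """
    if fit.n_events < 2:
        raise ValueError("need at least 2 events for the diagnostic")
    resid = schoenfeld_residuals(fit)
    event_times = resid.index.to_numpy(dtype=float)
    if transform == "rank":
        g = st.rankdata(event_times)
    elif transform == "identity":
        g = event_times.copy()
    else:
        raise ValueError(f"unknown time transform {transform!r}")
    g = g - g.mean()
    s = resid.to_numpy()
    d = len(resid)
    V = fit.cov.to_numpy()
    denom = float(np.sum(g**2))
    z = s.T @ g
    # With scaled residuals s* = d * s V, the per-covariate statistic is
    # [sum_j g_j s*_jk]^2 / (d V_kk sum_j g_j^2) = d (V z)_k^2 / (V_kk sum g^2)
    # and the global statistic is z' V z * d / sum g^2 (chi-squared, p df).
    vz = V @ z
    rows = []
    for i, name in enumerate(fit.params.index):
        chi2_i = d * vz[i] ** 2 / (V[i, i] * denom)
        rows.append({"covariate": name, "chi2": float(chi2_i), "df": 1,
                     "p_value": float(st.chi2.sf(chi2_i, 1))})
    chi2_g = float(z @ V @ z) * d / denom
    rows.append({"covariate": "GLOBAL", "chi2": chi2_g, "df": len(z),
                 "p_value": float(st.chi2.sf(chi2_g, len(z)))})
    return pd.DataFrame(rows)


def compare_scores_cox(
    records: pd.DataFrame,
    score_a: str,
    score_b: str,
    covariates: Sequence[str],
    **fit_kwargs,
) -> dict:
    """One-model comparison: both standardized scores in a single Cox model.

    Returns each score's hazard ratio and the Wald test of coefficient
    equality, ``(b_a - b_b)^2 / (V_aa + V_bb - 2 V_ab)`` on 1 df.
    """
    corr = records[score_a].corr(records[score_b])
    if not np.isfinite(corr) or abs(corr) > 1 - 1e-10:
        raise ValueError("scores are collinear: comparison is unidentifiable")
    fit = fit_cox_left_truncated(records, [score_a, score_b, *covariates],
                                 **fit_kwargs)
    ba, bb = fit.params[score_a], fit.params[score_b]
    var = (fit.cov.loc[score_a, score_a] + fit.cov.loc[score_b, score_b]
           - 2 * fit.cov.loc[score_a, score_b])
    chi2 = (ba - bb) ** 2 / var
    return {
        "fit": fit,
        "hr_a": float(np.exp(ba)),
        "hr_b": float(np.exp(bb)),
        "p_a": fit.wald_p(score_a),
        "p_b": fit.wald_p(score_b),
        "equality_chi2": float(chi2),
        "equality_p": float(st.chi2.sf(chi2, 1)),
    }


def hr_table(fits: Mapping[str, CoxFit], exposure_rows: Mapping[str, str]
             ) -> pd.DataFrame:
    """Tidy hazard-ratio table: one row per exposure term of each fit."""
    rows = []
    for model, fit in fits.items():
        for label, term in exposure_rows.items():
            if term not in fit.params.index:
                continue
            rows.append({
                "model": model, "exposure": label,
                "hr": float(fit.hazard_ratios[term]),
                "hr_lower_95": float(fit.ci_lower[term]),
                "hr_upper_95": float(fit.ci_upper[term]),
                "p_value": fit.wald_p(term),
                "n": fit.n, "n_events": fit.n_events,
            })
    return pd.DataFrame(rows)
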