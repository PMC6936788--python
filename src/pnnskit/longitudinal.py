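"""Multilevel models of log(BMI) with serially correlated residuals.

The model for participant i at time t (years since baseline) is

    log BMI_it = x_it' beta + b0_i + b1_i t + e_it,
    (b0_i, b1_i) ~ N(0, G)  (unstructured 2x2),
    corr(e_is, e_it) = rho^|t - s|  (continuous-time first-order
    autocorrelation, the "spatial power" residual structure),

estimated by restricted maximum likelihood.  The fixed effects include the
standardized dietary score, time, their interaction, the adjustment
covariates, and optionally the second- and third-order interactions with
sex.  No installed mixed-model implementation combines random slopes with
residual autocorrelation, so the marginal likelihood is assembled per
participant and profiled over the residual variance; participants with equal
numbers of measures are batched so the REML criterion is evaluated with
stacked Cholesky factorizations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize as opt
import scipy.stats as st

#: Adjustment covariates of the base and full model variants.
M0_COVARIATES = ("sex", "age_at_inclusion", "log_eiwa", "n_records")
M1_COVARIATES = M0_COVARIATES + (
    "height", "month_of_inclusion", "physical_activity", "occupation",
    "smoking", "education", "income", "cohabiting",
)

RESIDUAL_STRUCTURES = ("ar1", "independent", "compound_symmetry")


@dataclass
class LmmFit:
    """REML fit: fixed effects with covariance plus variance components."""

    params: pd.Series
    cov: pd.DataFrame
    random_intercept_sd: float
    random_slope_sd: float
    random_effect_corr: float
    residual_sd: float
    residual_autocorr_rho: float
    structure: str
    neg2_restricted_loglik: float
    aic: float
    n_participants: int
    n_obs: int
    converged: bool
    score_terms: tuple[str, ...] = ()

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def wald_p(self, name: str) -> float:
        z = self.params[name] / self.se[name]
        return float(2 * st.norm.sf(abs(z)))

    def wald_equality_p(self, name_a: str, name_b: str) -> float:
        var = (self.cov.loc[name_a, name_a] + self.cov.loc[name_b, name_b]
               - 2 * self.cov.loc[name_a, name_b])
        chi2 = (self.params[name_a] - self.params[name_b]) ** 2 / var
        return float(st.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

def _batch_clusters(ids: np.ndarray):
    """Group row indices by participant, batched by cluster size."""
    order = np.argsort(ids, kind="stable")
    sorted_ids = ids[order]
    boundaries = np.flatnonzero(np.diff(sorted_ids)) + 1
    clusters = np.split(order, boundaries)
    by_size: dict[int, list[np.ndarray]] = {}
    for c in clusters:
        by_size.setdefault(len(c), []).append(c)
    return {m: np.vstack(cs) for m, cs in by_size.items()}, len(clusters)


class _RemlProblem:
    """Profiled REML criterion for one dataset, vectorized over clusters."""

    def __init__(self, y: np.ndarray, X: np.ndarray, ids: np.ndarray,
                 times: np.ndarray, structure: str = "ar1"):
        if structure not in RESIDUAL_STRUCTURES:
            raise ValueError(f"unknown residual structure {structure!r}")
        self.structure = structure
        self.n, self.p = X.shape
        batches, self.n_clusters = _batch_clusters(ids)
        self.batches = []
        for m, idx in batches.items():        # idx: (g, m) row indices
            t = times[idx]                    # (g, m)
            self.batches.append({
                "idx": idx,
                "t": t,
                "gaps": np.abs(t[:, :, None] - t[:, None, :]),
                "X": X[idx],                  # (g, m, p)
                "y": y[idx],                  # (g, m)
            })
        self.y, self.X = y, X

    #: large finite value in place of +inf so numerical gradients stay finite
    BAD = 1e12

    # theta layout: [a, b, c] log-chol of G/sigma^2, then rho-param if any
    def n_theta(self) -> int:
        return 3 if self.structure == "independent" else 4

    def _unpack(self, theta: np.ndarray):
        # clip so exploratory optimizer steps cannot overflow exp()
        a, b, c = np.clip(theta[:3], -40.0, 40.0)
        L = np.array([[math.exp(a), 0.0], [c, math.exp(b)]])
        G = L @ L.T
        rho = 0.0
        if self.structure != "independent":
            rho = 1.0 / (1.0 + math.exp(-min(theta[3], 40.0)))
        return G, rho

    def _correlation(self, batch: dict, rho: float) -> np.ndarray:
        m = batch["t"].shape[1]
        if self.structure == "ar1" and rho > 0:
            return rho ** batch["gaps"]
        if self.structure == "compound_symmetry":
            eye = np.eye(m)
            return eye + rho * (1 - eye)
        return np.broadcast_to(np.eye(m), batch["gaps"].shape).copy()

    def neg2_loglik(self, theta: np.ndarray, return_fit: bool = False,
                    method: str = "reml"):
        G, rho = self._unpack(theta)
        p = self.p
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        ytWy = 0.0
        logdet = 0.0
        pieces = []
        for batch in self.batches:
            t = batch["t"]                    # (g, m)
            W = (G[0, 0]
                 + G[0, 1] * (t[:, :, None] + t[:, None, :])
                 + G[1, 1] * t[:, :, None] * t[:, None, :]
                 + self._correlation(batch, rho))
            try:
                L = np.linalg.cholesky(W)
            except np.linalg.LinAlgError:
                return (self.BAD, None) if return_fit else self.BAD
            K = np.concatenate([batch["X"], batch["y"][:, :, None]], axis=2)
            A = np.linalg.solve(L, K)         # (g, m, p+1), whitened
            Ax, Ay = A[:, :, :p], A[:, :, p]
            XtWX += np.einsum("gmp,gmq->pq", Ax, Ax)
            XtWy += np.einsum("gmp,gm->p", Ax, Ay)
            ytWy += float(np.einsum("gm,gm->", Ay, Ay))
            logdet += 2.0 * float(np.log(np.diagonal(L, axis1=1, axis2=2)).sum())
            if return_fit:
                pieces.append((batch, W))
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return (self.BAD, None) if return_fit else self.BAD
        rss = ytWy - float(beta @ XtWy)
        dof = self.n - p if method == "reml" else self.n
        if rss <= 0:
            return (self.BAD, None) if return_fit else self.BAD
        sigma2 = rss / dof
        value = dof * math.log(sigma2) + logdet + dof * (1.0 + math.log(2.0 * math.pi))
        if method == "reml":
            sign, logdet_xtx = np.linalg.slogdet(XtWX)
            if sign <= 0:
                return (self.BAD, None) if return_fit else self.BAD
            value += logdet_xtx
        if not return_fit:
            return value
        cov_beta = sigma2 * np.linalg.inv(XtWX)
        return value, {
            "beta": beta, "cov_beta": cov_beta, "sigma2": sigma2,
            "G": sigma2 * G, "rho": rho,
        }


def _fit_reml(y, X, ids, times, structure="ar1", start=None,
              tol=1e-8, maxiter=500, method="reml"):
    problem = _RemlProblem(y, X, ids, times, structure)
    default = np.zeros(problem.n_theta())
    default[0] = math.log(2.0)       # random-intercept sd ~ 2x residual sd
    default[1] = math.log(0.2)

    def _minimize(x0):
        return opt.minimize(
            lambda th: problem.neg2_loglik(th, method=method),
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-6})

    res = _minimize(default if start is None else start)
    if start is not None and (not res.success or res.fun >= 1e10):
        # a degenerate warm start must not trap the fit; retry cold
        res_cold = _minimize(default)
        if res_cold.fun < res.fun:
            res = res_cold
    value, fit = problem.neg2_loglik(res.x, return_fit=True, method=method)
    if fit is None:
        raise RuntimeError("singular REML fit: variance profile degenerate")
    fit.update({"neg2_reml": value, "theta": res.x,
                "converged": bool(res.success),
                "n_theta": problem.n_theta(),
                "n_clusters": problem.n_clusters})
    return fit


# ---------------------------------------------------------------------------
# Model-facing API
# ---------------------------------------------------------------------------

def build_design(data: pd.DataFrame,
                 score_cols: Sequence[str],
                 covariates: Sequence[str],
                 time_col: str = "time",
                 include_sex_interactions: bool = True) -> pd.DataFrame:
    """Fixed-effects design: scores, time, score x time, covariates.

    Categorical covariates (object/bool dtype) are dummy-coded with the first
    level as reference.  When ``sex`` is among the covariates and
    ``include_sex_interactions`` is set, the score x sex, time x sex and
    score x time x sex terms are appended.
    """
    cols: dict[str, pd.Series] = {"intercept": pd.Series(1.0, index=data.index)}
    t = data[time_col].astype(float)
    for s_col in score_cols:
        cols[s_col] = data[s_col].astype(float)
    cols["time"] = t
    for s_col in score_cols:
        cols[f"{s_col}:time"] = data[s_col].astype(float) * t
    sex_ind = None
    for c in covariates:
        s = data[c]
        if c == "sex":
            sex_ind = (s == "male").astype(float)
            cols["sex_male"] = sex_ind
        elif s.dtype == bool:
            cols[c] = s.astype(float)
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            for dc, dv in pd.get_dummies(s, prefix=c, drop_first=True,
                                         dtype=float).items():
                cols[dc] = dv
        else:
            cols[c] = s.astype(float)
    if include_sex_interactions and sex_ind is not None:
        cols["time:sex_male"] = t * sex_ind
        for s_col in score_cols:
            cols[f"{s_col}:sex_male"] = data[s_col].astype(float) * sex_ind
            cols[f"{s_col}:time:sex_male"] = (
                data[s_col].astype(float) * t * sex_ind
            )
    X = pd.DataFrame(cols, index=data.index)
    constant = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant design column(s): {constant}")
    return X


def fit_logbmi_lmm(
    data: pd.DataFrame,
    score_cols: Sequence[str] | str = ("score_std",),
    model_set: str | None = "m0",
    covariates: Sequence[str] | None = None,
    time_col: str = "time",
    bmi_col: str = "bmi",
    id_col: str = "participant_id",
    include_sex_interactions: bool = True,
    structure: str = "ar1",
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 500,
    method: str = "reml",
) -> LmmFit:
    """Fit the log-BMI multilevel model by REML.

    ``model_set`` selects the adjustment set (``"m0"``/``"m1"``); an explicit
    ``covariates`` sequence overrides it (only covariates present in the data
    are used).  The outcome column may be BMI (log taken here) or already a
    log-BMI column named ``log_bmi``.
    """
    if isinstance(score_cols, str):
        score_cols = (score_cols,)
    if covariates is None:
        base = M0_COVARIATES if model_set in (None, "m0") else M1_COVARIATES
        covariates = [c for c in base if c in data.columns]
    if bmi_col == "log_bmi":
        y = data["log_bmi"].astype(float).to_numpy()
    else:
        bmi = data[bmi_col].astype(float).to_numpy()
        if np.any(bmi <= 0):
            raise ValueError("non-positive BMI cannot be log-transformed")
        y = np.log(bmi)
    X = build_design(data, score_cols, covariates, time_col,
                     include_sex_interactions)
    ids = pd.factorize(data[id_col])[0]
    times = data[time_col].astype(float).to_numpy()
    fit = _fit_reml(y, X.to_numpy(), ids, times, structure=structure,
                    start=start, tol=tol, maxiter=maxiter, method=method)
    G = fit["G"]
    ri_sd = math.sqrt(max(G[0, 0], 0.0))
    rs_sd = math.sqrt(max(G[1, 1], 0.0))
    corr = G[0, 1] / (ri_sd * rs_sd) if ri_sd > 0 and rs_sd > 0 else 0.0
    n_var_params = fit["n_theta"] + 1     # + profiled residual variance
    return LmmFit(
        params=pd.Series(fit["beta"], index=X.columns),
        cov=pd.DataFrame(fit["cov_beta"], index=X.columns, columns=X.columns),
        random_intercept_sd=ri_sd,
        random_slope_sd=rs_sd,
        random_effect_corr=float(corr),
        residual_sd=math.sqrt(fit["sigma2"]),
        residual_autocorr_rho=float(fit["rho"]),
        structure=structure,
        neg2_restricted_loglik=float(fit["neg2_reml"]),
        aic=float(fit["neg2_reml"] + 2 * n_var_params),
        n_participants=int(fit["n_clusters"]),
        n_obs=len(y),
        converged=fit["converged"],
        score_terms=tuple(score_cols),
    )


def bmi_multiplier(beta_score: float, beta_time: float,
                   beta_interaction: float,
                   delta_score_sd: float, years: float) -> float:
    """Multiplicative BMI change for a score shift sustained over time.

    Because the model is linear on log(BMI), a shift of ``delta_score_sd``
    standard deviations of score over ``years`` years multiplies BMI by
    ``exp(dS*b_score + t*b_time + t*dS*b_interaction)``.
    """
    return math.exp(delta_score_sd * beta_score + years * beta_time
                    + years * delta_score_sd * beta_interaction)


def compare_scores_lmm(
    data: pd.DataFrame,
    score_a: str,
    score_b: str,
    **fit_kwargs,
) -> dict:
    """One-model comparison: both standardized scores plus their time terms.

    Returns both coefficient pairs and two Wald equality p-values — baseline
    (score main effects) and slope (score x time interactions).
    """
    corr = data[score_a].corr(data[score_b])
    if not np.isfinite(corr) or abs(corr) > 1 - 1e-10:
        raise ValueError("scores are collinear: comparison is unidentifiable")
    fit = fit_logbmi_lmm(data, score_cols=(score_a, score_b), **fit_kwargs)
    return {
        "fit": fit,
        "beta_a": float(fit.params[score_a]),
        "beta_b": float(fit.params[score_b]),
        "beta_a_time": float(fit.params[f"{score_a}:time"]),
        "beta_b_time": float(fit.params[f"{score_b}:time"]),
        "baseline_equality_p": fit.wald_equality_p(score_a, score_b),
        "slope_equality_p": fit.wald_equality_p(f"{score_a}:time",
                                                f"{score_b}:time"),
    }


def compare_covariance_structures(data: pd.DataFrame, **fit_kwargs) -> dict:
    """AIC of the independent, AR(1) and compound-symmetry residual models."""
    out = {}
    for structure in RESIDUAL_STRUCTURES:
        fit = fit_logbmi_lmm(data, structure=structure, **fit_kwargs)
        out[structure] = fit.aic
    return out
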