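"""End-to-end study runner: simulate -> score -> prepare -> fit -> report.

Every stage reads and writes plain files inside a run directory, so a run is
reproducible from its config alone; ``manifest.json`` records the package
version, the seed, and a SHA-256 checksum of every artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import intake, longitudinal, scoring, survival, synthetic

DEFAULT_CONFIG = {
    "out_dir": "study_run",
    "simulation": {"n_participants": 1000, "seed": 0},
    "truth": {},
    "cohort": {
        "min_records": 3,
        "record_window_years": 2.0,
        "exclude_underreporters": False,
        "sensitivity": False,
        "thresholds": [25.0, 30.0],
    },
    "models": {
        "score": "pnns_gs2",
        "model_sets": ["m0", "m1"],
        "quintiles_by_sex": True,
        "spline_covariates": ["log_eiwa", "height", "physical_activity"],
        "residual_structure": "ar1",
        "include_sex_interactions": True,
    },
    "compare": [["pnns_gs2_std", "mpnns_gs1_std"],
                ["pnns_gs2_std", "spnns_gs2_std"],
                ["spnns_gs2_std", "mpnns_gs1_std"]],
}

COX_M0 = ["sex", "log_eiwa", "n_records"]
COX_M1 = COX_M0 + ["height", "month_of_inclusion", "physical_activity",
                   "occupation", "smoking", "education", "income", "cohabiting"]


def load_config(path: str | Path | None = None, overrides: dict | None = None
                ) -> dict:
    """Merge a YAML config file and overrides onto the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for source in (
        yaml.safe_load(Path(path).read_text()) if path is not None else None,
        overrides,
    ):
        if not source:
            continue
        for key, value in source.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _collapse_rare_levels(s: pd.Series, min_count: int) -> pd.Series:
    counts = s.value_counts()
    rare = counts[counts < min_count].index
    if len(rare) == 0:
        return s
    return s.where(~s.isin(rare), "pooled_rare")


class StudyRun:
    """A run directory with staged artifacts."""

    def __init__(self, config: dict, out_dir: str | Path | None = None):
        self.config = config
        self.dir = Path(out_dir or config["out_dir"])
        self.dir.mkdir(parents=True, exist_ok=True)

    def path(self, name: str) -> Path:
        return self.dir / name

    # ------------------------------------------------------------------ #
    def simulate(self) -> None:
        sim_cfg = synthetic.SimulationConfig(**self.config["simulation"])
        truth = synthetic.TrueParameters(**self.config.get("truth", {}))
        synthetic.generate_cohort(sim_cfg, truth, out_dir=self.dir)

    def score(self) -> None:
        def_file = self.config.get("scoring", {}).get("definitions_file")
        if def_file is not None and not Path(def_file).exists():
            raise FileNotFoundError(
                f"score definitions file not found: {def_file!r}")
        defs = scoring.load_definitions(def_file)
        records = pd.read_csv(self.path("records.csv"), parse_dates=["date"])
        organic = pd.read_csv(self.path("organic.csv"))
        participants = pd.read_csv(self.path("participants.csv"),
                                   parse_dates=["inclusion_date"])
        inputs = intake.build_scoring_inputs(records, organic, participants)
        intake.scoring_inputs_to_frame(inputs).to_csv(
            self.path("scoring_input.csv"), index=False)
        panel = scoring.standardize_panel(scoring.score_panel(inputs, defs))
        panel.to_csv(self.path("scores.csv"), index=False)

    def prepare(self) -> None:
        cfg = self.config["cohort"]
        bad = [t for t in cfg["thresholds"] if float(t) not in (25.0, 30.0, 40.0)]
        if bad:
            raise ValueError(
                f"BMI thresholds must be 25, 30 or 40 kg/m^2, got {bad}")
        participants = pd.read_csv(self.path("participants.csv"),
                                   parse_dates=["inclusion_date"])
        records = pd.read_csv(self.path("records.csv"), parse_dates=["date"])
        anthro = pd.read_csv(self.path("anthro.csv"))
        panel = pd.read_csv(self.path("scores.csv"))
        rules = cohort_mod.SelectionRules(
            min_records=cfg["min_records"],
            record_window_years=cfg["record_window_years"],
            exclude_underreporters=cfg["exclude_underreporters"],
            sensitivity=cfg["sensitivity"],
        )
        working, log = cohort_mod.select_working_sample(
            participants, records, anthro, rules)
        score_col = self.config["models"]["score"]
        working = working.merge(
            panel[["participant_id", score_col, f"{score_col}_std"]],
            on="participant_id",
        )
        offsets = cohort_mod.baseline_offsets(
            records[records["participant_id"].isin(working["participant_id"])],
            working,
        )
        working["baseline_offset_years"] = working["participant_id"].map(offsets)
        working["quintile"] = cohort_mod.assign_quintiles(
            working, score_col,
            by_sex=self.config["models"]["quintiles_by_sex"],
        )
        scoring_inp = pd.read_csv(self.path("scoring_input.csv"))
        working = working.merge(
            scoring_inp[["participant_id", "eiwa_kcal_per_day"]],
            on="participant_id",
        )
        working["log_eiwa"] = np.log(working["eiwa_kcal_per_day"])
        working["n_records"] = working["participant_id"].map(
            records.groupby("participant_id").size())
        working.to_csv(self.path("working_sample.csv"), index=False)

        survival_logs = {}
        for thr in cfg["thresholds"]:
            table, ex_log = cohort_mod.build_survival_table(
                anthro[anthro["participant_id"].isin(working["participant_id"])],
                working, offsets, float(thr))
            table.to_csv(self.path(f"survival_{int(thr)}.csv"), index=False)
            survival_logs[str(int(thr))] = ex_log
        self.path("exclusion_log.json").write_text(
            json.dumps({"working_sample": log, "survival": survival_logs},
                       indent=2))

        tests = cohort_mod.descriptive_association_tests(
            working, "quintile",
            {"sex": "binary", "cohabiting": "binary",
             "education": "ordered", "income": "ordered",
             "smoking": "unordered", "occupation": "unordered",
             "age_at_inclusion": "numeric", "physical_activity": "numeric",
             "eiwa_kcal_per_day": "numeric"},
        )
        tests.to_csv(self.path("descriptive_table.csv"), index=False)

    # ------------------------------------------------------------------ #
    def _cox_inputs(self, threshold: float) -> pd.DataFrame:
        working = pd.read_csv(self.path("working_sample.csv"))
        surv = pd.read_csv(self.path(f"survival_{int(threshold)}.csv"))
        score_col = self.config["models"]["score"]
        df = surv.merge(working, on="participant_id")
        df = df.rename(columns={f"{score_col}_std": "score_std",
                                score_col: "score_raw"})
        # sparse factor levels destabilise the partial likelihood; pool them
        for c in ("occupation", "smoking", "education", "income",
                  "month_of_inclusion"):
            if c in df.columns:
                df[c] = _collapse_rare_levels(df[c].astype(str), min_count=10)
        return df

    def _available(self, df: pd.DataFrame, covariates: list[str]) -> list[str]:
        usable = []
        for c in covariates:
            if c in df.columns and df[c].nunique() > 1:
                usable.append(c)
        return usable

    def fit_cox(self) -> None:
        mcfg = self.config["models"]
        results, hr_frames = {}, []
        for thr in self.config["cohort"]["thresholds"]:
            df = self._cox_inputs(float(thr))
            if len(df) == 0 or not df["event"].any():
                continue
            for model_set, base in (("m0", COX_M0), ("m1", COX_M1)):
                if model_set not in mcfg["model_sets"]:
                    continue
                covs = self._available(df, base)
                splines = [c for c in mcfg["spline_covariates"] if c in covs]
                key = f"threshold_{int(thr)}_{model_set}"
                fits, notes = {}, {}
                events_by_q = df.groupby("quintile")["event"].sum()
                quintiles_ok = (events_by_q > 0).all()
                if not quintiles_ok:
                    notes["quintile"] = (
                        "skipped: zero events in at least one quintile")
                for form, frame, terms in (
                    ("per_point", df, ["score_raw"]),
                    ("per_sd", df, ["score_std"]),
                ):
                    fits[form] = survival.fit_cox_left_truncated(
                        frame, terms + covs, spline_covariates=splines)
                if quintiles_ok:
                    qd = pd.get_dummies(df["quintile"].astype(int),
                                        prefix="Q", dtype=float)
                    dq = pd.concat([df, qd.drop(columns=["Q_1"])], axis=1)
                    q_terms = [c for c in dq.columns if c.startswith("Q_")
                               and c != "Q_1"]
                    try:
                        fits["quintile"] = survival.fit_cox_left_truncated(
                            dq, q_terms + covs, spline_covariates=splines)
                    except Exception as exc:   # sparse-stratum convergence
                        notes["quintile"] = f"failed: {exc}"
                trend_p = None
                if quintiles_ok:
                    trend_p, _ = survival.quintile_trend_test(
                        df, "quintile", "score_raw", covs)
                ph = survival.proportional_hazards_test(fits["per_sd"])
                results[key] = {
                    "trend_p": trend_p,
                    "ph_global_p": float(
                        ph.loc[ph["covariate"] == "GLOBAL", "p_value"].iloc[0]),
                    "n": fits["per_sd"].n,
                    "n_events": fits["per_sd"].n_events,
                    "notes": notes,
                    "coefficients": {
                        form: {"params": f.params.to_dict(),
                               "cov": f.cov.to_dict()}
                        for form, f in fits.items()
                    },
                }
                tab = survival.hr_table(
                    {key: fits["per_point"]}, {"per_point": "score_raw"})
                tab = pd.concat([tab, survival.hr_table(
                    {key: fits["per_sd"]}, {"per_sd": "score_std"})])
                if "quintile" in fits:
                    tab = pd.concat([survival.hr_table(
                        {key: fits["quintile"]},
                        {f"Q{q}": f"Q_{q}" for q in (2, 3, 4, 5)}), tab])
                hr_frames.append(tab)
        self.path("cox_results.json").write_text(json.dumps(results, indent=2))
        if hr_frames:
            pd.concat(hr_frames, ignore_index=True).to_csv(
                self.path("hr_table.csv"), index=False)

    # ------------------------------------------------------------------ #
    def _lmm_inputs(self) -> pd.DataFrame:
        working = pd.read_csv(self.path("working_sample.csv"))
        anthro = pd.read_csv(self.path("anthro.csv"))
        df = anthro.merge(working, on="participant_id")
        df["time"] = df["time_years"] - df["baseline_offset_years"]
        score_col = self.config["models"]["score"]
        df = df.rename(columns={f"{score_col}_std": "score_std"})
        df["month_of_inclusion"] = df["month_of_inclusion"].astype(str)
        return df

    def fit_lmm(self) -> None:
        mcfg = self.config["models"]
        df = self._lmm_inputs()
        results = {}
        for model_set in mcfg["model_sets"]:
            base = (longitudinal.M0_COVARIATES if model_set == "m0"
                    else longitudinal.M1_COVARIATES)
            covs = self._available(df, list(base))
            fit = longitudinal.fit_logbmi_lmm(
                df, score_cols=("score_std",), covariates=covs,
                structure=mcfg["residual_structure"],
                include_sex_interactions=mcfg["include_sex_interactions"],
            )
            results[model_set] = {
                "fixed_effects": fit.params.to_dict(),
                "se": fit.se.to_dict(),
                "p": {k: fit.wald_p(k) for k in fit.params.index},
                "random_intercept_sd": fit.random_intercept_sd,
                "random_slope_sd": fit.random_slope_sd,
                "random_effect_corr": fit.random_effect_corr,
                "residual_sd": fit.residual_sd,
                "rho": fit.residual_autocorr_rho,
                "aic": fit.aic,
                "n_participants": fit.n_participants,
                "n_obs": fit.n_obs,
                "bmi_multiplier_2sd_5y": longitudinal.bmi_multiplier(
                    fit.params["score_std"], fit.params["time"],
                    fit.params["score_std:time"], 2.0, 5.0),
            }
        self.path("lmm_results.json").write_text(json.dumps(results, indent=2))
        rows = []
        for model_set, res in results.items():
            for label, term in (("score_1sd", "score_std"), ("time", "time"),
                                ("score_x_time", "score_std:time")):
                rows.append({
                    "model": model_set, "term": label,
                    "beta": res["fixed_effects"][term],
                    "se": res["se"][term], "p_value": res["p"][term],
                })
        pd.DataFrame(rows).to_csv(self.path("lmm_table.csv"), index=False)

    def compare(self) -> None:
        pairs = self.config.get("compare", [])
        panel = pd.read_csv(self.path("scores.csv"))
        working = pd.read_csv(self.path("working_sample.csv"))
        df_l = self._lmm_inputs().merge(
            panel[["participant_id"] + sorted({c for p in pairs for c in p})],
            on="participant_id")
        out = {"lmm": {}, "cox": {}}
        covs_l = self._available(df_l, list(longitudinal.M1_COVARIATES))
        for a, b in pairs:
            res = longitudinal.compare_scores_lmm(
                df_l, a, b, covariates=covs_l,
                include_sex_interactions=self.config["models"][
                    "include_sex_interactions"],
            )
            out["lmm"][f"{a}_vs_{b}"] = {
                k: v for k, v in res.items() if k != "fit"}
        for thr in self.config["cohort"]["thresholds"]:
            df_c = self._cox_inputs(float(thr)).merge(
                panel[["participant_id"]
                      + sorted({c for p in pairs for c in p})],
                on="participant_id")
            covs_c = self._available(df_c, COX_M1)
            for a, b in pairs:
                res = survival.compare_scores_cox(df_c, a, b, covs_c)
                out["cox"][f"threshold_{int(thr)}_{a}_vs_{b}"] = {
                    k: v for k, v in res.items() if k != "fit"}
        self.path("comparison_results.json").write_text(
            json.dumps(out, indent=2))

    # ------------------------------------------------------------------ #
    def report(self) -> str:
        required = ["descriptive_table.csv", "hr_table.csv", "lmm_table.csv"]
        missing = [f for f in required if not self.path(f).exists()]
        if missing:
            raise FileNotFoundError(f"incomplete run, missing: {missing}")
        lines = ["# Study report", ""]
        lines += ["## Baseline associations across score quintiles", ""]
        lines.append(pd.read_csv(self.path("descriptive_table.csv"))
                     .to_string(index=False))
        lines += ["", "## Hazard ratios", ""]
        lines.append(pd.read_csv(self.path("hr_table.csv")).to_string(index=False))
        lines += ["", "## Longitudinal log-BMI model", ""]
        lines.append(pd.read_csv(self.path("lmm_table.csv")).to_string(index=False))
        if self.path("comparison_results.json").exists():
            lines += ["", "## One-model score comparisons", ""]
            lines.append(self.path("comparison_results.json").read_text())
        text = "\n".join(lines) + "\n"
        self.path("report.md").write_text(text)
        return text

    def write_manifest(self) -> dict:
        from . import __version__
        artifacts = sorted(p.name for p in self.dir.iterdir()
                           if p.is_file() and p.name != "manifest.json")
        manifest = {
            "package_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config": self.config,
            "checksums": {name: _sha256(self.path(name)) for name in artifacts},
        }
        self.path("manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def run_study(config: dict | str | Path | None = None,
              out_dir: str | Path | None = None) -> StudyRun:
    """Execute every stage in order and write the manifest."""
    cfg = config if isinstance(config, dict) else load_config(config)
    run = StudyRun(cfg, out_dir)
    for stage in ("simulate", "score", "prepare", "fit_cox", "fit_lmm",
                  "compare"):
        try:
            getattr(run, stage)()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    run.report()
    run.write_manifest()
    return run
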