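"""Config-driven pipeline: generate/load -> harmonize -> impute -> score ->
classify -> model -> report.

Stages mirror the analysis flow of a biological-aging / multimorbidity
cohort study: biological-age scores and acceleration residuals on the full
cohort; cross-sectional logistic models of baseline state; Cox models of
incident disorder, multimorbidity and death in the baseline disorder-free
subset; an interval-censored multistate model; and Royston-Parmar life
expectancy by baseline state.  Every exclusion step is counted so that
retained + excluded = input rows at each stage.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, bioage, cohort, life_expectancy, multistate, preprocess, states

DEFAULT_ADJUSTMENT = [
    "chronological_age", "is_female", "is_white", "bmi_category", "smoking",
    "alcohol", "diet_score", "physical_activity", "townsend", "income",
    "no2", "nox", "pm25", "pm10",
]

DEFAULT_IMPUTE_STRATEGIES = {
    "education": "ordered_logistic",
    "income": "ordered_logistic",
    "townsend": "multivariate_normal_bounded",
    "physical_activity": "mean_substitution",
    "diet_score": "mean_substitution",
    "no2": "mean_substitution",
    "nox": "mean_substitution",
    "pm25": "mean_substitution",
    "pm10": "mean_substitution",
    "smoking": "mean_substitution",
    "alcohol": "mean_substitution",
    "bmi_category": "mean_substitution",
}


@dataclass
class PipelineConfig:
    """What to run and how; see the CLI for the file-based interface."""

    generator: cohort.GeneratorConfig | None = None
    input_csv: str | None = None
    unit_map: dict | None = None
    metrics: tuple = ("kdm", "phenoage")
    model_blocks: tuple = ("logistic", "cox", "multistate", "life_expectancy")
    m_imputations: int = 20
    no_impute: bool = False
    landmark_years: float = 0.0
    seed: int = 0
    out_dir: str | None = None
    n_ci_draws: int = 400
    rcs_dose_response: bool = True

    def validate(self) -> None:
        if self.generator is None and self.input_csv is None:
            raise ValueError("config needs a generator config or an input CSV path")
        if not self.model_blocks:
            raise ValueError("at least one model block must be enabled")
        unknown = set(self.model_blocks) - {"logistic", "cox", "multistate", "life_expectancy"}
        if unknown:
            raise ValueError(f"unknown model blocks: {sorted(unknown)}")
        for m in self.metrics:
            if m not in ("kdm", "phenoage") and not m.startswith("custom:"):
                raise ValueError(f"unknown metric {m!r}")


def _load_table(config: PipelineConfig) -> pd.DataFrame:
    if config.generator is not None:
        return cohort.generate_cohort(config.generator)
    return pd.read_csv(config.input_csv)


def score_cohort(table: pd.DataFrame, metrics=("kdm", "phenoage"),
                 unit_map: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Attach biological-age scores, acceleration residuals, accelerated
    flags and quartiles for each requested metric; returns the scored table
    and the exclusion accounting."""
    report = {"n_input": len(table)}
    if unit_map:
        table, prov = preprocess.harmonize_units(table, unit_map)
        report["unit_transforms"] = prov
    out = table.copy()
    score_cols = []
    for metric in metrics:
        if metric == "kdm":
            est = bioage.KlemeraDoubalAge().fit(out)
            out["kdm_ba"] = est.predict(out)
            score_cols.append("kdm_ba")
        elif metric == "phenoage":
            out["phenoage"] = bioage.PhenoAge().fit().predict(out)
            score_cols.append("phenoage")
        else:
            col = metric.split(":", 1)[1]
            if col not in out.columns:
                raise ValueError(f"custom exposure column {col!r} absent")
            score_cols.append(col)

    # exclusions mirroring the score-availability and 5-SD rules
    has_scores = out[score_cols].notna().all(axis=1)
    report["n_missing_scores"] = int((~has_scores).sum())
    out = out[has_scores].copy()
    extreme = np.zeros(len(out), bool)
    for c in score_cols:
        extreme |= bioage.flag_extreme(out[c].to_numpy(float))
    report["n_extreme_5sd"] = int(extreme.sum())
    out = out[~extreme].copy()
    report["n_scored"] = len(out)

    ca = out["chronological_age"].to_numpy(float)
    for metric, col in zip(metrics, score_cols):
        tag = {"kdm": "kdm", "phenoage": "phenoage"}.get(metric, col)
        if metric.startswith("custom:"):
            # generic exposure passthrough: standardize only
            v = out[col].to_numpy(float)
            out[f"{tag}_accel"] = v - np.nanmean(v)
            out[f"{tag}_accel_sd"] = out[f"{tag}_accel"] / np.nanstd(v, ddof=1)
            out[f"{tag}_accelerated"] = out[f"{tag}_accel"] > 0
        else:
            acc = bioage.compute_acceleration(out[col].to_numpy(float), ca)
            out[f"{tag}_accel"] = acc["residual"].to_numpy()
            out[f"{tag}_accel_sd"] = acc["residual_sd"].to_numpy()
            out[f"{tag}_accelerated"] = acc["accelerated"].to_numpy()
        out[f"{tag}_quartile"] = bioage.assign_quartiles(out[f"{tag}_accel"].to_numpy())
    return out, report


def _metric_tag(metric: str) -> str:
    return metric.split(":", 1)[1] if metric.startswith("custom:") else metric


def _covariate_frame(table: pd.DataFrame, drop=("chronological_age",)) -> pd.DataFrame:
    t = table.copy()
    t["is_female"] = (t["sex"] == "female").astype(float)
    t["is_white"] = (t.get("ethnicity", "white") == "white").astype(float)
    cols = [c for c in DEFAULT_ADJUSTMENT if c in t.columns and c not in drop]
    return t[cols].astype(float)


def impute_covariates(table: pd.DataFrame, m: int, seed: int) -> list[pd.DataFrame]:
    strategies = {c: s for c, s in DEFAULT_IMPUTE_STRATEGIES.items()
                  if c in table.columns and table[c].isna().any()}
    if not strategies:
        return [table.copy() for _ in range(m)]
    spec = preprocess.ImputationSpec(
        m=m, strategies=strategies,
        bounds={"townsend": (-10.0, 15.0)},
        predictors=["chronological_age"], seed=seed)
    spec.bounds = {c: b for c, b in spec.bounds.items() if c in strategies}
    return preprocess.impute(table, spec)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run report and
    persists artifacts under ``config.out_dir`` when set."""
    config.validate()
    t_start = time.time()
    report = {"seed": config.seed, "stages": {}, "exclusions": {}}
    artifacts = {}

    stage = "load"
    try:
        table = _load_table(config)
        report["exclusions"]["input_rows"] = len(table)

        stage = "score"
        scored, score_rep = score_cohort(table, config.metrics, config.unit_map)
        report["exclusions"].update({
            "missing_scores": score_rep["n_missing_scores"],
            "extreme_5sd": score_rep["n_extreme_5sd"],
            "scored": score_rep["n_scored"],
        })
        artifacts["scored"] = scored

        stage = "impute"
        if config.no_impute:
            complete = scored.dropna(subset=[c for c in DEFAULT_IMPUTE_STRATEGIES
                                             if c in scored.columns])
            imputed = [complete.reset_index(drop=True)]
            report["stages"]["impute"] = {"mode": "complete_cases", "n": len(complete)}
        else:
            imputed = impute_covariates(scored.reset_index(drop=True),
                                        config.m_imputations, config.seed)
            report["stages"]["impute"] = {"mode": "multiple_imputation",
                                          "m": len(imputed)}

        stage = "states"
        timelines = [states.build_timeline(row) for _, row in scored.iterrows()]
        if config.landmark_years > 0:
            before = len(timelines)
            timelines = states.landmark_exclude(timelines, config.landmark_years)
            report["exclusions"]["landmark_excluded"] = before - len(timelines)
            kept = {tl.id for tl in timelines}
            scored = scored[scored["id"].isin(kept)]
            imputed = [t[t["id"].isin(kept)] for t in imputed]
        baseline_state = pd.Series(
            {tl.id: int(tl.baseline_state) for tl in timelines}, name="baseline_state")
        scored = scored.merge(baseline_state, left_on="id", right_index=True)
        panel, panel_rep = states.make_panel(timelines)
        report["exclusions"]["none_to_death_excluded"] = panel_rep["n_excluded_none_to_death"]

        results = {}
        for metric in config.metrics:
            tag = _metric_tag(metric)
            mres = {}
            if "logistic" in config.model_blocks:
                stage = f"logistic[{tag}]"
                mres["logistic"] = _logistic_block(scored, imputed, tag)
            if "cox" in config.model_blocks:
                stage = f"cox[{tag}]"
                mres["cox"] = _cox_block(scored, imputed, tag, config)
            if "multistate" in config.model_blocks:
                stage = f"multistate[{tag}]"
                mres["multistate"] = _multistate_block(scored, panel, tag)
            if "life_expectancy" in config.model_blocks:
                stage = f"life_expectancy[{tag}]"
                mres["life_expectancy"] = _le_block(scored, tag, config)
            results[tag] = mres
        artifacts["results"] = results

        report["runtime_s"] = round(time.time() - t_start, 2)
        report["status"] = "ok"
    except Exception as err:
        report["status"] = "error"
        report["failed_stage"] = stage
        report["error"] = str(err)
        if config.out_dir:
            _persist(config, report, artifacts)
        raise

    if config.out_dir:
        _persist(config, report, artifacts)
    return {"report": report, "artifacts": artifacts}


# --------------------------------------------------------------------------
# Model blocks
# --------------------------------------------------------------------------

def _pool_or_single(fit_fn, datasets):
    fits = [fit_fn(t) for t in datasets]
    if len(fits) == 1:
        return fits[0].summary.assign(ratio=np.exp(fits[0].summary["estimate"]),
                                      ratio_low=np.exp(fits[0].summary["ci_low"]),
                                      ratio_high=np.exp(fits[0].summary["ci_high"]))
    return assoc.pool_fits(fits)


def _logistic_block(scored, imputed, tag):
    """Baseline prevalence of single disorder and of dual-or-worse vs the
    acceleration exposure, per SD and by quartile."""
    out = {}
    base = scored.set_index("id")["baseline_state"]
    for outcome_name, pos_states in (("single", [2]), ("dual_plus", [3, 4])):
        ref_states = [1]
        keep_states = ref_states + pos_states
        for coding in ("per_sd", "quartile"):
            def fit_one(t):
                t = t.merge(base, left_on="id", right_index=True) \
                    if "baseline_state" not in t.columns else t
                sub = t[t["baseline_state"].isin(keep_states)]
                y = sub["baseline_state"].isin(pos_states).astype(float)
                expo = (sub[f"{tag}_accel_sd"] if coding == "per_sd"
                        else sub[f"{tag}_quartile"])
                return assoc.fit_logistic(y.reset_index(drop=True),
                                          expo.reset_index(drop=True),
                                          _covariate_frame(sub, drop=("chronological_age", tag)))
            out[f"{outcome_name}_{coding}"] = _pool_or_single(fit_one, imputed)
    return out


def _incident_outcomes(t):
    """Follow-up outcomes among the baseline disorder-free: time-to first
    disorder, time-to dual-or-worse, and death."""
    base_free = t[t["baseline_state"] == 1].copy()
    onset_cols = [f"onset_age_{d}" for d in states.DOMAINS]
    onsets = base_free[onset_cols].to_numpy(float)
    baseline = base_free["chronological_age"].to_numpy(float)
    later = np.where(np.isfinite(onsets) & (onsets > baseline[:, None]), onsets, np.inf)
    later.sort(axis=1)
    first, second = later[:, 0], later[:, 1]
    death = base_free["death_age"].to_numpy(float)
    censor = base_free["censor_age"].to_numpy(float)
    end = np.where(np.isfinite(death), np.minimum(death, censor), censor)
    return base_free, {
        "single": (np.minimum(first, end) - baseline, (first <= end).astype(int)),
        "dual_plus": (np.minimum(second, end) - baseline, (second <= end).astype(int)),
        "death": (end - baseline, (np.isfinite(death) & (death <= censor)).astype(int)),
    }


def _cox_block(scored, imputed, tag, config):
    out = {}
    for coding in ("per_sd", "quartile"):
        for outcome in ("single", "dual_plus", "death"):
            def fit_one(t):
                if "baseline_state" not in t.columns:
                    t = t.merge(scored.set_index("id")["baseline_state"],
                                left_on="id", right_index=True)
                sub, outcomes = _incident_outcomes(t)
                time_, event = outcomes[outcome]
                keep = time_ > 0
                expo = (sub[f"{tag}_accel_sd"] if coding == "per_sd"
                        else sub[f"{tag}_quartile"])
                return assoc.fit_cox(pd.Series(time_[keep]),
                                     pd.Series(event[keep]),
                                     expo[keep].reset_index(drop=True),
                                     _covariate_frame(sub[keep], drop=(tag,)))
            out[f"{outcome}_{coding}"] = _pool_or_single(fit_one, imputed)

        # overall mortality on the full cohort, baseline hazard stratified by
        # baseline state (the well-powered mortality design)
        def fit_death_all(t):
            if "baseline_state" not in t.columns:
                t = t.merge(scored.set_index("id")["baseline_state"],
                            left_on="id", right_index=True)
            death = t["death_age"].to_numpy(float)
            censor = t["censor_age"].to_numpy(float)
            baseline = t["chronological_age"].to_numpy(float)
            end = np.where(np.isfinite(death), np.minimum(death, censor), censor)
            event = (np.isfinite(death) & (death <= censor)).astype(int)
            keep = end > baseline
            expo = (t[f"{tag}_accel_sd"] if coding == "per_sd"
                    else t[f"{tag}_quartile"])
            return assoc.fit_cox(pd.Series(end[keep] - baseline[keep]),
                                 pd.Series(event[keep]),
                                 expo[keep].reset_index(drop=True),
                                 _covariate_frame(t[keep], drop=(tag,)),
                                 strata=t.loc[keep, "baseline_state"].values)
        out[f"death_all_states_{coding}"] = _pool_or_single(fit_death_all, imputed)
    if config.rcs_dose_response:
        sub, outcomes = _incident_outcomes(
            imputed[0].merge(scored.set_index("id")["baseline_state"],
                             left_on="id", right_index=True)
            if "baseline_state" not in imputed[0].columns else imputed[0])
        time_, event = outcomes["single"]
        keep = time_ > 0
        x = sub[f"{tag}_accel_sd"].to_numpy(float)[keep]
        knots = assoc.default_knots(x)
        X = assoc.rcs_frame(x, knots)
        fit = assoc.fit_cox(pd.Series(time_[keep]), pd.Series(event[keep]), X,
                            _covariate_frame(sub[keep], drop=(tag,)))
        grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), 41)
        out["dose_response"] = assoc.dose_response_curve(
            fit, knots, grid, reference_value=0.0,
            data_range=(x.min(), x.max()))
    return out


def _multistate_block(scored, panel, tag):
    cov = scored[["id", "chronological_age", f"{tag}_accel_sd"]].copy()
    cov["is_female"] = (scored["sex"] == "female").astype(float)
    cov["age_c"] = (cov["chronological_age"] - cov["chronological_age"].mean()) / 10.0
    cov = cov.rename(columns={f"{tag}_accel_sd": "accel_sd"})
    panel_m = panel[panel["id"].isin(cov["id"])]
    est = multistate.MultistateMarkov(
        covariates=("is_female", "age_c", "accel_sd")).fit(panel_m, cov)
    hr = est.model_.hazard_ratios()
    return {"model": est.model_, "hr_table": hr,
            "accel_hr": hr[hr["term"] == "accel_sd"].set_index("transition")}


def _le_block(scored, tag, config):
    entry = scored["chronological_age"].to_numpy(float)
    death = scored["death_age"].to_numpy(float)
    censor = scored["censor_age"].to_numpy(float)
    exit_ = np.where(np.isfinite(death), np.minimum(death, censor), censor)
    event = (np.isfinite(death) & (death <= censor)).astype(int)
    grp = pd.get_dummies(scored["baseline_state"].map(
        {1: "none", 2: "single", 3: "dual", 4: "triple"}))
    Z = pd.DataFrame({
        "is_female": (scored["sex"] == "female").astype(float),
        "accelerated": scored[f"{tag}_accelerated"].astype(float),
    })
    for g in ("single", "dual", "triple"):
        Z[f"state_{g}"] = grp.get(g, 0.0)
    ok = exit_ > entry
    rp = life_expectancy.RoystonParmar(df=4).fit(entry[ok], exit_[ok], event[ok], Z[ok])
    groups = {}
    zbase = np.zeros(Z.shape[1])
    zbase[0] = float(Z["is_female"].mean())
    for name in ("none", "single", "dual", "triple"):
        z = zbase.copy()
        if name != "none":
            z[list(Z.columns).index(f"state_{name}")] = 1.0
        groups[name] = z
    table = life_expectancy.le_table(rp.fit_, groups, ages=np.arange(45.0, 100.0, 5.0),
                                     referent="none", n_draws=config.n_ci_draws,
                                     seed=config.seed)
    return {"fit": rp.fit_, "table": table}


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def _persist(config: PipelineConfig, report: dict, artifacts: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    if "scored" in artifacts:
        artifacts["scored"].to_csv(out / "scored_cohort.csv", index=False)
    for tag, blocks in artifacts.get("results", {}).items():
        for block, res in blocks.items():
            if isinstance(res, dict):
                for key, obj in res.items():
                    if isinstance(obj, pd.DataFrame):
                        obj.to_csv(out / f"{tag}_{block}_{key}.csv", index=False)
            elif isinstance(res, pd.DataFrame):
                res.to_csv(out / f"{tag}_{block}.csv", index=False)


def load_pipeline_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    gen = raw.pop("generator", None)
    cfg = PipelineConfig(**raw)
    if gen is not None:
        if isinstance(gen, dict):
            cfg.generator = cohort.default_config(**gen)
        else:
            cfg.generator = gen
    cfg.validate()
    return cfg
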