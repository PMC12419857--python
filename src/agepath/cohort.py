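"""Seeded synthetic cohort generator.

Emulates the statistical structure a biological-aging / multimorbidity
analysis assumes: age- and sex-dependent biomarker means with residual
noise, a single latent frailty factor shared between biomarkers and disease
progression (which is what makes biological-age acceleration prognostic),
proportional-intensity disorder progression over the illness-death graph
none -> single -> dual -> triple with per-state death exits, Gompertz
age-dependent mortality, and realistic covariate missingness.

Disease histories are simulated by competing exponential clocks refreshed
at every jump; the Gompertz death intensity is approximated as
piecewise-constant on 1-year age segments (evaluated at the segment
midpoint).  Participants are disease-free at ``process_start_age``; their
pre-baseline history yields baseline-prevalent states, and death is only
enabled from the baseline age onwards (enrolment implies survival to
baseline).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .states import DOMAINS

STATE_NAMES = {1: "none", 2: "single", 3: "dual", 4: "triple", 5: "death"}
ALLOWED_EDGES = (
    "none->single", "single->dual", "dual->triple",
    "single->death", "dual->death", "triple->death",
)
PROTECTED_COLUMNS = frozenset(
    {"id", "chronological_age", "sex", "death_age", "censor_age"}
    | {f"onset_age_{d}" for d in DOMAINS}
)


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n_participants: int
    seed: int
    age_range: tuple
    sex_ratio: float
    biomarker_models: dict
    frailty_sd: float
    transition_log_intensities: dict
    transition_frailty_loghr: dict
    gompertz_mortality: dict
    followup_years: float
    missingness_rates: dict = field(default_factory=dict)
    missingness_mechanism: str = "mcar"
    process_start_age: float = 25.0

    def validate(self) -> None:
        def bad(name, msg):
            raise ConfigurationError(f"invalid config field {name!r}: {msg}")

        if self.n_participants <= 0:
            bad("n_participants", "must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            bad("sex_ratio", "must be in [0, 1]")
        lo, hi = self.age_range
        if not 0 < lo < hi:
            bad("age_range", "need 0 < low < high")
        if self.followup_years <= 0:
            bad("followup_years", "must be positive")
        if self.frailty_sd < 0:
            bad("frailty_sd", "must be non-negative")
        if self.process_start_age > lo:
            bad("process_start_age", "must not exceed the lower age bound")
        for m, spec in self.biomarker_models.items():
            if spec["residual_sd"] <= 0:
                bad(f"biomarker_models[{m}].residual_sd", "must be positive")
        if set(self.transition_log_intensities) != set(ALLOWED_EDGES):
            bad("transition_log_intensities",
                f"must define exactly the allowed transitions {ALLOWED_EDGES}")
        extra = set(self.transition_frailty_loghr) - set(ALLOWED_EDGES)
        if extra:
            bad("transition_frailty_loghr", f"unknown transitions {sorted(extra)}")
        for col, r in self.missingness_rates.items():
            if not 0.0 <= r <= 1.0:
                bad(f"missingness_rates[{col}]", "must be in [0, 1]")
        if self.missingness_mechanism not in ("mcar", "mar_age"):
            bad("missingness_mechanism", "must be 'mcar' or 'mar_age'")


def default_config(**overrides) -> GeneratorConfig:
    """Load the versioned default calibration, with field overrides."""
    raw = yaml.safe_load(
        (resources.files("agepath.data") / "default_generator.yaml").read_text())
    raw["age_range"] = tuple(raw["age_range"])
    raw.update(overrides)
    cfg = GeneratorConfig(**raw)
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# Disease-history simulation
# --------------------------------------------------------------------------

def _edge_rates(state: int, age: float, frailty: float, config: GeneratorConfig,
                death_enabled: bool):
    """(target_state, rate) pairs for the exits of ``state`` at ``age``."""
    out = []
    if state < 4:
        edge = f"{STATE_NAMES[state]}->{STATE_NAMES[state + 1]}"
        logq = (config.transition_log_intensities[edge]
                + config.transition_frailty_loghr.get(edge, 0.0) * frailty)
        out.append((state + 1, float(np.exp(logq))))
    if state >= 2 and death_enabled:
        edge = f"{STATE_NAMES[state]}->death"
        g = config.gompertz_mortality
        logq = (g["rate_intercept"] + g["age_slope"] * age
                + config.transition_log_intensities[edge]
                + config.transition_frailty_loghr.get(edge, 0.0) * frailty)
        out.append((5, float(np.exp(logq))))
    return out


def simulate_disease_history(baseline_age: float, sex, frailty: float,
                             config: GeneratorConfig, *, end_age: float | None = None,
                             rng=None, start_state: int = 1,
                             death_from_age: float | None = None) -> list:
    """Simulate one participant's jump process from ``baseline_age``.

    Returns the ordered event list ``[(age, state), ...]`` (the initial
    state is not an event; no transitions gives an empty list).  Competing
    exponential clocks are refreshed at each jump; within each 1-year age
    segment all intensities are constant, with the Gompertz death intensity
    evaluated at the segment midpoint.  Death intensities are zero below
    ``death_from_age``.
    """
    if not np.isfinite(frailty):
        raise ValueError("frailty must be finite")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if end_age is None:
        end_age = baseline_age + config.followup_years
    if death_from_age is None:
        death_from_age = baseline_age

    events = []
    state = start_state
    age = baseline_age
    while age < end_age and state != 5:
        # segments: calendar years, split at the death-enabling age; the
        # Gompertz rate is the step function evaluated at floor(age) + 0.5
        seg_end = min(np.floor(age + 1e-9) + 1.0, end_age)
        if age < death_from_age < seg_end:
            seg_end = death_from_age
        mid = np.floor(age + 1e-9) + 0.5
        rates = _edge_rates(state, mid, frailty, config,
                            death_enabled=age >= death_from_age)
        total = sum(r for _, r in rates)
        if total <= 0.0:
            age = seg_end
            continue
        wait = rng.exponential(1.0 / total)
        if age + wait >= seg_end:
            age = seg_end
            continue
        age += wait
        u = rng.random() * total
        acc = 0.0
        for target, r in rates:
            acc += r
            if u <= acc:
                state = target
                break
        events.append((age, state))
    return events


# --------------------------------------------------------------------------
# Cohort assembly
# --------------------------------------------------------------------------

def _covariates(n, age, rng):
    """Baseline covariate schema: demographic, socioeconomic, lifestyle,
    diet and air-pollution fields.  Independent of the latent frailty."""
    return {
        "ethnicity": np.where(rng.random(n) < 0.945, "white", "other"),
        "education": rng.choice([1, 2, 3, 4], size=n, p=[0.33, 0.11, 0.27, 0.29]),
        "townsend": rng.normal(-1.37, 3.04, n),
        "income": rng.choice([1, 2, 3, 4, 5], size=n, p=[0.22, 0.25, 0.26, 0.21, 0.06]),
        "smoking": (rng.random(n) < 0.45).astype(int),     # ever-smoker
        "alcohol": (rng.random(n) < 0.92).astype(int),     # ever-drinker
        "bmi_category": rng.choice([1, 2, 3], size=n, p=[0.34, 0.43, 0.23]),
        "physical_activity": rng.gamma(1.0, 2660.0, n),
        "diet_score": rng.choice(np.arange(6), size=n,
                                 p=[0.17, 0.20, 0.26, 0.23, 0.10, 0.04]),
        "no2": rng.normal(26.6, 7.6, n),
        "nox": rng.normal(43.9, 15.5, n),
        "pm25": rng.normal(10.0, 1.05, n),
        "pm10": rng.normal(16.2, 1.9, n),
    }


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the full synthetic cohort table.

    One latent frailty draw per participant is shared by the biomarker
    residual shifts and the transition intensities; all randomness flows
    from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    lo, hi = config.age_range

    baseline_age = rng.uniform(lo, hi, n)
    sex = np.where(rng.random(n) < config.sex_ratio, "female", "male")
    frailty = rng.normal(0.0, config.frailty_sd, n) if config.frailty_sd > 0 else np.zeros(n)
    is_female = (sex == "female").astype(float)

    cols = {
        "id": np.arange(1, n + 1),
        "chronological_age": baseline_age,
        "sex": sex,
        "frailty": frailty,
    }
    for m, spec in config.biomarker_models.items():
        mean = (spec["intercept"] + spec["age_slope"] * baseline_age
                + spec.get("sex_offset", 0.0) * is_female
                + spec.get("frailty_loading", 0.0) * frailty * spec["residual_sd"])
        vals = mean + rng.normal(0.0, spec["residual_sd"], n)
        cols[m] = np.exp(vals) if spec.get("log_scale", False) else vals
    cols.update(_covariates(n, baseline_age, rng))

    onset = {d: np.full(n, np.nan) for d in DOMAINS}
    death_age = np.full(n, np.nan)
    censor_age = baseline_age + config.followup_years
    for i in range(n):
        events = simulate_disease_history(
            config.process_start_age, sex[i], frailty[i], config,
            end_age=censor_age[i], rng=rng, death_from_age=baseline_age[i])
        held = []
        for age, state in events:
            if state == 5:
                death_age[i] = age
                break
            absent = [d for d in DOMAINS if d not in held]
            dom = absent[rng.integers(len(absent))]
            held.append(dom)
            onset[dom][i] = age
    for d in DOMAINS:
        cols[f"onset_age_{d}"] = onset[d]
    cols["death_age"] = death_age
    cols["censor_age"] = censor_age

    table = pd.DataFrame(cols)
    if config.missingness_rates:
        table = inject_missingness(
            table, config.missingness_rates,
            seed=int(rng.integers(2**31)), mechanism=config.missingness_mechanism)
    return table


def inject_missingness(table: pd.DataFrame, rates: dict, seed: int,
                       mechanism: str = "mcar") -> pd.DataFrame:
    """Mask cells at the requested per-column rates (seeded).

    Outcome, date, id, age and sex columns are protected and may never be
    masked.  Under ``mar_age`` the per-row masking probability tilts with
    baseline age (older rows more likely missing) while preserving the
    column-average rate.
    """
    protected = PROTECTED_COLUMNS & set(rates)
    if protected:
        raise ValueError(f"refusing to mask protected columns: {sorted(protected)}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    n = len(out)
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {col!r} outside [0, 1]: {rate}")
        if col not in out.columns or rate == 0.0:
            continue
        if mechanism == "mar_age":
            age = out["chronological_age"].to_numpy(float)
            w = np.exp(0.05 * (age - age.mean()))
            p = np.clip(rate * w / w.mean(), 0.0, 1.0)
        else:
            p = np.full(n, rate)
        mask = rng.random(n) < p
        if mask.any():
            if out[col].dtype.kind in "iub":
                out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan if out[col].dtype.kind == "f" else None
    return out


def write_cohort(table: pd.DataFrame, config: GeneratorConfig, outdir) -> dict:
    """Persist cohort CSV, config YAML and a provenance JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.csv",
        "config": outdir / "generator_config.yaml",
        "provenance": outdir / "provenance.json",
    }
    table.to_csv(paths["cohort"], index=False)
    cfg = asdict(config)
    cfg["age_range"] = list(cfg["age_range"])
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=False))
    paths["provenance"].write_text(json.dumps(
        {"seed": config.seed, "n_participants": int(len(table)),
         "columns": list(table.columns)}, indent=2))
    return {k: str(v) for k, v in paths.items()}
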