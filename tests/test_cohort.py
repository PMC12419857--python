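"""Synthetic cohort generator: reproducibility, disease-history simulation,
missingness injection, and calibration against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agepath import cohort
from agepath.cohort import (
    ConfigurationError,
    default_config,
    generate_cohort,
    inject_missingness,
    simulate_disease_history,
)
from agepath.states import DOMAINS, HealthState, timelines_from_table


class TestConfig:
    def test_invalid_fields_named(self):
        with pytest.raises(ConfigurationError, match="sex_ratio"):
            default_config(sex_ratio=1.5).validate()
        with pytest.raises(ConfigurationError, match="followup_years"):
            default_config(followup_years=-1.0)
        with pytest.raises(ConfigurationError, match="transition_log_intensities"):
            default_config(transition_log_intensities={"none->single": -3.0})

    def test_default_config_is_valid(self):
        default_config().validate()


class TestReproducibility:
    def test_same_seed_identical_tables(self):
        cfg = default_config(n_participants=100, seed=1)
        t1 = generate_cohort(cfg)
        t2 = generate_cohort(default_config(n_participants=100, seed=1))
        pd.testing.assert_frame_equal(t1, t2)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_different_seed_differs(self):
        t1 = generate_cohort(default_config(n_participants=100, seed=1))
        t2 = generate_cohort(default_config(n_participants=100, seed=2))
        assert not t1["sbp"].equals(t2["sbp"])


class TestDiseaseHistory:
    def test_zero_intensities_empty_event_list(self):
        cfg = default_config(
            transition_log_intensities={e: -np.inf for e in cohort.ALLOWED_EDGES})
        rng = np.random.default_rng(0)
        events = simulate_disease_history(50.0, "female", 0.0, cfg,
                                          end_age=70.0, rng=rng)
        assert events == []

    def test_single_edge_waiting_time_is_exponential(self):
        # only none->single open; time to first event must be Exp(q)
        q = 0.12
        tli = {e: -np.inf for e in cohort.ALLOWED_EDGES}
        tli["none->single"] = np.log(q)
        cfg = default_config(transition_log_intensities=tli,
                             transition_frailty_loghr={})
        rng = np.random.default_rng(3)
        waits = []
        for _ in range(10000):
            ev = simulate_disease_history(50.0, "male", 0.0, cfg,
                                          end_age=50.0 + 400.0, rng=rng)
            waits.append(ev[0][0] - 50.0)
        ks = stats.kstest(waits, "expon", args=(0, 1 / q))
        assert ks.pvalue > 1e-3

    def test_event_ages_strictly_increasing_and_allowed(self, small_cohort):
        cfg = default_config(n_participants=200, seed=5)
        rng = np.random.default_rng(7)
        for _ in range(200):
            ev = simulate_disease_history(45.0, "female", rng.normal(), cfg,
                                          end_age=90.0, rng=rng)
            ages = [a for a, _ in ev]
            assert all(b > a for a, b in zip(ages, ages[1:]))
            path = [1] + [s for _, s in ev]
            for s0, s1 in zip(path, path[1:]):
                assert (s1 == s0 + 1) or (s1 == 5 and s0 >= 2)

    def test_median_onset_age_decreases_with_frailty(self):
        cfg = default_config()
        medians = []
        for f in (-2.0, 0.0, 2.0):
            rng = np.random.default_rng(11)
            onsets = []
            for _ in range(3000):
                ev = simulate_disease_history(45.0, "female", f, cfg,
                                              end_age=45.0 + 200.0, rng=rng)
                onsets.append(ev[0][0] if ev else np.inf)
            medians.append(np.median(onsets))
        assert medians[0] > medians[1] > medians[2]


def _gillespie_oracle(cfg, n, seed):
    """Independent forward simulation of the same intensity functions,
    written as a direct Gillespie loop over the full age axis (no 1-year
    segment refresh for the constant disorder rates; thinning for the
    Gompertz death rate against a dominating bound)."""
    rng = np.random.default_rng(seed)
    lo, hi = cfg.age_range
    g = cfg.gompertz_mortality
    count_dual = 0
    for i in range(n):
        baseline = rng.uniform(lo, hi)
        frailty = rng.normal(0.0, cfg.frailty_sd)
        end = baseline + cfg.followup_years
        age, state = cfg.process_start_age, 1
        max_transient = 1
        while age < end and state != 5:
            prog = (np.exp(cfg.transition_log_intensities[
                        f"{cohort.STATE_NAMES[state]}->{cohort.STATE_NAMES[state+1]}"]
                    + cfg.transition_frailty_loghr.get(
                        f"{cohort.STATE_NAMES[state]}->{cohort.STATE_NAMES[state+1]}", 0)
                    * frailty) if state < 4 else 0.0)
            death_edge = f"{cohort.STATE_NAMES[state]}->death" if state >= 2 else None
            death_bound = (np.exp(g["rate_intercept"] + g["age_slope"] * (end + 1)
                                  + cfg.transition_log_intensities[death_edge]
                                  + cfg.transition_frailty_loghr.get(death_edge, 0)
                                  * frailty) if death_edge else 0.0)
            total = prog + death_bound
            if total <= 0:
                break
            age += rng.exponential(1.0 / total)
            if age >= end:
                break
            u = rng.random() * total
            if u <= prog:
                state += 1
                max_transient = max(max_transient, state)
            else:
                # thinning: accept death with prob rate(age)/bound, using the
                # piecewise-constant midpoint convention of the generator
                if age < baseline:
                    continue
                seg_mid = np.floor(age) + 0.5
                rate = np.exp(g["rate_intercept"] + g["age_slope"] * seg_mid
                              + cfg.transition_log_intensities[death_edge]
                              + cfg.transition_frailty_loghr.get(death_edge, 0) * frailty)
                if rng.random() < rate / death_bound:
                    state = 5
        if max_transient >= 3:
            count_dual += 1
    return count_dual / n


def test_dual_or_worse_fraction_matches_gillespie_oracle(big_cohort):
    """Proportion ever reaching dual-or-worse within follow-up agrees with an
    independent continuous-time forward simulation within 3 binomial SE."""
    n = 20000
    cfg = default_config(n_participants=n, seed=17, missingness_rates={})
    tls = timelines_from_table(big_cohort)

    def max_state(tl):
        return max(int(s) for _, s in tl.entries if s != HealthState.DEATH)

    reached = np.mean([max_state(tl) >= 3 for tl in tls])
    oracle = _gillespie_oracle(cfg, n, seed=999)
    se = np.sqrt(oracle * (1 - oracle) / n) * np.sqrt(2)  # both are MC estimates
    assert abs(reached - oracle) < 3 * se


def test_no_frailty_no_residual_onset_association():
    """With frailty_sd = 0 the biomarker residuals carry no information about
    onset times beyond age and sex: near-zero rank correlation."""
    n = 20000
    cfg = default_config(n_participants=n, seed=23, frailty_sd=0.0,
                         missingness_rates={})
    t = generate_cohort(cfg)
    # age/sex-adjusted residual of a high-loading biomarker
    X = np.column_stack([np.ones(n), t["chronological_age"],
                         (t["sex"] == "female").astype(float)])
    resid = t["hba1c"] - X @ np.linalg.lstsq(X, t["hba1c"], rcond=None)[0]
    onset = t[[f"onset_age_{d}" for d in DOMAINS]].min(axis=1)
    has_onset = onset.notna()
    rho, _ = stats.spearmanr(resid[has_onset], onset[has_onset])
    assert abs(rho) < 3.0 / np.sqrt(has_onset.sum())


def test_accelerated_participants_have_earlier_onsets(big_cohort):
    """Positive frailty loadings make high-frailty participants progress
    faster: log-rank on first incident onset among the baseline
    disorder-free."""
    from lifelines.statistics import logrank_test

    t = big_cohort
    first = t[[f"onset_age_{d}" for d in DOMAINS]].min(axis=1)
    base_free = first.isna() | (first > t["chronological_age"])
    t = t[base_free]
    first = first[base_free]
    high = t["frailty"] > 0
    end = first.fillna(t["censor_age"]).clip(upper=t["censor_age"])
    dur = end - t["chronological_age"]
    ev = (first.notna() & (first <= t["censor_age"])).astype(int)
    keep = dur > 0
    res = logrank_test(dur[keep & high], dur[keep & ~high],
                       ev[keep & high], ev[keep & ~high])
    assert res.p_value < 0.01
    # direction: high-frailty onsets are earlier on average among events
    assert first[keep & high].dropna().mean() < first[keep & ~high].dropna().mean()


class TestInjectMissingness:
    def test_rate_zero_unchanged(self, clean_cohort):
        out = inject_missingness(clean_cohort, {"townsend": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out, clean_cohort)

    def test_rate_one_all_missing(self, clean_cohort):
        out = inject_missingness(clean_cohort, {"townsend": 1.0}, seed=1)
        assert out["townsend"].isna().all()

    def test_binomial_band_at_rate_02(self):
        cfg = default_config(n_participants=10000, seed=31, missingness_rates={})
        t = generate_cohort(cfg)
        out = inject_missingness(t, {"income": 0.2}, seed=5)
        frac = out["income"].isna().mean()
        assert 0.188 <= frac <= 0.212

    def test_protected_columns_refused(self, clean_cohort):
        with pytest.raises(ValueError, match="protected"):
            inject_missingness(clean_cohort, {"death_age": 0.1}, seed=1)

    def test_mar_by_age_tilts_missingness_with_age(self):
        cfg = default_config(n_participants=20000, seed=37, missingness_rates={})
        t = generate_cohort(cfg)
        out = inject_missingness(t, {"income": 0.3}, seed=5, mechanism="mar_age")
        miss = out["income"].isna()
        assert (t.loc[miss, "chronological_age"].mean()
                > t.loc[~miss, "chronological_age"].mean() + 0.2)
        assert abs(miss.mean() - 0.3) < 0.02

    def test_seeded(self, clean_cohort):
        a = inject_missingness(clean_cohort, {"income": 0.3}, seed=9)
        b = inject_missingness(clean_cohort, {"income": 0.3}, seed=9)
        pd.testing.assert_frame_equal(a, b)


def test_baseline_state_mix_near_default_calibration(small_cohort):
    """Default calibration echoes the target baseline mix (~18/55/23/3)."""
    tls = timelines_from_table(small_cohort)
    counts = pd.Series([tl.baseline_state.name for tl in tls]).value_counts(normalize=True)
    assert abs(counts.get("NO_CONDITION", 0) - 0.18) < 0.05
    assert abs(counts.get("SINGLE", 0) - 0.55) < 0.07
    assert abs(counts.get("DUAL", 0) - 0.23) < 0.06
    assert counts.get("TRIPLE", 0) < 0.10


def test_write_cohort_artifacts(tmp_path, clean_cohort):
    cfg = default_config(n_participants=10, seed=3)
    t = generate_cohort(cfg)
    paths = cohort.write_cohort(t, cfg, tmp_path)
    import json, yaml
    assert pd.read_csv(paths["cohort"]).shape == t.shape
    prov = json.loads(open(paths["provenance"]).read())
    assert prov["seed"] == 3
    raw = yaml.safe_load(open(paths["config"]).read())
    assert raw["n_participants"] == 10
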