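"""Biological-age scores: KDM-BA, PhenoAge, acceleration, quartiles."""

import numpy as np
import pandas as pd
import pytest
from agepath import bioage
from agepath.bioage import (
    PHENOAGE_GAMMA,
    PHENOAGE_HORIZON,
    DegenerateScoreWarning,
    KlemeraDoubalAge,
    PhenoAge,
    assign_quartiles,
    compute_acceleration,
    compute_kdm,
    compute_phenoage,
    flag_extreme,
    phenoage_from_risk,
    phenoage_from_xb,
)


def _kdm_training_frame(rng, n=4000, markers=("m1", "m2", "m3"), noise=1.0):
    age = rng.uniform(40, 70, n)
    sex = rng.choice(["female", "male"], n)
    df = pd.DataFrame({"chronological_age": age, "sex": sex})
    truth = {}
    for i, m in enumerate(markers):
        q, k, s = 10.0 * (i + 1), 0.5 + 0.3 * i, noise * (1 + 0.5 * i)
        truth[m] = (q, k, s)
        df[m] = q + k * age + rng.normal(0, s, n)
    return df, truth


class TestKDMFit:
    def test_noiseless_regression_recovers_line_and_flags_degeneracy(self, rng):
        age = rng.uniform(40, 70, 500)
        df = pd.DataFrame({"chronological_age": age,
                           "sex": ["female"] * 500,
                           "m": 3.0 + 0.7 * age})
        with pytest.warns(DegenerateScoreWarning):
            est = KlemeraDoubalAge(biomarkers=("m",)).fit(df)
        q, k, s = est.params_.per_sex["female"]["m"]
        assert abs(q - 3.0) < 1e-8 and abs(k - 0.7) < 1e-8
        assert s < 1e-8

    def test_parameter_recovery_within_3se(self, rng):
        n = 50000
        df, truth = _kdm_training_frame(rng, n=n)
        est = KlemeraDoubalAge(biomarkers=tuple(truth)).fit(df)
        for sex, grp in df.groupby("sex"):
            age = grp["chronological_age"].to_numpy()
            m = len(grp)
            for marker, (q, k, s) in truth.items():
                qh, kh, sh = est.params_.per_sex[sex][marker]
                se_k = s / (np.std(age) * np.sqrt(m))
                se_q = se_k * np.sqrt(np.mean(age**2))
                assert abs(kh - k) < 3 * se_k
                assert abs(qh - q) < 3 * se_q
                assert abs(sh - s) < 3 * s / np.sqrt(2 * m)

    def test_uninformative_biomarkers_give_zero_sba_with_warning(self, rng):
        n = 3000
        df = pd.DataFrame({"chronological_age": rng.uniform(40, 70, n),
                           "sex": ["male"] * n,
                           "m": rng.normal(0, 1, n)})
        with pytest.warns(DegenerateScoreWarning):
            est = KlemeraDoubalAge(biomarkers=("m",), slope_floor=1e-2).fit(df)
        assert est.params_.s_ba["male"] < 1.0  # ~sqrt(R2~0 * Var) up to noise

    def test_insufficient_rows_error(self):
        df = pd.DataFrame({"chronological_age": [50, 51], "sex": ["f", "f"],
                           "m": [1.0, 2.0]})
        with pytest.raises(ValueError, match="insufficient"):
            KlemeraDoubalAge(biomarkers=("m",), min_rows=100).fit(df)

    def test_zero_variance_biomarker_named_in_error(self, rng):
        n = 300
        df = pd.DataFrame({"chronological_age": rng.uniform(40, 70, n),
                           "sex": ["male"] * n, "flat": np.ones(n)})
        with pytest.raises(ValueError, match="flat"):
            KlemeraDoubalAge(biomarkers=("flat",), min_rows=100).fit(df)


def _brute_force_kdm(xs, qs, ks, ss, ca, sba):
    """Direct term-by-term evaluation of the weighted-average equation."""
    num = sum((x - q) * k / s**2 for x, q, k, s in zip(xs, qs, ks, ss))
    den = sum((k / s) ** 2 for k, s in zip(ks, ss))
    num += ca / sba**2
    den += 1.0 / sba**2
    return num / den


class TestComputeKDM:
    def _params(self, markers, qs, ks, ss, sba):
        from agepath.bioage import KDMParameters
        per_sex = {"female": {m: (q, k, s) for m, q, k, s in zip(markers, qs, ks, ss)}}
        return KDMParameters(tuple(markers), per_sex, {"female": sba},
                             {"female": (40.0, 70.0)})

    def test_on_the_line_returns_chronological_age(self):
        p = self._params(["m"], [2.0], [0.8], [1.5], 10.0)
        x = 2.0 + 0.8 * 50.0
        assert compute_kdm({"m": x}, 50.0, p, sex="female") == pytest.approx(50.0, abs=1e-12)

    def test_matches_brute_force_on_random_panels(self, rng):
        markers = [f"b{i}" for i in range(9)]
        for _ in range(200):
            qs = rng.uniform(-5, 50, 9)
            ks = rng.uniform(0.1, 2.0, 9) * rng.choice([-1, 1], 9)
            ss = rng.uniform(0.5, 5.0, 9)
            sba = rng.uniform(5, 20)
            ca = rng.uniform(40, 70)
            xs = rng.uniform(-10, 80, 9)
            p = self._params(markers, qs, ks, ss, sba)
            got = compute_kdm(dict(zip(markers, xs)), ca, p, sex="female")
            want = _brute_force_kdm(xs, qs, ks, ss, ca, sba)
            assert got == pytest.approx(want, rel=1e-10)

    def test_large_sba_limit_is_marker_inverted_age(self):
        q, k = 4.0, 0.6
        p = self._params(["m"], [q], [k], [1.0], 1e9)
        x = 25.0
        got = compute_kdm({"m": x}, 55.0, p, sex="female")
        assert got == pytest.approx((x - q) / k, rel=1e-6)

    def test_missing_biomarker_withheld_with_reason(self, rng):
        df, truth = _kdm_training_frame(rng, n=500)
        est = KlemeraDoubalAge(biomarkers=tuple(truth)).fit(df)
        df2 = df.head(5).copy()
        df2.loc[df2.index[0], "m1"] = np.nan
        scores = est.predict(df2)
        assert np.isnan(scores[0]) and np.isfinite(scores[1:]).all()
        assert "m1" in str(est.withheld_reasons_[df2.index[0]])

    def test_unit_rescaling_equivariance(self, rng):
        """Rescaling a biomarker's units and refitting leaves scores unchanged."""
        df, truth = _kdm_training_frame(rng, n=4000)
        est1 = KlemeraDoubalAge(biomarkers=tuple(truth)).fit(df)
        s1 = est1.predict(df.head(50))
        df2 = df.copy()
        df2["m1"] = df2["m1"] * 38.5 + 4.2
        est2 = KlemeraDoubalAge(biomarkers=tuple(truth)).fit(df2)
        s2 = est2.predict(df2.head(50))
        np.testing.assert_allclose(s1, s2, rtol=1e-8)


class TestPhenoAge:
    def test_boundary_constant(self):
        # the xb at which the outer log argument is exactly 1 must return
        # the leading constant exactly
        g = PHENOAGE_GAMMA
        C = (np.exp(PHENOAGE_HORIZON * g) - 1.0) / g
        xb = np.log((1.0 / 0.00553) / C)
        assert phenoage_from_xb(xb) == pytest.approx(141.50225, abs=1e-9)

    def test_monotone_in_linear_predictor(self):
        xbs = np.linspace(-8, 2, 50)
        vals = [phenoage_from_xb(x) for x in xbs]
        assert np.all(np.diff(vals) > 0)

    def test_extreme_xb_guarded(self):
        with pytest.raises(ValueError, match="risk"):
            phenoage_from_xb(-800.0)  # risk -> 0: guarded error, not -inf
        with pytest.raises(ValueError, match="risk"):
            phenoage_from_risk(1.0)   # saturated risk input rejected

    def test_step_by_step_arithmetic_oracle(self, rng):
        est = PhenoAge().fit()
        markers = [m for m in est.markers_ if m != "chronological_age"]
        for _ in range(200):
            vals = {m: rng.uniform(0.5, 50.0) for m in markers}
            ca = rng.uniform(40, 70)
            got = compute_phenoage(vals, ca, est)
            # independent arithmetic: xb, then risk, then outer transform
            xb = est.intercept_
            for m in markers:
                v = np.log(vals[m]) if est.transforms_[m] == "log" else vals[m]
                xb += est.weights_[m] * v
            xb += est.weights_["chronological_age"] * ca
            g = PHENOAGE_GAMMA
            log1m_risk = -np.exp(xb) * (np.exp(PHENOAGE_HORIZON * g) - 1) / g
            want = 141.50225 + np.log(-0.00553 * log1m_risk) / 0.090165
            assert got == pytest.approx(want, rel=1e-10)

    def test_crp_log_transform_applied(self):
        est = PhenoAge().fit()
        assert est.transforms_["crp"] == "log"
        vals = {m: 10.0 for m in est.markers_ if m != "chronological_age"}
        vals["crp"] = 1.0  # log -> 0
        xb1 = est.linear_predictor({**vals, "chronological_age": 50.0})
        vals["crp"] = np.e  # log -> 1
        xb2 = est.linear_predictor({**vals, "chronological_age": 50.0})
        assert xb2 - xb1 == pytest.approx(est.weights_["crp"], rel=1e-9)

    def test_monotone_in_positive_weight_markers(self, clean_cohort):
        est = PhenoAge().fit()
        row = clean_cohort.iloc[0]
        base = {m: row[m] for m in est.markers_ if m != "chronological_age"}
        p0 = compute_phenoage(base, 55.0, est)
        bumped = dict(base)
        bumped["glucose"] += 1.0   # positive weight
        assert compute_phenoage(bumped, 55.0, est) > p0

    def test_missing_marker_withheld(self, clean_cohort):
        est = PhenoAge().fit()
        df = clean_cohort.head(3).copy()
        df.loc[df.index[0], "glucose"] = np.nan
        out = est.predict(df)
        assert np.isnan(out[0]) and np.isfinite(out[1:]).all()


class TestAcceleration:
    def test_identity_and_shift_give_zero_residuals(self):
        ca = np.linspace(40, 70, 100)
        for ba in (ca, ca + 7.0):
            res = compute_acceleration(ba, ca)
            np.testing.assert_allclose(res["residual"], 0.0, atol=1e-10)

    def test_five_point_normal_equation_oracle(self):
        ca = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ba = np.array([2.0, 2.5, 4.5, 4.0, 6.0])
        X = np.column_stack([np.ones(5), ca])
        beta = np.linalg.solve(X.T @ X, X.T @ ba)
        want = ba - X @ beta
        res = compute_acceleration(ba, ca)
        np.testing.assert_allclose(res["residual"], want, atol=1e-12)

    def test_residuals_uncorrelated_with_age(self, rng):
        ca = rng.uniform(40, 70, 5000)
        ba = 0.9 * ca + rng.normal(0, 5, 5000)
        res = compute_acceleration(ba, ca)
        r = np.corrcoef(res["residual"], ca)[0, 1]
        assert abs(r) < 1e-10

    def test_accelerated_flag_and_sd_scale(self, rng):
        ca = rng.uniform(40, 70, 1000)
        ba = ca + rng.normal(0, 4, 1000)
        res = compute_acceleration(ba, ca)
        assert ((res["residual"] > 0) == res["accelerated"]).all()
        assert np.std(res["residual_sd"], ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_acceleration(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))


class TestQuartiles:
    def test_one_to_eight(self):
        labels = assign_quartiles(np.arange(1.0, 9.0))
        assert list(labels) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_all_equal_degenerate(self):
        with pytest.warns(DegenerateScoreWarning):
            labels = assign_quartiles(np.full(10, 3.3))
        assert set(labels) == {"Q1"}

    def test_balanced_sizes_on_uniform_draws(self, rng):
        n = 10000
        labels = assign_quartiles(rng.random(n))
        counts = pd.Series(labels).value_counts()
        se = np.sqrt(n * 0.25 * 0.75)
        assert (np.abs(counts - n / 4) < 3 * se).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            assign_quartiles([1.0, 2.0, 3.0])


def test_flag_extreme_five_sd(rng):
    v = rng.normal(0, 1, 1000)
    v[0] = 50.0
    flags = flag_extreme(v, n_sd=5.0)
    assert flags[0] and flags[1:].sum() == 0


def test_stratified_acceleration_removes_group_offsets(rng):
    """With a stratified regression, a constant per-group BA offset is
    absorbed and residuals centre at zero within each stratum."""
    ca = rng.uniform(40, 70, 600)
    sex = rng.choice(["f", "m"], 600)
    ba = ca + np.where(sex == "f", 3.0, -2.0) + rng.normal(0, 3, 600)
    res = compute_acceleration(ba, ca, groups=sex)
    assert abs(res["residual"][sex == "f"].mean()) < 1e-9
    assert abs(res["residual"][sex == "m"].mean()) < 1e-9
    pooled = compute_acceleration(ba, ca)
    assert abs(pooled["residual"][sex == "f"].mean()) > 1.0  # offset not absorbed
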