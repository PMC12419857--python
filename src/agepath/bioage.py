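"""Biomarker-based biological-age scores and aging-acceleration residuals.

Two scores are implemented:

* **Klemera–Doubal biological age (KDM-BA)** — an inverse-variance-weighted
  combination of biomarker-implied ages and chronological age.  Each
  biomarker is regressed on chronological age within sex strata
  (``x_i ≈ q_i + k_i·CA``, residual RMSE ``s_i``); the score for a panel
  ``x`` at chronological age ``CA`` is::

      KDM-BA = [ Σ_i (x_i − q_i)·k_i/s_i² + CA/s_BA² ]
               / [ Σ_i (k_i/s_i)² + 1/s_BA² ]

  where ``s_BA`` is the square root of the variance in chronological age
  explained by the biomarker set.  Note on notation: we use the standard
  Klemera–Doubal convention in which ``q`` is the intercept and ``k`` the
  slope of the biomarker-on-age regression.

* **PhenoAge** — the chronological age at which a reference population's
  120-month mortality risk equals the individual's Gompertz-model risk.
  With linear predictor ``xb`` over nine markers plus chronological age::

      risk     = 1 − exp(−exp(xb)·(exp(120·γ) − 1)/γ),   γ = 0.0076927 / month
      PhenoAge = 141.50225 + ln(−0.00553·ln(1 − risk)) / 0.090165

**Aging acceleration** is the residual from ordinary least squares of
biological age on chronological age; positive residuals define the
"accelerated" group, and the residual divided by its SD is the per-SD
exposure used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

KDM_BIOMARKERS = (
    "sbp",
    "fev1",
    "total_cholesterol",
    "hba1c",
    "urea",
    "crp",
    "alkaline_phosphatase",
    "albumin",
    "creatinine",
)

PHENOAGE_GAMMA = 0.0076927      # Gompertz rate, per month
PHENOAGE_HORIZON = 120.0        # months
PHENOAGE_OUTER = (141.50225, -0.00553, 0.090165)


class DegenerateScoreWarning(UserWarning):
    pass


# --------------------------------------------------------------------------
# KDM-BA
# --------------------------------------------------------------------------

@dataclass
class KDMParameters:
    """Sex-stratified KDM scoring parameters.

    ``per_sex[sex][marker] = (q, k, s)`` with q the intercept (marker units),
    k the slope (marker units per year) and s the residual RMSE;
    ``s_ba[sex]`` in years; ``age_range[sex] = (low, high)``.
    """

    biomarkers: tuple
    per_sex: dict
    s_ba: dict
    age_range: dict
    flagged: dict = field(default_factory=dict)  # sex -> [marker, ...]

    @property
    def sexes(self):
        return tuple(self.per_sex)


class KlemeraDoubalAge(BaseEstimator):
    """Klemera–Doubal biological age, trained by sex-stratified least squares.

    Parameters
    ----------
    biomarkers : sequence of str
        Biomarker columns entering the score.
    min_rows : int
        Minimum complete training rows required per sex stratum.
    slope_floor : float
        Markers with ``|k|/s`` below this are flagged: their weight in the
        score is numerically negligible.
    s_ba_override : float or None
        Replace the fitted ``s_BA`` (e.g. to supply the fuller
        Klemera–Doubal variance correction).
    """

    def __init__(self, biomarkers=KDM_BIOMARKERS, min_rows=100,
                 slope_floor=1e-4, s_ba_override=None):
        self.biomarkers = biomarkers
        self.min_rows = min_rows
        self.slope_floor = slope_floor
        self.s_ba_override = s_ba_override

    def fit(self, X: pd.DataFrame, y=None):
        """Estimate (q, k, s) per biomarker and s_BA within each sex stratum."""
        cols = list(self.biomarkers)
        missing = [c for c in cols + ["chronological_age", "sex"] if c not in X.columns]
        if missing:
            raise ValueError(f"training table lacks columns: {missing}")
        per_sex, s_ba, age_range, flagged = {}, {}, {}, {}
        for sex, grp in X.groupby("sex", observed=True):
            grp = grp.dropna(subset=cols + ["chronological_age"])
            n = len(grp)
            if n < self.min_rows:
                raise ValueError(
                    f"insufficient complete rows for sex={sex!r}: {n} < {self.min_rows}")
            age = grp["chronological_age"].to_numpy(float)
            if np.var(age) == 0:
                raise ValueError(f"chronological age constant in sex={sex!r} stratum")
            params, flags = {}, []
            for m in cols:
                x = grp[m].to_numpy(float)
                if np.var(x) == 0:
                    raise ValueError(f"zero-variance biomarker: {m!r} (sex={sex!r})")
                k, q = np.polyfit(age, x, 1)
                resid = x - (q + k * age)
                s = float(np.sqrt(resid @ resid / max(n - 2, 1)))
                if s <= 1e-8 * np.std(x) or abs(k) / s < self.slope_floor:
                    flags.append(m)
                    warnings.warn(
                        f"biomarker {m!r} (sex={sex!r}) has near-degenerate "
                        f"age regression (k={k:.3g}, s={s:.3g})",
                        DegenerateScoreWarning, stacklevel=2)
                params[m] = (float(q), float(k), s)
            # s_BA: sqrt of the age variance explained by the biomarker set
            Z = np.column_stack([np.ones(n)] + [grp[m].to_numpy(float) for m in cols])
            beta, *_ = np.linalg.lstsq(Z, age, rcond=None)
            fitted = Z @ beta
            r2 = 1.0 - np.sum((age - fitted) ** 2) / np.sum((age - age.mean()) ** 2)
            r2 = max(r2, 0.0)
            sba = float(np.sqrt(r2 * np.var(age)))
            if sba < 1e-6:
                warnings.warn(
                    f"s_BA ~ 0 for sex={sex!r}: biomarkers explain no age variance",
                    DegenerateScoreWarning, stacklevel=2)
            if self.s_ba_override is not None:
                sba = float(self.s_ba_override)
            per_sex[sex] = params
            s_ba[sex] = sba
            age_range[sex] = (float(age.min()), float(age.max()))
            flagged[sex] = flags
        self.params_ = KDMParameters(tuple(cols), per_sex, s_ba, age_range, flagged)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Score each row; rows missing any biomarker get NaN (score withheld)."""
        ba, self.withheld_reasons_ = _kdm_score_table(X, self.params_)
        return ba


def _kdm_score_one(x: dict, chronological_age: float, params: KDMParameters, sex):
    if sex not in params.per_sex:
        raise ValueError(f"no KDM parameters for sex={sex!r}")
    p = params.per_sex[sex]
    sba = params.s_ba[sex]
    num = 0.0
    den = 0.0
    for m in params.biomarkers:
        v = x[m]
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            raise FloatingPointError(f"non-finite biomarker {m!r}")
        q, k, s = p[m]
        if s == 0:
            raise ZeroDivisionError(f"degenerate biomarker {m!r}: s=0")
        num += (v - q) * k / s**2
        den += (k / s) ** 2
    if sba > 0:
        num += chronological_age / sba**2
        den += 1.0 / sba**2
    return num / den


def _kdm_score_table(X: pd.DataFrame, params: KDMParameters):
    cols = list(params.biomarkers)
    out = np.full(len(X), np.nan)
    reasons = {}
    vals = X[cols].to_numpy(float)
    ages = X["chronological_age"].to_numpy(float)
    sexes = X["sex"].to_numpy(object)
    for i in range(len(X)):
        bad = [cols[j] for j in range(len(cols)) if not np.isfinite(vals[i, j])]
        if bad:
            reasons[X.index[i]] = f"missing biomarkers: {bad}"
            continue
        out[i] = _kdm_score_one(dict(zip(cols, vals[i])), ages[i], params, sexes[i])
    return out, reasons


def fit_kdm(training_table: pd.DataFrame, biomarkers=KDM_BIOMARKERS, **kw) -> KDMParameters:
    return KlemeraDoubalAge(biomarkers=biomarkers, **kw).fit(training_table).params_


def compute_kdm(panel, chronological_age: float, params: KDMParameters, sex=None) -> float:
    """Score a single biomarker panel (mapping marker -> value)."""
    if sex is None:
        sex = panel["sex"]
    return _kdm_score_one(panel, chronological_age, params, sex)


# --------------------------------------------------------------------------
# PhenoAge
# --------------------------------------------------------------------------

def load_phenoage_coefficients(path=None) -> pd.DataFrame:
    """Load the packaged (or user-supplied) PhenoAge coefficient table."""
    if path is None:
        path = resources.files("agepath.data") / "phenoage_coefficients.csv"
    coeffs = pd.read_csv(path, comment="#")
    required = {"marker", "transform", "weight"}
    if not required <= set(coeffs.columns):
        raise ValueError(f"coefficient file lacks columns {required}")
    if "intercept" not in set(coeffs["marker"]):
        raise ValueError("coefficient file lacks an intercept row")
    return coeffs


class PhenoAge(BaseEstimator):
    """Phenotypic age from nine markers plus chronological age.

    The coefficient table ships with the package (see
    ``data/phenoage_coefficients.csv``) and can be replaced via
    ``coefficients_path``.  Markers must arrive in the training units
    recorded in that file; C-reactive protein is log-transformed before
    weighting (driven by the file's ``transform`` column).
    """

    def __init__(self, coefficients_path=None):
        self.coefficients_path = coefficients_path

    def fit(self, X=None, y=None):
        self.coefficients_ = load_phenoage_coefficients(self.coefficients_path)
        rows = self.coefficients_.set_index("marker")
        self.intercept_ = float(rows.loc["intercept", "weight"])
        marker_rows = rows.drop(index="intercept")
        self.markers_ = list(marker_rows.index)
        self.weights_ = marker_rows["weight"].astype(float).to_dict()
        self.transforms_ = marker_rows["transform"].fillna("none").to_dict()
        return self

    def _check_fitted(self):
        if not hasattr(self, "coefficients_"):
            self.fit()

    def linear_predictor(self, values: dict) -> float:
        """xb for one participant; ``values`` keyed by marker name."""
        self._check_fitted()
        xb = self.intercept_
        for m in self.markers_:
            v = values[m]
            if not np.isfinite(v):
                raise FloatingPointError(f"non-finite marker {m!r}")
            if self.transforms_[m] == "log":
                if v <= 0:
                    raise ValueError(f"marker {m!r} must be positive for log transform")
                v = np.log(v)
            xb += self.weights_[m] * v
        return float(xb)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Score each row; rows missing any marker get NaN (score withheld)."""
        self._check_fitted()
        out = np.full(len(X), np.nan)
        self.withheld_reasons_ = {}
        data_markers = [m for m in self.markers_ if m != "chronological_age"]
        missing_cols = [m for m in data_markers if m not in X.columns]
        if missing_cols or "chronological_age" not in X.columns:
            raise ValueError(f"table lacks marker columns: {missing_cols}")
        for i, (idx, row) in enumerate(X.iterrows()):
            vals = {m: row[m] for m in data_markers}
            vals["chronological_age"] = row["chronological_age"]
            bad = [m for m, v in vals.items() if not np.isfinite(v)]
            if bad:
                self.withheld_reasons_[idx] = f"missing markers: {bad}"
                continue
            out[i] = phenoage_from_xb(self.linear_predictor(vals))
        return out


def phenoage_log1m_risk_from_xb(xb: float) -> float:
    """ln(1 - risk) for linear predictor ``xb`` under the 120-month Gompertz
    model; kept in log space because the risk saturates to 1.0 in floating
    point long before the score degenerates."""
    g = PHENOAGE_GAMMA
    return float(-np.exp(xb) * (np.exp(PHENOAGE_HORIZON * g) - 1.0) / g)


def phenoage_risk_from_xb(xb: float) -> float:
    """120-month Gompertz mortality risk for linear predictor ``xb``."""
    return float(-np.expm1(phenoage_log1m_risk_from_xb(xb)))


def _phenoage_from_log1m_risk(log1m: float) -> float:
    c0, c1, c2 = PHENOAGE_OUTER
    inner = c1 * log1m          # c1 < 0, log1m < 0 => positive
    if not inner > 0:
        raise ValueError(
            f"mortality risk numerically 0 (ln(1-risk)={log1m}): extreme linear predictor")
    val = c0 + np.log(inner) / c2
    if not np.isfinite(val):
        raise ValueError("mortality risk numerically 1: extreme linear predictor")
    return float(val)


def phenoage_from_risk(risk: float) -> float:
    if not 0.0 < risk < 1.0:
        raise ValueError(f"mortality risk {risk} outside (0, 1): extreme linear predictor")
    return _phenoage_from_log1m_risk(float(np.log1p(-risk)))


def phenoage_from_xb(xb: float) -> float:
    return _phenoage_from_log1m_risk(phenoage_log1m_risk_from_xb(xb))


def compute_phenoage(panel: dict, chronological_age: float, coeffs: PhenoAge | None = None) -> float:
    """Score a single marker panel (mapping marker -> value, training units)."""
    est = coeffs if coeffs is not None else PhenoAge().fit()
    est._check_fitted()
    vals = dict(panel)
    vals["chronological_age"] = chronological_age
    return phenoage_from_xb(est.linear_predictor(vals))


# --------------------------------------------------------------------------
# Acceleration, quartiles, extreme-value flags
# --------------------------------------------------------------------------

def compute_acceleration(biological_ages, chronological_ages, groups=None) -> pd.DataFrame:
    """Residuals from OLS of biological age on chronological age.

    Returns a DataFrame with ``residual`` (years), ``residual_sd`` (the
    SD-standardized residual used as the per-SD exposure) and ``accelerated``
    (residual > 0).  Residuals sum to zero and are uncorrelated with
    chronological age by construction of least squares with intercept.
    The regression is pooled by default; pass ``groups`` (e.g. sex) to fit
    it within strata instead.
    """
    ba = np.asarray(biological_ages, float)
    ca = np.asarray(chronological_ages, float)
    if ba.shape != ca.shape or ba.ndim != 1:
        raise ValueError("biological and chronological ages must be equal-length vectors")
    if len(ba) < 3:
        raise ValueError("need at least 3 observations")
    ok = np.isfinite(ba) & np.isfinite(ca)
    if np.var(ca[ok]) == 0:
        raise ValueError("chronological age vector is constant")
    resid = np.full_like(ba, np.nan)
    if groups is None:
        slope, intercept = np.polyfit(ca[ok], ba[ok], 1)
        resid[ok] = ba[ok] - (intercept + slope * ca[ok])
    else:
        groups = np.asarray(groups, object)
        for g in pd.unique(groups[ok]):
            sel = ok & (groups == g)
            if sel.sum() < 3 or np.var(ca[sel]) == 0:
                raise ValueError(f"stratum {g!r} too small or age-degenerate")
            slope, intercept = np.polyfit(ca[sel], ba[sel], 1)
            resid[sel] = ba[sel] - (intercept + slope * ca[sel])
    sd = float(np.std(resid[ok], ddof=1))
    accel = pd.array(resid > 0, dtype="boolean")
    accel[~ok] = pd.NA
    return pd.DataFrame({
        "residual": resid,
        "residual_sd": resid / sd if sd > 0 else resid * np.nan,
        "accelerated": accel,
    })


def assign_quartiles(values) -> np.ndarray:
    """Empirical quartile labels Q1..Q4; ties at a cutpoint go to the lower quartile."""
    v = np.asarray(values, float)
    finite = v[np.isfinite(v)]
    if finite.size < 4:
        raise ValueError("need at least 4 finite values for quartiles")
    cuts = np.quantile(finite, [0.25, 0.50, 0.75])
    if cuts[0] == cuts[2]:
        warnings.warn("degenerate quartiles: all cutpoints equal",
                      DegenerateScoreWarning, stacklevel=2)
    idx = np.searchsorted(cuts, v, side="left")
    labels = np.array([f"Q{i + 1}" for i in idx], dtype=object)
    labels[~np.isfinite(v)] = None
    return labels


def flag_extreme(values, n_sd: float = 5.0) -> np.ndarray:
    """Flag scores beyond ``n_sd`` SDs from the cohort mean for exclusion."""
    v = np.asarray(values, float)
    ok = np.isfinite(v)
    mu, sd = v[ok].mean(), v[ok].std(ddof=1)
    flags = np.zeros(v.shape, bool)
    if sd > 0:
        flags[ok] = np.abs(v[ok] - mu) > n_sd * sd
    return flags
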