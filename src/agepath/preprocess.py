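"""Unit harmonization, three-strategy multiple imputation, and Rubin pooling.

Imputation follows a fixed per-column strategy assignment rather than chained
equations: ordinal categorical columns are imputed by proportional-odds
ordered logistic draws, continuous columns that may be negative by
regression-based normal draws constrained to a plausible range, and
non-negative continuous columns by mean substitution.  ``m`` completed
copies of the table are produced (default 20) and downstream estimates are
combined with Rubin's rules, on the log scale for ratio measures (caller
contract).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

STRATEGIES = ("ordered_logistic", "multivariate_normal_bounded", "mean_substitution")


# --------------------------------------------------------------------------
# Unit harmonization
# --------------------------------------------------------------------------

def harmonize_units(table: pd.DataFrame, unit_map: dict, biomarker_columns=None):
    """Affine-transform biomarker columns into scoring (training) units.

    ``unit_map[col] = {"scale": a, "offset": b, "log": False}`` maps
    ``x -> a·x + b`` (then optionally natural log).  Every biomarker column
    must be covered; the applied transforms are returned as a provenance
    record that :func:`invert_units` can undo exactly.

    Returns ``(transformed_table, provenance)``.
    """
    if biomarker_columns is None:
        biomarker_columns = [c for c in unit_map if c in table.columns]
    unmapped = [c for c in biomarker_columns if c not in unit_map]
    if unmapped:
        raise KeyError(f"biomarker columns without unit mapping: {unmapped}")
    out = table.copy()
    provenance = {}
    for col in biomarker_columns:
        spec = unit_map[col]
        a = float(spec.get("scale", 1.0))
        b = float(spec.get("offset", 0.0))
        log = bool(spec.get("log", False))
        if a == 0:
            raise ValueError(f"unit scale for {col!r} must be nonzero (invertibility)")
        x = out[col].astype(float) * a + b
        if log:
            x = np.log(x)
        out[col] = x
        provenance[col] = {"scale": a, "offset": b, "log": log}
    return out, provenance


def invert_units(table: pd.DataFrame, provenance: dict) -> pd.DataFrame:
    """Exact inverse of :func:`harmonize_units` given its provenance record."""
    out = table.copy()
    for col, spec in provenance.items():
        x = out[col].astype(float)
        if spec["log"]:
            x = np.exp(x)
        out[col] = (x - spec["offset"]) / spec["scale"]
    return out


# --------------------------------------------------------------------------
# Multiple imputation
# --------------------------------------------------------------------------

@dataclass
class ImputationSpec:
    """Per-column imputation plan.

    ``strategies`` maps column -> one of ``ordered_logistic``,
    ``multivariate_normal_bounded``, ``mean_substitution``; ``bounds`` gives
    (low, high) plausibility bounds for bounded-normal columns;
    ``predictors`` names the columns used in the regression-based
    strategies (default: all baseline covariates plus age and sex — in
    practice, whatever numeric columns the caller lists).
    """

    m: int = 20
    strategies: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    predictors: list | None = None
    seed: int = 0
    max_rejection_retries: int = 100

    def validate(self, table: pd.DataFrame) -> None:
        if self.m < 2:
            raise ValueError("imputation requires m >= 2")
        for col, strat in self.strategies.items():
            if strat not in STRATEGIES:
                raise ValueError(f"unknown strategy {strat!r} for column {col!r}")
            if col not in table.columns:
                raise ValueError(f"strategy assigned to absent column {col!r}")
        for col, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {col!r} exclude all mass: ({lo}, {hi})")


class MultipleImputer(BaseEstimator):
    """Generate ``spec.m`` completed copies of a table.

    Observed cells are never altered; stochastic strategies draw
    independently per imputation from models fit on the observed data, so
    completed tables differ across imputations while mean-substitution
    columns are identical.
    """

    def __init__(self, spec: ImputationSpec):
        self.spec = spec

    def fit_transform(self, table: pd.DataFrame, y=None) -> list[pd.DataFrame]:
        spec = self.spec
        spec.validate(table)
        rng = np.random.default_rng(spec.seed)
        out = [table.copy() for _ in range(spec.m)]
        design = self._predictor_matrix(table)
        for col, strat in spec.strategies.items():
            obs_mask = table[col].notna().to_numpy()
            if not obs_mask.any():
                raise ValueError(f"column {col!r} has no observed values")
            if obs_mask.all():
                continue
            if strat == "mean_substitution":
                fill = float(table.loc[obs_mask, col].mean())
                for t in out:
                    t.loc[~obs_mask, col] = fill
            elif strat == "multivariate_normal_bounded":
                draws = self._bounded_normal_draws(table, col, obs_mask, design, rng)
                for t, d in zip(out, draws):
                    t.loc[~obs_mask, col] = d
            else:  # ordered_logistic
                draws = self._ordered_logistic_draws(table, col, obs_mask, design, rng)
                for t, d in zip(out, draws):
                    t.loc[~obs_mask, col] = d
        return out

    # -- helpers ----------------------------------------------------------

    def _predictor_matrix(self, table: pd.DataFrame) -> np.ndarray:
        """Numeric predictor matrix; missing predictor cells are mean-filled
        for the imputation models only (never written back)."""
        cols = self.spec.predictors
        if cols is None:
            cols = [c for c in table.columns
                    if c not in self.spec.strategies
                    and pd.api.types.is_numeric_dtype(table[c])]
        Z = []
        for c in cols:
            if c not in table.columns:
                raise ValueError(f"predictor column {c!r} absent from table")
            v = pd.to_numeric(table[c], errors="coerce").to_numpy(float)
            mu = np.nanmean(v) if np.isfinite(v).any() else 0.0
            v = np.where(np.isfinite(v), v, mu)
            if np.std(v) > 0:
                Z.append((v - v.mean()) / v.std())
        n = len(table)
        return np.column_stack([np.ones(n)] + Z) if Z else np.ones((n, 1))

    def _bounded_normal_draws(self, table, col, obs_mask, Z, rng):
        """Regression-based conditional normal draws with bound rejection.

        Coefficients are redrawn from their sampling distribution per
        imputation (proper-MI flavour); values outside the plausibility
        bounds are resampled up to a retry cap, then clamped.
        """
        y = table.loc[obs_mask, col].to_numpy(float)
        Zo, Zm = Z[obs_mask], Z[~obs_mask]
        beta, res, rank, _ = np.linalg.lstsq(Zo, y, rcond=None)
        resid = y - Zo @ beta
        dof = max(len(y) - Zo.shape[1], 1)
        sigma2 = float(resid @ resid / dof)
        XtX_inv = np.linalg.pinv(Zo.T @ Zo)
        lo, hi = self.spec.bounds.get(col, (-np.inf, np.inf))
        draws = []
        for _ in range(self.spec.m):
            b = rng.multivariate_normal(beta, sigma2 * XtX_inv, method="cholesky")
            mu = Zm @ b
            d = mu + rng.normal(0.0, np.sqrt(sigma2), size=len(mu))
            bad = (d < lo) | (d > hi)
            tries = 0
            while bad.any() and tries < self.spec.max_rejection_retries:
                d[bad] = mu[bad] + rng.normal(0.0, np.sqrt(sigma2), size=bad.sum())
                bad = (d < lo) | (d > hi)
                tries += 1
            draws.append(np.clip(d, lo, hi))
        return draws

    def _ordered_logistic_draws(self, table, col, obs_mask, Z, rng):
        """Proportional-odds fit on observed data; draw categories from the
        predicted probabilities, independently per imputation."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y_obs = table.loc[obs_mask, col]
        levels = np.sort(y_obs.dropna().unique())
        if len(levels) < 2:
            raise ValueError(f"ordinal column {col!r} has fewer than 2 observed levels")
        codes = pd.Categorical(y_obs, categories=levels, ordered=True).codes
        Zo, Zm = Z[obs_mask][:, 1:], Z[~obs_mask][:, 1:]  # model adds its own cuts
        if Zo.shape[1] == 0:
            probs = np.bincount(codes, minlength=len(levels)) / len(codes)
            prob_m = np.tile(probs, (Zm.shape[0], 1))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = OrderedModel(codes, Zo, distr="logit")
                fit = model.fit(method="bfgs", disp=False, maxiter=200)
            prob_m = fit.model.predict(fit.params, exog=Zm)
        cum = np.cumsum(prob_m, axis=1)
        u = rng.random(size=(self.spec.m, Zm.shape[0]))
        return [levels[np.minimum((u[j][:, None] > cum).sum(axis=1), len(levels) - 1)]
                for j in range(self.spec.m)]


def impute(table: pd.DataFrame, spec: ImputationSpec) -> list[pd.DataFrame]:
    return MultipleImputer(spec).fit_transform(table)


# --------------------------------------------------------------------------
# Rubin pooling
# --------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci95: tuple

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Combine ``m`` per-imputation estimates and variances by Rubin's rules.

    ``point`` is the mean estimate, ``within_var`` the mean variance,
    ``between_var`` the sample variance of estimates, and
    ``total_var = within + (1 + 1/m)·between``.  The small-sample df is
    ``(m−1)(1 + within/((1+1/m)·between))²``; with zero between-imputation
    variance the df is infinite and normal quantiles apply.  Ratio measures
    must be pooled on the log scale by the caller.
    """
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    m = len(est)
    if m < 2:
        raise ValueError("Rubin pooling requires m >= 2 imputations")
    if est.shape != var.shape or not (np.isfinite(est).all() and np.isfinite(var).all()):
        raise ValueError("estimates and variances must be finite and equal length")
    if (var < 0).any():
        raise ValueError("variances must be non-negative")
    point = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between == 0:
        df = np.inf
        q = stats.norm.ppf(0.975)
    else:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
        q = stats.t.ppf(0.975, df)
    se = np.sqrt(total)
    return PooledEstimate(point, within, between, total, float(df),
                          (point - q * se, point + q * se))
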