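"""Association models: logistic ORs, Cox HRs, restricted-cubic-spline
dose-response curves, and Rubin pooling across imputed datasets.

The exposure of interest is an aging-acceleration score, entered either
continuously per SD or as quartile indicators with the lowest quartile as
referent plus an ordinal-score trend test.  Logistic fits use maximum
likelihood (statsmodels); Cox fits use the partial likelihood with Efron
tie handling (lifelines).  Ratio measures are pooled across imputations on
the log (coefficient) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .preprocess import pool_rubin


@dataclass
class ModelFit:
    """Tidy fit container shared by the logistic and Cox paths."""

    params: pd.Series
    cov: pd.DataFrame
    summary: pd.DataFrame      # term, estimate, se, ci_low, ci_high, p
    n: int
    events: int | None = None
    exposure_coding: str = "per_sd"
    extra: dict = field(default_factory=dict)

    def ratio_table(self, label: str = "ratio") -> pd.DataFrame:
        out = self.summary.copy()
        out[label] = np.exp(out["estimate"])
        out[f"{label}_low"] = np.exp(out["ci_low"])
        out[f"{label}_high"] = np.exp(out["ci_high"])
        return out


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        collinear = []
        for c in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy(float)) == rank:
                collinear.append(c)
        raise ValueError(f"design matrix rank deficient; collinear columns: {collinear}")


def _tidy(params, cov, n, events=None, coding="per_sd") -> ModelFit:
    se = pd.Series(np.sqrt(np.diag(cov)), index=params.index)
    z = params / se
    summary = pd.DataFrame({
        "term": params.index,
        "estimate": params.values,
        "se": se.values,
        "ci_low": (params - 1.96 * se).values,
        "ci_high": (params + 1.96 * se).values,
        "p": 2 * stats.norm.sf(np.abs(z.values)),
    }).set_index("term", drop=False)
    return ModelFit(params, pd.DataFrame(cov, index=params.index, columns=params.index),
                    summary, n, events, coding)


def _exposure_frame(exposure) -> tuple[pd.DataFrame, str, pd.Series | None]:
    """Encode the exposure: continuous column, or Q1-referent indicators plus
    an ordinal trend score when labels Q1..Q4 are supplied."""
    if isinstance(exposure, pd.DataFrame):
        return exposure, "custom", None
    s = pd.Series(exposure).reset_index(drop=True)
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        levels = ["Q1", "Q2", "Q3", "Q4"]
        if not set(s.dropna().unique()) <= set(levels):
            raise ValueError("categorical exposure must use labels Q1..Q4")
        X = pd.DataFrame({f"exposure_{q}": (s == q).astype(float) for q in levels[1:]})
        trend = s.map({q: i + 1 for i, q in enumerate(levels)}).astype(float)
        return X, "quartile", trend
    return pd.DataFrame({"exposure": s.astype(float)}), "per_sd", None


def fit_logistic(outcome, exposure, covariates: pd.DataFrame | None = None) -> ModelFit:
    """Maximum-likelihood logistic regression; ORs are exp(coef).

    Quartile exposures get indicator coding with Q1 referent and a separate
    ordinal-score refit whose exposure p-value is reported as
    ``extra['p_trend']``.
    """
    import statsmodels.api as sm

    y = pd.Series(outcome).reset_index(drop=True).astype(float)
    if set(y.dropna().unique()) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes (0 and 1)")
    Xexp, coding, trend = _exposure_frame(exposure)
    parts = [Xexp]
    if covariates is not None:
        parts.append(covariates.reset_index(drop=True).astype(float))
    X = pd.concat(parts, axis=1)
    keep = y.notna() & X.notna().all(axis=1)
    X, y = X[keep], y[keep]
    Xc = sm.add_constant(X, has_constant="add")
    _check_design(Xc)
    try:
        res = sm.Logit(y, Xc).fit(disp=False, maxiter=200)
    except Exception as err:  # statsmodels PerfectSeparation errors vary by version
        raise ValueError(
            f"logistic fit failed ({err}); check for separation or drop sparse "
            "covariates") from err
    if np.abs(res.params.drop("const")).max() > 15:
        raise ValueError(
            "separation detected (diverging coefficient); consider collapsing "
            "sparse exposure levels or penalised regression")
    fit = _tidy(res.params, res.cov_params(), int(keep.sum()), None, coding)
    if trend is not None:
        tX = pd.concat([pd.DataFrame({"trend": trend[keep]}),
                        X.drop(columns=Xexp.columns)], axis=1)
        tres = sm.Logit(y, sm.add_constant(tX, has_constant="add")).fit(disp=False)
        fit.extra["p_trend"] = float(tres.pvalues["trend"])
    return fit


def fit_cox(time, event, exposure, covariates: pd.DataFrame | None = None,
            strata=None) -> ModelFit:
    """Cox proportional hazards (Efron ties); HRs are exp(coef).

    ``strata`` (e.g. baseline state) stratifies the baseline hazard.
    """
    t = pd.Series(time).reset_index(drop=True).astype(float)
    e = pd.Series(event).reset_index(drop=True).astype(int)
    if (t <= 0).any():
        raise ValueError("all event/censor times must be positive")
    if e.sum() == 0:
        raise ValueError("no events observed")
    Xexp, coding, trend = _exposure_frame(exposure)
    parts = [Xexp]
    if covariates is not None:
        parts.append(covariates.reset_index(drop=True).astype(float))
    X = pd.concat(parts, axis=1)
    df = pd.concat([pd.DataFrame({"time": t, "event": e}), X], axis=1)
    if strata is not None:
        df["strata"] = pd.Series(strata).reset_index(drop=True).values
    keep = df.drop(columns=["strata"], errors="ignore").notna().all(axis=1)
    df = df[keep]
    _check_design(df[X.columns])
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event",
                strata=["strata"] if strata is not None else None)
    except Exception as err:
        raise RuntimeError(f"Cox fit did not converge: {err}") from err
    fit = _tidy(cph.params_, cph.variance_matrix_, len(df), int(df["event"].sum()), coding)
    if trend is not None:
        tdf = df.drop(columns=list(Xexp.columns))
        tdf["trend"] = trend[keep].values
        tcph = CoxPHFitter()
        tcph.fit(tdf, duration_col="time", event_col="event",
                 strata=["strata"] if strata is not None else None)
        fit.extra["p_trend"] = float(tcph.summary.loc["trend", "p"])
    return fit


def schoenfeld_summary(time, event, exposure, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Proportional-hazards check: correlation of scaled Schoenfeld
    residuals with event rank time, per term, with a p-value.  A small
    correlation is consistent with proportional hazards."""
    t = pd.Series(time).reset_index(drop=True).astype(float)
    e = pd.Series(event).reset_index(drop=True).astype(int)
    Xexp, _, _ = _exposure_frame(exposure)
    parts = [Xexp]
    if covariates is not None:
        parts.append(covariates.reset_index(drop=True).astype(float))
    df = pd.concat([pd.DataFrame({"time": t, "event": e})] + parts, axis=1).dropna()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    resid = cph.compute_residuals(df, kind="scaled_schoenfeld")
    ranks = stats.rankdata(df.loc[resid.index, "time"])
    rows = []
    for term in resid.columns:
        r, p = stats.pearsonr(ranks, resid[term])
        rows.append({"term": term, "rank_time_corr": r, "p": p})
    return pd.DataFrame(rows).set_index("term")


# --------------------------------------------------------------------------
# Restricted cubic splines
# --------------------------------------------------------------------------

def default_knots(x, n_knots: int = 4) -> np.ndarray:
    """Knots at the 5th/35th/65th/95th percentiles (Harrell's convention for
    four knots); for other counts, equally spaced quantiles between 5 and 95."""
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if n_knots == 4:
        qs = [0.05, 0.35, 0.65, 0.95]
    else:
        qs = np.linspace(0.05, 0.95, n_knots)
    return np.quantile(x, qs)


def rcs_basis(x, knots) -> np.ndarray:
    """Harrell-form restricted cubic spline basis.

    Column 0 is the linear term; columns 1..k-2 are truncated-cubic
    combinations, normalised by (t_k - t_1)^2, that are linear beyond the
    boundary knots and C2-continuous at every knot.
    """
    x = np.asarray(x, float)
    t = np.asarray(knots, float)
    if len(t) < 3:
        raise ValueError("need at least 3 knots")
    if (np.diff(t) <= 0).any():
        raise ValueError("knots must be strictly increasing (no duplicates)")
    k = len(t)
    norm = (t[-1] - t[0]) ** 2

    def tp3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (tp3(x - t[j])
                - tp3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + tp3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
        cols.append(term / norm)
    return np.column_stack(cols)


def rcs_frame(x, knots, prefix: str = "rcs") -> pd.DataFrame:
    B = rcs_basis(x, knots)
    names = [f"{prefix}_lin"] + [f"{prefix}_nl{j}" for j in range(1, B.shape[1])]
    return pd.DataFrame(B, columns=names)


def dose_response_curve(fit: ModelFit, knots, grid, reference_value: float = 0.0,
                        prefix: str = "rcs", data_range=None) -> pd.DataFrame:
    """Pointwise HR(x) = exp(eta(x) - eta(ref)) with delta-method 95% CIs.

    ``fit`` must contain the spline terms produced by :func:`rcs_frame` with
    the same ``knots`` and ``prefix``.  The curve is exactly 1 at the
    reference.  Grid points outside ``data_range`` are truncated with a
    warning.
    """
    import warnings

    grid = np.asarray(grid, float)
    if data_range is not None:
        lo, hi = data_range
        if (grid < lo).any() or (grid > hi).any():
            warnings.warn("dose-response grid truncated to the observed exposure range",
                          stacklevel=2)
            grid = grid[(grid >= lo) & (grid <= hi)]
    terms = [c for c in fit.params.index if c.startswith(prefix + "_")]
    if not terms:
        raise ValueError(f"fit contains no spline terms with prefix {prefix!r}")
    Bg = rcs_frame(grid, knots, prefix)[terms].to_numpy()
    Br = rcs_frame(np.array([reference_value]), knots, prefix)[terms].to_numpy()
    D = Bg - Br
    beta = fit.params[terms].to_numpy()
    V = fit.cov.loc[terms, terms].to_numpy()
    eta = D @ beta
    se = np.sqrt(np.einsum("gi,ij,gj->g", D, V, D))
    return pd.DataFrame({
        "x": grid,
        "hr": np.exp(eta),
        "ci_low": np.exp(eta - 1.96 * se),
        "ci_high": np.exp(eta + 1.96 * se),
    })


# --------------------------------------------------------------------------
# Rubin pooling of fits across imputed datasets
# --------------------------------------------------------------------------

def pool_fits(fits: list[ModelFit]) -> pd.DataFrame:
    """Pool per-term coefficients across imputations (log scale) by Rubin's
    rules; returns a tidy table with pooled ratio estimates."""
    if len(fits) < 2:
        raise ValueError("pooling requires at least 2 fits")
    terms = fits[0].params.index
    rows = []
    for term in terms:
        est = [f.params[term] for f in fits]
        var = [f.cov.loc[term, term] for f in fits]
        pe = pool_rubin(est, var)
        rows.append({"term": term, "estimate": pe.point, "se": pe.se,
                     "ci_low": pe.ci95[0], "ci_high": pe.ci95[1],
                     "ratio": np.exp(pe.point),
                     "ratio_low": np.exp(pe.ci95[0]),
                     "ratio_high": np.exp(pe.ci95[1]),
                     "between_var": pe.between_var, "df": pe.df})
    return pd.DataFrame(rows).set_index("term", drop=False)
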