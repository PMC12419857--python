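"""Continuous-time Markov illness-death model with interval censoring.

States are 1 = no condition, 2 = single disorder, 3 = dual comorbidity,
4 = triple comorbidity, 5 = death (absorbing).  Allowed transitions are the
progressive chain 1->2->3->4 plus death exits 2->5, 3->5, 4->5; the direct
1->5 edge is excluded from the graph.  Transition intensities follow
proportional hazards::

    q_rs(z) = q0_rs * exp(beta_rs . z)

and the generator Q(z) has these intensities off-diagonal with rows summing
to zero.  Panel observations contribute interval-censored likelihood terms
P(dt|z)[s_prev, s_next] with P = exp(dt Q); an exactly observed death at the
end of an interval contributes sum_s P(dt)[s_prev, s] * q_s,death(z) over
transient states s.

The fitting path evaluates the likelihood and its exact gradient with a
uniformization series (P = e^{-L t} sum_k w_k M^k, M = I + Q/L), vectorised
across intervals; the series and its term-by-term derivative are exact for
any rate bound L >= max total exit rate, and the gradient is checked against
finite differences in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

N_STATES = 5
DEATH = 5  # 1-based state code


@dataclass(frozen=True)
class TransitionStructure:
    """Allowed edges of the illness-death graph (1-based state codes)."""

    edges: tuple = ((1, 2), (2, 3), (3, 4), (2, 5), (3, 5), (4, 5))
    n_states: int = N_STATES
    absorbing: tuple = (DEATH,)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def death_edges(self) -> tuple:
        return tuple(e for e in self.edges if e[1] == DEATH)


DEFAULT_STRUCTURE = TransitionStructure()


@dataclass
class IntensityModel:
    """Baseline log intensities and per-transition covariate effects."""

    structure: TransitionStructure
    log_q0: np.ndarray                 # (n_edges,)
    beta: np.ndarray                   # (n_edges, n_cov)
    covariate_names: tuple = ()
    cov: np.ndarray | None = None      # covariance of [log_q0, beta.ravel()]
    loglik: float | None = None

    @property
    def n_cov(self) -> int:
        return self.beta.shape[1] if self.beta.ndim == 2 else 0

    def theta(self) -> np.ndarray:
        return np.concatenate([self.log_q0, self.beta.ravel()])

    @classmethod
    def from_theta(cls, theta, structure, covariate_names=(), **kw):
        ne = structure.n_edges
        nc = len(covariate_names)
        return cls(structure, np.asarray(theta[:ne], float),
                   np.asarray(theta[ne:], float).reshape(ne, nc),
                   tuple(covariate_names), **kw)

    def generator(self, z=None) -> np.ndarray:
        """Q(z) as a dense (n_states, n_states) matrix."""
        z = np.zeros(self.n_cov) if z is None else np.asarray(z, float)
        Q = np.zeros((self.structure.n_states, self.structure.n_states))
        for e, (r, s) in enumerate(self.structure.edges):
            q = np.exp(self.log_q0[e] + (self.beta[e] @ z if self.n_cov else 0.0))
            if not np.isfinite(q):
                raise FloatingPointError(f"non-finite intensity on edge {r}->{s}")
            Q[r - 1, s - 1] = q
        Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
        return Q

    def to_json(self) -> str:
        """Serialize edges, log-intensities, covariate effects and (if
        present) the parameter covariance."""
        import json

        return json.dumps({
            "edges": [list(e) for e in self.structure.edges],
            "log_q0": self.log_q0.tolist(),
            "beta": self.beta.tolist(),
            "covariate_names": list(self.covariate_names),
            "cov": None if self.cov is None else self.cov.tolist(),
            "loglik": self.loglik,
        })

    @classmethod
    def from_json(cls, text: str) -> "IntensityModel":
        import json

        d = json.loads(text)
        return cls(TransitionStructure(tuple(tuple(e) for e in d["edges"])),
                   np.asarray(d["log_q0"], float), np.asarray(d["beta"], float),
                   tuple(d["covariate_names"]),
                   None if d["cov"] is None else np.asarray(d["cov"], float),
                   d["loglik"])

    def hazard_ratios(self) -> pd.DataFrame:
        """Per-transition covariate HRs with 95% CIs (needs the fit covariance)."""
        if self.cov is None:
            raise ValueError("model carries no covariance; fit with standard errors first")
        se = np.sqrt(np.diag(self.cov))
        rows = []
        ne = self.structure.n_edges
        for e, (r, s) in enumerate(self.structure.edges):
            rows.append({"transition": f"{r}->{s}", "term": "baseline_log_intensity",
                         "estimate": self.log_q0[e], "se": se[e]})
            for j, name in enumerate(self.covariate_names):
                idx = ne + e * self.n_cov + j
                rows.append({"transition": f"{r}->{s}", "term": name,
                             "estimate": self.beta[e, j], "se": se[idx]})
        df = pd.DataFrame(rows)
        df["hr"] = np.exp(df["estimate"])
        df["ci_low"] = np.exp(df["estimate"] - 1.96 * df["se"])
        df["ci_high"] = np.exp(df["estimate"] + 1.96 * df["se"])
        return df


def transition_probability(model: IntensityModel, z=None, dt: float = 1.0) -> np.ndarray:
    """P(dt|z) = expm(dt*Q(z)); rows sum to one, tiny negatives clamped."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    Q = model.generator(z)
    P = linalg.expm(dt * Q)
    if (P < -1e-12).any():
        raise FloatingPointError("transition probability matrix has negative entries")
    P = np.clip(P, 0.0, None)
    return P


# --------------------------------------------------------------------------
# Panel preparation
# --------------------------------------------------------------------------

@dataclass
class PanelData:
    """Flattened interval data for the likelihood."""

    Z: np.ndarray          # (n_intervals, n_cov) covariates
    s_prev: np.ndarray     # 0-based
    s_next: np.ndarray     # 0-based
    dt: np.ndarray
    is_death: np.ndarray   # bool
    ids: np.ndarray
    covariate_names: tuple = ()


def prepare_panel(panel: pd.DataFrame, covariates: pd.DataFrame | None = None,
                  covariate_names=()) -> PanelData:
    """Flatten a long-format panel (id, time, state, exact_death) into
    consecutive-observation intervals, joined with per-id covariates."""
    panel = panel.sort_values(["id", "time"])
    if covariates is not None and len(covariate_names):
        zlook = covariates.set_index("id")[list(covariate_names)]
    else:
        zlook = None
    Z, sp, sn, dts, death, ids = [], [], [], [], [], []
    for pid, grp in panel.groupby("id", sort=False):
        t = grp["time"].to_numpy(float)
        s = grp["state"].to_numpy(int)
        d = grp["exact_death"].to_numpy(bool)
        z = zlook.loc[pid].to_numpy(float) if zlook is not None else np.zeros(0)
        for j in range(len(grp) - 1):
            dt = t[j + 1] - t[j]
            if dt <= 0 and s[j + 1] == s[j]:
                continue
            Z.append(z)
            sp.append(s[j] - 1)
            sn.append(s[j + 1] - 1)
            dts.append(max(dt, 0.0))
            death.append(bool(d[j + 1]))
            ids.append(pid)
    return PanelData(np.asarray(Z, float), np.asarray(sp), np.asarray(sn),
                     np.asarray(dts, float), np.asarray(death, bool),
                     np.asarray(ids, object), tuple(covariate_names))


# --------------------------------------------------------------------------
# Likelihood with analytic gradient (uniformization)
# --------------------------------------------------------------------------

_MAX_SERIES_TERMS = 4000

try:  # optional numba fast path for the series kernel
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap


@_njit(cache=False)
def _series_kernel(M, lt, sprev, sel, Kcap):  # pragma: no cover - numba
    """Per-interval uniformization series: returns (L, vP, G).

    For each interval: L = v P sel, vP = v P, and G[r,s] such that
    v dP sel = (G : dQ)/Lam, using per-row Poisson truncation at tail mass
    1e-15.  Sequential forward/backward recurrences over the series terms.
    """
    m, ns, _ = M.shape
    L = np.zeros(m)
    vP = np.zeros((m, ns))
    G = np.zeros((m, ns, ns))
    fbuf = np.zeros((Kcap + 2, ns))
    w = np.zeros(Kcap + 2)
    for i in range(m):
        Mi = M[i]
        lti = lt[i]
        # Poisson weights and truncation point
        w[0] = np.exp(-lti)
        acc = w[0]
        K = 0
        for k in range(1, Kcap + 1):
            w[k] = w[k - 1] * lti / k
            acc += w[k]
            K = k
            if acc > 1.0 - 1e-15 and k > lti:
                break
        # forward: fbuf[j] = v M^j
        for s in range(ns):
            fbuf[0, s] = 0.0
        fbuf[0, sprev[i]] = 1.0
        for j in range(K):
            for s in range(ns):
                a = 0.0
                for r in range(ns):
                    a += fbuf[j, r] * Mi[r, s]
                fbuf[j + 1, s] = a
        # vP and L
        Li = 0.0
        for s in range(ns):
            a = 0.0
            for j in range(K + 1):
                a += w[j] * fbuf[j, s]
            vP[i, s] = a
            Li += a * sel[i, s]
        L[i] = Li
        # backward: Btil_j = w_{j+1} sel + M Btil_{j+1}; G += outer(f_j, Btil_j)
        bt = np.zeros(ns)
        for j in range(K - 1, -1, -1):
            nbt = np.zeros(ns)
            for r in range(ns):
                a = w[j + 1] * sel[i, r]
                for s in range(ns):
                    a += Mi[r, s] * bt[s]
                nbt[r] = a
            bt = nbt
            for r in range(ns):
                fr = fbuf[j, r]
                if fr != 0.0:
                    for s in range(ns):
                        G[i, r, s] += fr * bt[s]
    return L, vP, G
#: per-transition intensities are capped at 5/year during optimisation
#: (sojourn ~2.4 months, far beyond plausible chronic-disease rates); the
#: cap keeps the uniformization series bounded while the optimizer explores.
_LOG_Q_MAX = np.log(5.0)


def _edge_intensities(theta, structure, Z, n_cov):
    """q_e(z_i): (n_edges, m) matrix of per-interval intensities, clipped at
    the rate cap; returns (q, beta, clipped_mask)."""
    ne = structure.n_edges
    log_q0 = theta[:ne]
    beta = theta[ne:].reshape(ne, n_cov) if n_cov else np.zeros((ne, 0))
    eta = log_q0[:, None] + (beta @ Z.T if n_cov else np.zeros((ne, Z.shape[0])))
    clipped = eta > _LOG_Q_MAX
    return np.exp(np.minimum(eta, _LOG_Q_MAX)), beta, clipped


def _build_Q(qe, structure, m):
    ns = structure.n_states
    Q = np.zeros((m, ns, ns))
    for e, (r, s) in enumerate(structure.edges):
        Q[:, r - 1, s - 1] = qe[e]
    d = -Q.sum(axis=2)
    idx = np.arange(ns)
    Q[:, idx, idx] = d
    return Q


def _nll_and_grad(theta, data: PanelData, structure: TransitionStructure,
                  want_grad: bool = True, use_numba: bool = True):
    m = len(data.dt)
    n_cov = data.Z.shape[1] if data.Z.ndim == 2 else 0
    ns = structure.n_states
    qe, beta, clipped = _edge_intensities(theta, structure, data.Z, n_cov)
    Q = _build_Q(qe, structure, m)

    Lam = np.maximum(-Q[:, np.arange(ns), np.arange(ns)].min(axis=1), 1e-12)
    M = Q / Lam[:, None, None]
    M[:, np.arange(ns), np.arange(ns)] += 1.0
    lt = Lam * data.dt
    lt_max = float(lt.max()) if m else 0.0
    # truncate where the Poisson tail mass drops below 1e-15
    K = int(stats.poisson.isf(1e-15, lt_max) + 5) if lt_max > 0 else 5
    if K > _MAX_SERIES_TERMS:
        raise FloatingPointError(
            f"uniformization series needs {K} terms; intensities out of range")

    if not (use_numba and _HAVE_NUMBA):
        # Poisson weights w[k] per interval, (K+1, m)
        w = np.empty((K + 1, m))
        w[0] = np.exp(-lt)
        for k in range(1, K + 1):
            w[k] = w[k - 1] * (lt / k)

    # selection vector: one-hot of s_next, or q_{.,death} for death intervals
    sel = np.zeros((m, ns))
    sel[np.arange(m), data.s_next] = 1.0
    if data.is_death.any():
        dmask = data.is_death
        sel[dmask] = 0.0
        for e, (r, s) in enumerate(structure.edges):
            if s == DEATH:
                sel[dmask, r - 1] = qe[e][dmask]

    if use_numba and _HAVE_NUMBA:
        L, vP, G = _series_kernel(M, lt, data.s_prev.astype(np.int64), sel,
                                  _MAX_SERIES_TERMS)
        bad = L <= 0
        if bad.any():
            nll = np.inf
            return (nll, bad) if not want_grad else (nll, np.zeros_like(theta), bad)
        nll = -float(np.log(L).sum())
        if not want_grad:
            return nll, bad
    else:
        # forward pass: f_j = v M^j, and vP = sum_k w_k f_k
        F = np.empty((K + 1, m, ns))
        F[0] = 0.0
        F[0][np.arange(m), data.s_prev] = 1.0
        for k in range(K):
            F[k + 1] = np.matmul(F[k][:, None, :], M)[:, 0, :]
        vP = np.einsum("km,kmi->mi", w, F)

        L = np.einsum("mi,mi->m", vP, sel)
        bad = L <= 0
        if bad.any():
            # infeasible under the graph (or numerically extinct path)
            nll = np.inf
            if not want_grad:
                return nll, bad
            return nll, np.zeros_like(theta), bad

        nll = -float(np.log(L).sum())
        if not want_grad:
            return nll, bad

        # backward recurrence: Btil_j = w_{j+1} sel + M Btil_{j+1};
        # G[r,s] = sum_j f_j[r] * Btil_j[s] so that v dP sel = (G : dQ)/Lam
        B = np.empty((K, m, ns))
        Btil = np.zeros((m, ns, 1))
        for j in range(K - 1, -1, -1):
            Btil = w[j + 1][:, None, None] * sel[:, :, None] + np.matmul(M, Btil)
            B[j] = Btil[:, :, 0]
        G = np.einsum("kmi,kmj->mij", F[:K], B)

    invL = 1.0 / L
    ne = structure.n_edges
    grad = np.zeros_like(theta)
    for e, (r, s) in enumerate(structure.edges):
        # dQ = q_e(z) * (E_rs - E_rr)  =>  v dP sel = q_e (G[r,s]-G[r,r]) / Lam
        contrib = qe[e] * (G[:, r - 1, s - 1] - G[:, r - 1, r - 1]) / Lam
        if s == DEATH:
            # sel itself carries q_{r,death} on death intervals: dL += vP[r] q_e
            contrib = contrib + np.where(data.is_death, vP[:, r - 1] * qe[e], 0.0)
        dl = np.where(clipped[e], 0.0, contrib) * invL
        grad[e] = -dl.sum()
        if n_cov:
            grad[ne + e * n_cov: ne + (e + 1) * n_cov] = -(dl @ data.Z)
    return nll, grad, bad


def panel_loglik(model: IntensityModel, panel, covariates: pd.DataFrame | None = None):
    """Log-likelihood of a panel under ``model``.

    ``panel`` may be a long-format DataFrame or an already-prepared
    :class:`PanelData`.  Returns ``(loglik, diagnostics)`` where
    ``diagnostics`` lists participants with graph-infeasible observed pairs
    (their contribution makes the log-likelihood −inf).
    """
    data = panel if isinstance(panel, PanelData) else prepare_panel(
        panel, covariates, model.covariate_names)
    nll, bad = _nll_and_grad(model.theta(), data, model.structure, want_grad=False)
    diagnostics = {"infeasible_ids": sorted(set(data.ids[bad]))} if bad.any() else {}
    return (-nll if np.isfinite(nll) else -np.inf), diagnostics


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

class MultistateMarkov(BaseEstimator):
    """Maximum-likelihood illness-death model on interval-censored panels.

    Parameters
    ----------
    covariates : sequence of str
        Covariate columns (looked up per id) entering every transition with
        their own log hazard ratio.
    structure : TransitionStructure
    max_iter : int
        L-BFGS-B iteration cap.
    compute_se : bool
        Invert the observed information (finite differences of the analytic
        gradient) for standard errors.
    """

    def __init__(self, covariates=(), structure=DEFAULT_STRUCTURE,
                 max_iter=500, compute_se=True):
        self.covariates = covariates
        self.structure = structure
        self.max_iter = max_iter
        self.compute_se = compute_se

    def fit(self, panel: pd.DataFrame, covariate_table: pd.DataFrame | None = None,
            init: IntensityModel | None = None):
        structure = self.structure
        names = tuple(self.covariates)
        data = prepare_panel(panel, covariate_table, names)
        if (data.s_next < data.s_prev).any():
            bad_ids = sorted(set(data.ids[data.s_next < data.s_prev]))
            raise ValueError(f"backward state moves observed for ids {bad_ids[:10]}")
        self._check_identifiable(data, structure)
        n_cov = len(names)
        theta0 = (init.theta() if init is not None
                  else self._crude_init(data, structure, n_cov))
        ne = structure.n_edges
        bounds = [(-15.0, 2.0)] * ne + [(-8.0, 8.0)] * (ne * n_cov)

        def obj(th):
            nll, grad, _ = _nll_and_grad(th, data, structure)
            if not np.isfinite(nll):
                return 1e12, np.zeros_like(th)
            return nll, grad

        res = optimize.minimize(obj, theta0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": self.max_iter, "ftol": 1e-12,
                                         "gtol": 1e-7})
        if not res.success and np.linalg.norm(res.jac) > 1e-2:
            raise RuntimeError(
                f"multistate fit did not converge: {res.message} "
                f"(|grad| = {np.linalg.norm(res.jac):.3g})")
        cov = self._covariance(res.x, data, structure) if self.compute_se else None
        self.model_ = IntensityModel.from_theta(
            res.x, structure, names, cov=cov, loglik=-float(res.fun))
        self.n_intervals_ = len(data.dt)
        return self

    @staticmethod
    def _check_identifiable(data, structure):
        missing = []
        for r, s in structure.edges:
            if s == DEATH:
                seen = (data.is_death & (data.s_prev <= r - 1)).any()
            else:
                seen = ((data.s_prev <= r - 1) & (data.s_next >= s - 1)
                        & ~data.is_death).any() or (data.is_death
                                                    & (data.s_prev <= r - 1)).any()
            if not seen:
                missing.append(f"{r}->{s}")
        if missing:
            raise ValueError(f"unidentifiable transitions (never observed): {missing}")

    @staticmethod
    def _crude_init(data, structure, n_cov):
        """Occurrence/exposure rates: direct jumps over person-time in source state."""
        ne = structure.n_edges
        theta = np.zeros(ne + ne * n_cov)
        for e, (r, s) in enumerate(structure.edges):
            at_risk = data.s_prev == r - 1
            exposure = data.dt[at_risk].sum()
            if s == DEATH:
                count = (at_risk & data.is_death).sum()
            else:
                count = (at_risk & ~data.is_death & (data.s_next == s - 1)).sum()
            theta[e] = np.log((count + 0.5) / (exposure + 1.0))
        return theta

    def _covariance(self, theta, data, structure):
        p = len(theta)
        H = np.zeros((p, p))
        h = 1e-5 * np.maximum(1.0, np.abs(theta))
        for j in range(p):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h[j]
            tm[j] -= h[j]
            gp = _nll_and_grad(tp, data, structure)[1]
            gm = _nll_and_grad(tm, data, structure)[1]
            H[:, j] = (gp - gm) / (2.0 * h[j])
        H = 0.5 * (H + H.T)
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(H)


def fit_multistate(panel, structure=DEFAULT_STRUCTURE, covariates=(),
                   covariate_table=None, init=None, **kw) -> IntensityModel:
    est = MultistateMarkov(covariates=covariates, structure=structure, **kw)
    est.fit(panel, covariate_table, init=init)
    return est.model_


def simulate_panel(model: IntensityModel, Z: pd.DataFrame, obs_times,
                   seed: int = 0, start_state: int = 1) -> pd.DataFrame:
    """Simulate interval-censored panel observations from an intensity model.

    Each row of ``Z`` (with an ``id`` column) yields one participant observed
    at ``obs_times``; the underlying path is simulated by competing
    exponential clocks and recorded only at the observation times, except
    death which is recorded exactly.
    """
    rng = np.random.default_rng(seed)
    names = list(model.covariate_names)
    rows = []
    for _, zrow in Z.iterrows():
        z = zrow[names].to_numpy(float) if names else None
        Q = model.generator(z)
        t, state = 0.0, start_state
        jumps = []
        horizon = max(obs_times)
        while t < horizon and state != DEATH:
            rates = Q[state - 1].copy()
            rates[state - 1] = 0.0
            total = rates.sum()
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= horizon:
                break
            state = int(rng.choice(N_STATES, p=rates / total)) + 1
            jumps.append((t, state))
        pid = zrow["id"]
        death_time = next((tt for tt, ss in jumps if ss == DEATH), None)
        for ot in obs_times:
            if death_time is not None and ot >= death_time:
                break
            s_at = start_state
            for tt, ss in jumps:
                if tt <= ot:
                    s_at = ss
            rows.append((pid, ot, s_at, False))
        if death_time is not None:
            rows.append((pid, death_time, DEATH, True))
    return pd.DataFrame(rows, columns=["id", "time", "state", "exact_death"])
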