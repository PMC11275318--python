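"""Proportional landmark supermodel: pseudo partial likelihood estimation.

The stacked landmark rows are treated as counting-process observations
(entry, exit] on the common event-time axis.  The partial likelihood uses
Breslow tie handling and delayed entry: the risk set at event time ``t`` is
every row with ``entry < t <= exit``.  Because a patient contributes up to
one row per landmark, the rows are not independent; cluster-robust
(sandwich) covariance grouped by patient id is computed alongside the
model-based covariance and used for all reported confidence intervals.

Estimation is a Newton iteration with step-halving on the exact analytic
gradient and Hessian; per-iteration cost is O(n log n + n p^2) via
suffix-sum risk-set accumulation, so large stacks fit in well under a
second.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stacking import ALL_TERMS

__all__ = [
    "SupermodelFit",
    "ConvergenceError",
    "fit_supermodel",
    "breslow_baseline",
    "hazard_ratio_table",
]


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (non-convergence or separation)."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class SupermodelFit:
    """Fitted proportional landmark supermodel."""

    terms: list[str]
    coef: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n_patients: int
    n_rows: int
    n_events: int
    loglik_null: float
    loglik_model: float
    n_iter: int
    converged: bool
    dropped_terms: list[str] = field(default_factory=list)

    @property
    def chi_square(self) -> float:
        """Likelihood-ratio chi-square of the model against the null."""
        return 2.0 * (self.loglik_model - self.loglik_null)

    def se(self, robust: bool = True) -> np.ndarray:
        cov = self.cov_robust if robust else self.cov_model
        return np.sqrt(np.diag(cov))

    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coef))

    def linear_predictor(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Evaluate the fitted linear predictor on design rows over ``terms``."""
        if isinstance(X, pd.DataFrame):
            X = X[self.terms].to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.coef

    def cumhaz_at(self, t):
        """Step-interpolated baseline cumulative hazard at times ``t``."""
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.baseline_times, t, side="right")
        ch = np.concatenate([[0.0], self.baseline_cumhaz])
        out = ch[idx]
        return float(out[0]) if scalar else out

    def to_json(self, path) -> None:
        payload = {
            "terms": self.terms,
            "coef": self.coef.tolist(),
            "cov_model": self.cov_model.tolist(),
            "cov_robust": self.cov_robust.tolist(),
            "baseline_times": self.baseline_times.tolist(),
            "baseline_cumhaz": self.baseline_cumhaz.tolist(),
            "n_patients": self.n_patients,
            "n_rows": self.n_rows,
            "n_events": self.n_events,
            "loglik_null": self.loglik_null,
            "loglik_model": self.loglik_model,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "dropped_terms": self.dropped_terms,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SupermodelFit":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("coef", "cov_model", "cov_robust", "baseline_times", "baseline_cumhaz"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


class _PLWork:
    """Precomputed sort orders and event bookkeeping for one design."""

    def __init__(self, entry, exit_, event, Z):
        self.entry = entry
        self.exit = exit_
        self.event = event.astype(bool)
        self.Z = Z
        n, p = Z.shape
        self.n, self.p = n, p
        # unique event times, multiplicities, and covariate sums over events
        ev_t = exit_[self.event]
        self.t_uniq, inv = np.unique(ev_t, return_inverse=True)
        k = len(self.t_uniq)
        self.d = np.bincount(inv, minlength=k).astype(float)
        self.Zsum = np.zeros((k, p))
        np.add.at(self.Zsum, inv, Z[self.event])
        self.ev_time_idx = inv  # index into t_uniq for each event row
        # sorted views for suffix sums
        self.order_x = np.argsort(exit_, kind="stable")
        self.order_e = np.argsort(entry, kind="stable")
        self.exit_sorted = exit_[self.order_x]
        self.entry_sorted = entry[self.order_e]
        # positions of each unique event time in the sorted arrays:
        # suffix over {exit >= t} and {entry >= t}
        self.pos_x = np.searchsorted(self.exit_sorted, self.t_uniq, side="left")
        self.pos_e = np.searchsorted(self.entry_sorted, self.t_uniq, side="left")
        iu, ju = np.triu_indices(p)
        self.iu, self.ju = iu, ju
        self.Zpair = Z[:, iu] * Z[:, ju]  # n x p(p+1)/2 products for S2

    def _suffix(self, values):
        """suffix[i] = sum(values[i:]) with a trailing zero."""
        out = np.zeros(len(values) + 1)
        out[:-1] = np.cumsum(values[::-1])[::-1]
        return out

    def risk_sums(self, w):
        """S0, S1, S2 over the risk set at each unique event time.

        Uses entry < t <= exit and exit > entry >= 0:
        sum over {entry < t <= exit} = sum over {exit >= t} - sum over {entry >= t}.
        """
        p = self.p
        w_x = w[self.order_x]
        w_e = w[self.order_e]
        S0 = self._suffix(w_x)[self.pos_x] - self._suffix(w_e)[self.pos_e]

        wZ = w[:, None] * self.Z
        sfx = np.zeros((self.n + 1, p))
        sfx[:-1] = np.cumsum(wZ[self.order_x][::-1], axis=0)[::-1]
        sfe = np.zeros((self.n + 1, p))
        sfe[:-1] = np.cumsum(wZ[self.order_e][::-1], axis=0)[::-1]
        S1 = sfx[self.pos_x] - sfe[self.pos_e]

        wP = w[:, None] * self.Zpair
        sfx2 = np.zeros((self.n + 1, wP.shape[1]))
        sfx2[:-1] = np.cumsum(wP[self.order_x][::-1], axis=0)[::-1]
        sfe2 = np.zeros((self.n + 1, wP.shape[1]))
        sfe2[:-1] = np.cumsum(wP[self.order_e][::-1], axis=0)[::-1]
        S2flat = sfx2[self.pos_x] - sfe2[self.pos_e]
        return S0, S1, S2flat

    def loglik(self, beta):
        eta = self.Z @ beta
        w = np.exp(eta)
        w_x = w[self.order_x]
        w_e = w[self.order_e]
        S0 = self._suffix(w_x)[self.pos_x] - self._suffix(w_e)[self.pos_e]
        return float(np.sum(self.Zsum @ beta) - np.sum(self.d * np.log(S0)))

    def loglik_grad_hess(self, beta):
        eta = self.Z @ beta
        w = np.exp(eta)
        S0, S1, S2flat = self.risk_sums(w)
        zbar = S1 / S0[:, None]
        ll = float(np.sum(self.Zsum @ beta) - np.sum(self.d * np.log(S0)))
        grad = np.sum(self.Zsum - self.d[:, None] * zbar, axis=0)
        p = self.p
        H = np.zeros((p, p))
        m2 = np.sum(self.d[:, None] * (S2flat / S0[:, None]), axis=0)
        H[self.iu, self.ju] = m2
        H[self.ju, self.iu] = m2
        H -= (self.d[:, None] * zbar).T @ zbar
        return ll, grad, -H  # Hessian of the log PL is -H (H is the information)

    def score_residuals(self, beta):
        """Per-row score residuals (Lin–Wei form) for the sandwich estimator."""
        eta = self.Z @ beta
        w = np.exp(eta)
        S0, S1, _ = self.risk_sums(w)
        zbar = S1 / S0[:, None]
        # cumulative over event times: G0(t) = sum_{t_k<=t} d_k/S0_k,
        # G1(t) = sum_{t_k<=t} d_k*S1_k/S0_k^2
        g0 = np.concatenate([[0.0], np.cumsum(self.d / S0)])
        g1 = np.concatenate([np.zeros((1, self.p)),
                             np.cumsum(self.d[:, None] * S1 / S0[:, None] ** 2, axis=0)])
        ix = np.searchsorted(self.t_uniq, self.exit, side="right")
        ie = np.searchsorted(self.t_uniq, self.entry, side="right")
        dG0 = g0[ix] - g0[ie]
        dG1 = g1[ix] - g1[ie]
        U = -w[:, None] * (self.Z * dG0[:, None] - dG1)
        U[self.event] += self.Z[self.event] - zbar[self.ev_time_idx]
        return U


def _drop_degenerate(X: pd.DataFrame, terms: list[str]) -> tuple[list[str], list[str]]:
    keep, dropped = [], []
    for t in terms:
        col = X[t].to_numpy(dtype=float)
        if np.ptp(col) == 0.0:
            dropped.append(t)
        else:
            keep.append(t)
    return keep, dropped


def fit_supermodel(
    stack: pd.DataFrame,
    terms: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    beta_max: float = 10.0,
    penalizer: float = 0.0,
    drop_degenerate: bool = True,
) -> SupermodelFit:
    """Maximize the stacked pseudo partial likelihood.

    Parameters
    ----------
    stack
        Stacked landmark dataset from :func:`~dynapred.stacking.build_landmark_stack`.
    terms
        Design columns to include (default: every column of
        :data:`~dynapred.stacking.ALL_TERMS` present in the stack).
    drop_degenerate
        Silently drop constant columns (e.g. ``lm_time`` on a single-landmark
        grid at s=0); dropped names are recorded on the fit.
    penalizer
        Optional L2 (ridge) penalty strength on the coefficients; 0 gives the
        unpenalized maximum partial likelihood.  A small value stabilizes
        refits on tiny subsets (e.g. leave-one-out) where rare categories can
        separate.  Reported log-likelihoods are unpenalized.

    Raises
    ------
    ConvergenceError
        On non-convergence or apparent complete separation (coefficients
        diverging), with the log-likelihood trace attached.
    """
    if len(stack) == 0 or stack["event"].sum() < 1:
        raise ValueError("stack must be non-empty with at least one event")
    if terms is None:
        terms = [t for t in ALL_TERMS if t in stack.columns]
    terms = list(terms)
    if drop_degenerate:
        terms, dropped = _drop_degenerate(stack, terms)
    else:
        dropped = []
    if not terms:
        raise ValueError("no non-degenerate terms to fit")

    entry = stack["entry"].to_numpy(dtype=float)
    exit_ = stack["exit"].to_numpy(dtype=float)
    event = stack["event"].to_numpy(dtype=float)
    Z = stack[terms].to_numpy(dtype=float)
    if np.isnan(Z).any():
        raise ValueError("design matrix contains NaN; impute before fitting")
    center = Z.mean(axis=0)
    Zc = Z - center  # centering leaves coefficients unchanged, improves conditioning

    work = _PLWork(entry, exit_, event, Zc)
    p = len(terms)
    lam = float(penalizer)

    def objective(b):
        return work.loglik(b) - 0.5 * lam * float(b @ b)

    beta = np.zeros(p)
    ll_null = work.loglik(beta)
    obj_old = objective(beta)
    trace = [obj_old]
    converged = False
    it = 0
    ridge = 0.0
    for it in range(1, max_iter + 1):
        ll, grad, hess = work.loglik_grad_hess(beta)
        grad = grad - lam * beta
        info = -hess + lam * np.eye(p)
        try:
            step = np.linalg.solve(info + ridge * np.eye(p), grad)
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10, 1e-8)
            continue
        # step-halving until the objective does not decrease
        obj = objective(beta)
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            obj_new = objective(cand)
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            factor *= 0.5
        else:
            raise ConvergenceError("step-halving failed to improve the likelihood", trace)
        beta = beta + factor * step
        trace.append(obj_new)
        if np.max(np.abs(beta)) > beta_max:
            raise ConvergenceError(
                f"coefficients diverging (|beta| > {beta_max}): likely complete separation",
                trace,
            )
        rel = abs(obj_new - obj_old) / (abs(obj_old) + 1.0)
        obj_old = obj_new
        if rel < tol:
            # polish: Newton is quadratic, so one more check on the score
            _, grad_new, _ = work.loglik_grad_hess(beta)
            grad_new = grad_new - lam * beta
            if np.linalg.norm(grad_new) < 1e-6 * (1 + work.d.sum()):
                converged = True
                break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", trace)

    ll_model, grad, hess = work.loglik_grad_hess(beta)
    info = -hess + lam * np.eye(p)
    cov_model = np.linalg.inv(info)

    # cluster-robust sandwich grouped by patient id
    U = work.score_residuals(beta)
    ids = stack["id"].to_numpy()
    _, cluster_idx = np.unique(ids, return_inverse=True)
    n_clusters = cluster_idx.max() + 1
    Uc = np.zeros((n_clusters, p))
    np.add.at(Uc, cluster_idx, U)
    meat = Uc.T @ Uc
    cov_robust = cov_model @ meat @ cov_model

    # Breslow baseline on the original (uncentered) covariate scale
    times, cumhaz = _breslow(entry, exit_, event, Z @ beta)

    return SupermodelFit(
        terms=terms,
        coef=beta,
        cov_model=cov_model,
        cov_robust=cov_robust,
        baseline_times=times,
        baseline_cumhaz=cumhaz,
        n_patients=int(n_clusters),
        n_rows=len(stack),
        n_events=int(event.sum()),
        loglik_null=ll_null,
        loglik_model=ll_model,
        n_iter=it,
        converged=converged,
        dropped_terms=dropped,
    )


def _breslow(entry, exit_, event, eta):
    ev = event.astype(bool)
    t_uniq, inv = np.unique(exit_[ev], return_inverse=True)
    d = np.bincount(inv, minlength=len(t_uniq)).astype(float)
    w = np.exp(eta)
    order_x = np.argsort(exit_, kind="stable")
    order_e = np.argsort(entry, kind="stable")

    def suffix(v):
        out = np.zeros(len(v) + 1)
        out[:-1] = np.cumsum(v[::-1])[::-1]
        return out

    pos_x = np.searchsorted(exit_[order_x], t_uniq, side="left")
    pos_e = np.searchsorted(entry[order_e], t_uniq, side="left")
    S0 = suffix(w[order_x])[pos_x] - suffix(w[order_e])[pos_e]
    jumps = d / S0
    return t_uniq, np.cumsum(jumps)


def breslow_baseline(fit: SupermodelFit, stack: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Recompute the Breslow baseline cumulative hazard on a stack.

    Jump at each distinct event time t is (events at t) / sum of exp(linear
    predictor) over rows at risk (entry < t <= exit).  Returns (times,
    cumulative hazard), both empty when the stack has no events.
    """
    entry = stack["entry"].to_numpy(dtype=float)
    exit_ = stack["exit"].to_numpy(dtype=float)
    event = stack["event"].to_numpy(dtype=float)
    if event.sum() == 0:
        return np.array([]), np.array([])
    eta = fit.linear_predictor(stack)
    return _breslow(entry, exit_, event, eta)


def hazard_ratio_table(fit: SupermodelFit, level: float = 0.95, robust: bool = True) -> pd.DataFrame:
    """HR, CI and Wald p-value per term, with reference rows shown as HR=1.

    Rows follow the canonical reporting order: age (ref adolescent), sex
    (ref female), tumor location (ref other), volume (ref <200), excision
    (ref wide/radical), lung/other metastases (ref no), histological
    response constant + time-varying components (ref good), LR, NM
    (ref no), then the linear/quadratic follow-up-time effects.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = fit.se(robust=robust)
    coef = fit.coef_dict()
    se_map = dict(zip(fit.terms, se))

    layout = [
        ("Age", None),
        ("  Adolescent (ref)", "ref"),
        ("  Child", "child"),
        ("  Adult", "adult"),
        ("Sex", None),
        ("  Female (ref)", "ref"),
        ("  Male", "male"),
        ("Tumor location", None),
        ("  Other (ref)", "ref"),
        ("  Axial", "loc_axial"),
        ("  Proximal femur/humerus", "loc_proximal_fh"),
        ("Absolute tumor volume", None),
        ("  <200 cm3 (ref)", "ref"),
        ("  >=200 cm3", "volume_ge200"),
        ("Excision", None),
        ("  Wide/Radical (ref)", "ref"),
        ("  Marginal", "exc_marginal"),
        ("  Intralesional/Unknown", "exc_intralesional"),
        ("Presence of lung metastases", None),
        ("  No (ref)", "ref"),
        ("  Yes/Possible", "lung_mets"),
        ("Presence of other metastases", None),
        ("  No (ref)", "ref"),
        ("  Yes/Possible", "other_mets"),
        ("Histological response", None),
        ("  Good (ref)", "ref"),
        ("  Poor - Constant", "hist_poor"),
        ("  Poor - Linear time-varying effect", "hist_lm"),
        ("  Poor - Quadratic time-varying effect", "hist_lm_sq"),
        ("Local recurrence (LR)", None),
        ("  No (ref)", "ref"),
        ("  Yes", "lr_status"),
        ("New metastatic disease (NM)", None),
        ("  No (ref)", "ref"),
        ("  Yes", "nm_status"),
        ("Follow-up time (ref: time of surgery)", None),
        ("  Linear t", "lm_time"),
        ("  Quadratic t^2", "lm_time_sq"),
    ]

    rows = []
    for label, term in layout:
        if term is None:
            rows.append({"label": label, "term": "", "hr": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan})
        elif term == "ref":
            rows.append({"label": label, "term": "", "hr": 1.0,
                         "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan})
        elif term in coef:
            b, s = coef[term], se_map[term]
            pval = 2.0 * stats.norm.sf(abs(b) / s) if s > 0 else np.nan
            rows.append({"label": label, "term": term, "hr": np.exp(b),
                         "ci_low": np.exp(b - z * s), "ci_high": np.exp(b + z * s),
                         "p_value": pval})
        # terms dropped from the fit (degenerate columns) are omitted
    return pd.DataFrame(rows)
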