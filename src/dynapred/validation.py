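"""Internal validation: heuristic shrinkage, sliding-window concordance,
reverse Kaplan-Meier median follow-up."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .stacking import ALL_TERMS, LandmarkGrid, build_landmark_stack
from .supermodel import SupermodelFit, fit_supermodel

__all__ = [
    "heuristic_shrinkage",
    "dynamic_cindex",
    "cindex_from_scores",
    "reverse_km_median_followup",
    "ValidationReport",
]


@dataclass
class ValidationReport:
    shrinkage: float | None
    cindex_by_time: dict[float, tuple[float, int]]
    median_followup: float | None
    median_followup_ci: tuple[float, float]
    loo: bool = True
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "shrinkage": self.shrinkage,
            "cindex_by_time": {str(t): list(v) for t, v in self.cindex_by_time.items()},
            "median_followup": self.median_followup,
            "median_followup_ci": list(self.median_followup_ci),
            "leave_one_out": self.loo,
            "notes": self.notes,
        }


def heuristic_shrinkage(fit: SupermodelFit) -> float | None:
    """Heuristic shrinkage (chi2 - p) / chi2 with the likelihood-ratio chi2.

    ``p`` is the number of estimated coefficients.  Values near 1 indicate
    little overfitting; negative values (useless models) are returned as-is.
    Returns None when chi2 == 0 (undefined).
    """
    chi2 = fit.chi_square
    if chi2 == 0.0:
        return None
    return (chi2 - len(fit.terms)) / chi2


def cindex_from_scores(scores, t_os, os_status, t: float, w: float) -> tuple[float, int]:
    """Harrell's C restricted to the window (t, t+w].

    Pairs (i, j) are comparable when both are at risk at ``t`` (t_os > t),
    ``i`` dies at time ti with t < ti <= t+w, and ``tj > ti``.  Ties in
    score count 1/2.  Returns (C, number of comparable pairs); C is NaN
    when no pair is comparable.
    """
    scores = np.asarray(scores, dtype=float)
    t_os = np.asarray(t_os, dtype=float)
    dead = np.asarray(os_status, dtype=float) == 1.0
    at_risk = t_os > t
    cases = at_risk & dead & (t_os <= t + w)
    conc = 0.0
    npairs = 0
    idx_cases = np.flatnonzero(cases)
    for i in idx_cases:
        later = at_risk & (t_os > t_os[i])
        npairs += int(later.sum())
        conc += np.sum(scores[i] > scores[later]) + 0.5 * np.sum(scores[i] == scores[later])
    if npairs == 0:
        return float("nan"), 0
    return float(conc / npairs), npairs


def _status_design(cohort: pd.DataFrame, enc: pd.DataFrame, terms: list[str], t: float) -> np.ndarray:
    """Design rows at landmark t (status updated, interactions at s=t)."""
    X = pd.DataFrame(index=cohort.index)
    for term in terms:
        if term in enc.columns:
            X[term] = enc[term].to_numpy(dtype=float)
    hist = enc["hist_poor"].to_numpy(dtype=float)
    t_lr = cohort["t_lr"].to_numpy(dtype=float)
    t_nm = cohort["t_nm"].to_numpy(dtype=float)
    extra = {
        "hist_lm": hist * t,
        "hist_lm_sq": hist * t * t,
        "lr_status": (~np.isnan(t_lr) & (t_lr <= t)).astype(float),
        "nm_status": (~np.isnan(t_nm) & (t_nm <= t)).astype(float),
        "lm_time": np.full(len(cohort), t),
        "lm_time_sq": np.full(len(cohort), t * t),
    }
    for k, v in extra.items():
        if k in terms:
            X[k] = v
    return X[terms].to_numpy(dtype=float)


def dynamic_cindex(
    cohort: pd.DataFrame,
    t: float,
    w: float = 5.0,
    grid: LandmarkGrid | None = None,
    refit: bool = True,
    fit: SupermodelFit | None = None,
    penalizer: float | None = None,
    seed: int = 0,
) -> tuple[float, int]:
    """Dynamic C-index at time ``t`` for window ``w``.

    The risk score of a patient is the supermodel linear predictor at
    landmark ``t`` given their LR/NM status at ``t``.  With ``refit=True``
    (leave-one-out) patient ``i``'s score comes from a supermodel fitted on
    the stack excluding every row of ``i`` — n refits.  With
    ``refit=False`` a single fit scores everyone (fast approximation; flag
    it as such in reports).  A prefitted model may be passed via ``fit`` to
    reuse across time points in fast mode.

    ``penalizer`` defaults to a tiny ridge (0.01) in leave-one-out mode —
    refits on n-1 patients can otherwise separate on rare categories — and
    to 0 in fast mode.
    """
    from .cohort import encode_covariates

    grid = grid or LandmarkGrid()
    enc = encode_covariates(cohort)
    stack = build_landmark_stack(cohort, grid)

    if refit:
        lam = 0.01 if penalizer is None else penalizer
        scores = np.full(len(cohort), np.nan)
        ids = cohort["id"].to_numpy()
        at_risk = cohort["t_os"].to_numpy(dtype=float) > t
        for pos in np.flatnonzero(at_risk):
            sub = stack[stack["id"] != ids[pos]]
            f = fit_supermodel(sub, penalizer=lam)
            X = _status_design(cohort.iloc[[pos]], enc.iloc[[pos]], f.terms, t)
            scores[pos] = (X @ f.coef)[0]
    else:
        f = fit if fit is not None else fit_supermodel(stack, penalizer=penalizer or 0.0)
        X = _status_design(cohort, enc, f.terms, t)
        scores = X @ f.coef

    return cindex_from_scores(
        scores, cohort["t_os"].to_numpy(dtype=float), cohort["os_status"].to_numpy(dtype=float), t, w
    )


def reverse_km_median_followup(
    cohort: pd.DataFrame, level: float = 0.95
) -> tuple[float | None, tuple[float, float]]:
    """Median follow-up by reverse Kaplan-Meier (censorings as events).

    Returns (median, (ci_low, ci_high)); median is None when not reached
    (e.g. no censored observations), and CI bounds are NaN where the
    log-log interval does not cross 1/2.
    """
    t = cohort["t_os"].to_numpy(dtype=float)
    censored = 1.0 - cohort["os_status"].to_numpy(dtype=float)
    km = KaplanMeierFitter(alpha=1 - level)
    km.fit(t, event_observed=censored)
    median = km.median_survival_time_
    if not np.isfinite(median):
        return None, (float("nan"), float("nan"))
    ci = km.confidence_interval_survival_function_
    lo_col, hi_col = ci.columns[0], ci.columns[1]

    def crossing(col):
        below = ci.index[ci[col].to_numpy() <= 0.5]
        return float(below[0]) if len(below) else float("nan")

    # lower survival band crosses 1/2 earlier -> lower bound for the median
    return float(median), (crossing(lo_col), crossing(hi_col))
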