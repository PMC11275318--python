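"""Dynamic predictions from a fitted landmark supermodel.

Two products: the time-varying hazard ratio of poor vs good histological
response as a function of prediction time (constant x linear^tp x
quadratic^(tp^2), with delta-method pointwise intervals on the log scale),
and conditional 5-year death probabilities for covariate profiles under the
four disease statuses (none / LR / NM / LR+NM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BASELINE_TERMS, encode_covariates
from .supermodel import SupermodelFit

__all__ = [
    "TimeVaryingEffect",
    "PatientProfile",
    "time_varying_hr",
    "hr_crossing_time",
    "histology_effect",
    "predict_window_death_probability",
    "profile_prediction_curves",
]

DISEASE_STATUSES = ("none", "LR", "NM", "LR+NM")

_EFFECT_TERMS = ("hist_poor", "hist_lm", "hist_lm_sq")


@dataclass(frozen=True)
class TimeVaryingEffect:
    """Multiplicative time-varying hazard-ratio components.

    ``hr_constant * hr_linear**tp * hr_quadratic**(tp**2)`` with a 3x3
    covariance of the component logs for pointwise intervals.
    """

    hr_constant: float
    hr_linear: float
    hr_quadratic: float
    covariance: np.ndarray | None = None

    def __post_init__(self):
        if min(self.hr_constant, self.hr_linear, self.hr_quadratic) <= 0:
            raise ValueError("hazard-ratio components must be > 0")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.shape != (3, 3):
                raise ValueError("covariance must be 3x3 (log scale)")
            object.__setattr__(self, "covariance", cov)


def histology_effect(fit: SupermodelFit, robust: bool = True) -> TimeVaryingEffect:
    """Extract the histological-response effect components from a fit."""
    idx = [fit.terms.index(t) for t in _EFFECT_TERMS]
    cov = (fit.cov_robust if robust else fit.cov_model)[np.ix_(idx, idx)]
    b = fit.coef[idx]
    return TimeVaryingEffect(*np.exp(b), covariance=cov)


def time_varying_hr(
    effect: TimeVaryingEffect, tp: float, level: float = 0.95
) -> tuple[float, float, float]:
    """HR(tp) with a pointwise CI; (hr, nan, nan) when no covariance is set.

    The log HR is linear in the component logs with gradient (1, tp, tp^2),
    so the delta-method variance is g' C g exactly.
    """
    if tp < 0:
        raise ValueError("tp must be >= 0")
    g = np.array([1.0, tp, tp * tp])
    log_hr = (
        np.log(effect.hr_constant)
        + tp * np.log(effect.hr_linear)
        + tp * tp * np.log(effect.hr_quadratic)
    )
    if effect.covariance is None:
        return float(np.exp(log_hr)), float("nan"), float("nan")
    var = float(g @ effect.covariance @ g)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(np.exp(log_hr)), float(np.exp(log_hr - half)), float(np.exp(log_hr + half))


def hr_crossing_time(
    effect: TimeVaryingEffect,
    grid_step: float = 0.25,
    t_max: float = 5.0,
    level: float = 0.95,
) -> float | None:
    """Smallest grid tp whose CI contains 1, or None if never on the grid."""
    if effect.covariance is None:
        raise ValueError("crossing time requires the component covariance")
    for tp in np.round(np.arange(0.0, t_max + grid_step / 2, grid_step), 10):
        _, lo, hi = time_varying_hr(effect, float(tp), level=level)
        if lo <= 1.0 <= hi:
            return float(tp)
    return None


@dataclass(frozen=True)
class PatientProfile:
    """Baseline covariate profile plus disease status at prediction time."""

    covariates: dict[str, float]
    disease_status: str = "none"
    label: str = ""

    def __post_init__(self):
        if self.disease_status not in DISEASE_STATUSES:
            raise ValueError(f"disease_status must be one of {DISEASE_STATUSES}")
        unknown = set(self.covariates) - set(BASELINE_TERMS)
        if unknown:
            raise ValueError(f"unknown covariate terms: {sorted(unknown)}")

    @classmethod
    def reference(cls, status: str = "none", label: str = "reference") -> "PatientProfile":
        return cls(covariates={}, disease_status=status, label=label)

    @classmethod
    def from_cohort_row(cls, row: pd.Series, status: str = "none",
                        label: str = "") -> "PatientProfile":
        enc = encode_covariates(row.to_frame().T).iloc[0]
        return cls(covariates={t: float(enc[t]) for t in BASELINE_TERMS},
                   disease_status=status, label=label or str(row.get("id", "")))

    def design_row(self, terms: list[str], tp: float) -> np.ndarray:
        hist = self.covariates.get("hist_poor", 0.0)
        full = dict.fromkeys(terms, 0.0)
        for k, v in self.covariates.items():
            if k in full:
                full[k] = v
        values = {
            "hist_lm": hist * tp,
            "hist_lm_sq": hist * tp * tp,
            "lr_status": 1.0 if self.disease_status in ("LR", "LR+NM") else 0.0,
            "nm_status": 1.0 if self.disease_status in ("NM", "LR+NM") else 0.0,
            "lm_time": tp,
            "lm_time_sq": tp * tp,
        }
        for k, v in values.items():
            if k in full:
                full[k] = v
        return np.array([full[t] for t in terms])


def predict_window_death_probability(
    fit: SupermodelFit,
    profile: PatientProfile,
    tp: float,
    window: float = 5.0,
    tp_max: float | None = None,
) -> float:
    """Probability of dying in (tp, tp + window] given alive at tp.

    Computed as 1 - exp(-[H0(tp+w) - H0(tp)] * exp(lp)) where lp evaluates
    the supermodel linear predictor at landmark time tp for the profile's
    covariates and disease status.  ``tp`` outside the fitted landmark range
    is rejected (no extrapolation); the range defaults to [0, max landmark
    time seen at fitting] inferred from the baseline support.
    """
    if not window > 0:
        raise ValueError("window must be > 0")
    limit = tp_max if tp_max is not None else _fitted_tp_max(fit)
    if tp < 0 or tp > limit + 1e-9:
        raise ValueError(f"tp={tp} outside fitted landmark range [0, {limit}]")
    x = profile.design_row(fit.terms, tp)
    lp = float(x @ fit.coef)
    h = float(fit.cumhaz_at(tp + window) - fit.cumhaz_at(tp))
    prob = 1.0 - np.exp(-h * np.exp(lp))
    return float(np.clip(prob, 0.0, 1.0))


def _fitted_tp_max(fit: SupermodelFit) -> float:
    # conservative default: the latest landmark a prediction can be anchored
    # at is window-length before the last baseline support point; fits store
    # no grid, so fall back to the common 5-year range
    return 5.0


def profile_prediction_curves(
    fit: SupermodelFit,
    profiles: list[PatientProfile],
    tp_grid,
    window: float = 5.0,
    statuses: tuple[str, ...] = DISEASE_STATUSES,
) -> pd.DataFrame:
    """Long-format table of window death probabilities per profile x status x tp."""
    rows = []
    for prof in profiles:
        for status in statuses:
            variant = PatientProfile(prof.covariates, status, prof.label)
            for tp in tp_grid:
                prob = predict_window_death_probability(fit, variant, float(tp), window)
                rows.append(
                    {"profile": prof.label, "status": status, "tp": float(tp),
                     "window": window, "death_probability": prob}
                )
    return pd.DataFrame(rows)
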