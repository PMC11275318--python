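"""Eligibility filtering and construction of the stacked landmark dataset.

Each landmark time ``s`` contributes one counting-process row per patient
still at risk at ``s`` (``t_os > s``, strictly), with delayed entry at ``s``
and administrative censoring at ``s + w``.  LR/NM status is the value known
at ``s`` (onset at or before ``s``, inclusive).  All landmark datasets share
the common event-time axis (years since surgery), which is what allows a
single Breslow baseline across landmarks in the proportional supermodel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import BASELINE_TERMS, encode_covariates, validate_cohort

__all__ = ["LandmarkGrid", "apply_eligibility_filters", "build_landmark_stack", "risk_set_counts"]

#: stack-only design columns appended after the baseline terms
STACK_TERMS = ["hist_lm", "hist_lm_sq", "lr_status", "nm_status", "lm_time", "lm_time_sq"]

#: full supermodel term set in reporting order
ALL_TERMS = BASELINE_TERMS + STACK_TERMS

STACK_META = ["id", "lm_time", "entry", "exit", "event"]


@dataclass(frozen=True)
class LandmarkGrid:
    """Grid of landmark times (years) and the prediction window width."""

    landmark_times: tuple[float, ...] = tuple(np.round(np.arange(0, 5.01, 0.25), 4))
    window_w: float = 5.0

    def __post_init__(self):
        times = np.asarray(self.landmark_times, dtype=float)
        if len(times) == 0 or np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("landmark_times must be non-negative and strictly increasing")
        if not self.window_w > 0:
            raise ValueError("window_w must be > 0")

    @classmethod
    def regular(cls, start: float = 0.0, end: float = 5.0, step: float = 0.25,
                window: float = 5.0) -> "LandmarkGrid":
        n = int(round((end - start) / step))
        times = tuple(np.round(start + step * np.arange(n + 1), 10))
        return cls(landmark_times=times, window_w=window)


def apply_eligibility_filters(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Exclude ineligible patients; return the filtered table and consort counts.

    Exclusion criteria (a patient may meet several; each count includes every
    patient meeting that criterion):

    1. ``lr_nm_before_surgery`` — LR or NM recorded at or before time 0;
    2. ``no_followup`` — missing or non-positive overall-survival time.
    """
    t_os = cohort["t_os"].to_numpy(dtype=float)
    t_lr = cohort["t_lr"].to_numpy(dtype=float)
    t_nm = cohort["t_nm"].to_numpy(dtype=float)

    pre_surgery = (~np.isnan(t_lr) & (t_lr <= 0)) | (~np.isnan(t_nm) & (t_nm <= 0))
    no_followup = np.isnan(t_os) | (t_os <= 0)
    excluded = pre_surgery | no_followup

    counts = {
        "lr_nm_before_surgery": int(pre_surgery.sum()),
        "no_followup": int(no_followup.sum()),
        "total_excluded": int(excluded.sum()),
        "eligible": int((~excluded).sum()),
    }
    return cohort.loc[~excluded].reset_index(drop=True), counts


def build_landmark_stack(cohort: pd.DataFrame, grid: LandmarkGrid) -> pd.DataFrame:
    """Stack the cohort over the landmark grid.

    Returns one row per (patient at risk at s, landmark s) with columns
    ``id, lm_time, entry, exit, event`` followed by the encoded covariates,
    status columns and landmark-time columns (:data:`ALL_TERMS`).

    Conventions: at-risk means ``t_os > s`` strictly; the window is the
    closed interval ``(s, s + w]`` so a death at exactly ``s + w`` counts as
    an event; LR/NM status at ``s`` uses onset ``<= s`` inclusive.
    """
    validate_cohort(cohort)
    enc = encode_covariates(cohort)
    if enc[BASELINE_TERMS].isna().any().any():
        raise ValueError("stack requires complete covariates; impute volume/histology first")

    w = grid.window_w
    pieces = []
    for s in grid.landmark_times:
        at_risk = cohort["t_os"].to_numpy(dtype=float) > s
        if not at_risk.any():
            continue
        sub = cohort.loc[at_risk]
        esub = enc.loc[at_risk]
        t_os = sub["t_os"].to_numpy(dtype=float)
        died = sub["os_status"].to_numpy(dtype=float) == 1.0
        exit_t = np.minimum(t_os, s + w)
        event = (died & (t_os <= s + w)).astype(float)
        t_lr = sub["t_lr"].to_numpy(dtype=float)
        t_nm = sub["t_nm"].to_numpy(dtype=float)
        hist = esub["hist_poor"].to_numpy(dtype=float)
        piece = pd.DataFrame(
            {
                "id": sub["id"].to_numpy(),
                "lm_time": s,
                "entry": s,
                "exit": exit_t,
                "event": event,
            }
        )
        for term in BASELINE_TERMS:
            piece[term] = esub[term].to_numpy(dtype=float)
        piece["hist_lm"] = hist * s
        piece["hist_lm_sq"] = hist * s * s
        piece["lr_status"] = (~np.isnan(t_lr) & (t_lr <= s)).astype(float)
        piece["nm_status"] = (~np.isnan(t_nm) & (t_nm <= s)).astype(float)
        piece["lm_time"] = float(s)
        piece["lm_time_sq"] = float(s) ** 2
        pieces.append(piece)

    cols = STACK_META + [t for t in ALL_TERMS if t not in STACK_META]
    if not pieces:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    stack = pd.concat(pieces, ignore_index=True)
    return stack[cols]


def risk_set_counts(stack: pd.DataFrame) -> pd.DataFrame:
    """Per-landmark risk-set sizes split by LR and by NM status.

    Returns a frame with columns ``lm_time, n_at_risk, n_lr, n_nm``; totals
    are non-increasing in landmark time.
    """
    if len(stack) == 0:
        return pd.DataFrame(columns=["lm_time", "n_at_risk", "n_lr", "n_nm"])
    g = stack.groupby("lm_time", sort=True)
    out = pd.DataFrame(
        {
            "n_at_risk": g.size(),
            "n_lr": g["lr_status"].sum().astype(int),
            "n_nm": g["nm_status"].sum().astype(int),
        }
    ).reset_index()
    return out
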