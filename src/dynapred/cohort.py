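"""Patient-level cohort table: schema, validation, covariate encoding, CSV I/O.

A cohort table holds one row per patient with baseline covariates measured at
surgery, times of the two intermediate events (local recurrence, new
metastatic disease), and the overall-survival endpoint.  All times are in
years since surgery.  Missing values (allowed only for ``volume_cm3`` and
``histology``) are represented as NaN / empty strings on disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# canonical category labels
SEX_LEVELS = ("female", "male")
LOCATION_LEVELS = ("other", "axial", "proximal femur/humerus")
EXCISION_LEVELS = ("wide/radical", "marginal", "intralesional/unknown")
METS_LEVELS = ("no", "yes/possible")
HISTOLOGY_LEVELS = ("good", "poor")

#: columns of a cohort table, in canonical order
COHORT_COLUMNS = [
    "id",
    "age_years",
    "sex",
    "tumor_location",
    "volume_cm3",
    "excision",
    "lung_mets",
    "other_mets",
    "histology",
    "t_lr",
    "t_nm",
    "t_os",
    "os_status",
]

#: design-matrix columns produced by :func:`encode_covariates`, in model order
BASELINE_TERMS = [
    "child",
    "adult",
    "male",
    "loc_axial",
    "loc_proximal_fh",
    "volume_ge200",
    "exc_marginal",
    "exc_intralesional",
    "lung_mets",
    "other_mets",
    "hist_poor",
]

#: tumor-volume dichotomization threshold (cm^3)
VOLUME_THRESHOLD = 200.0


class SchemaError(ValueError):
    """Raised when a cohort table violates the documented schema."""


def empty_cohort() -> pd.DataFrame:
    """Return an empty cohort table with the full schema."""
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in COHORT_COLUMNS})
    df["id"] = df["id"].astype(int)
    for c in ("sex", "tumor_location", "excision", "lung_mets", "other_mets", "histology"):
        df[c] = df[c].astype(object)
    return df


def age_group(age_years: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Classify age into child / adolescent / adult with sex-specific cutoffs.

    Boundaries (age in completed years): males are children through 12 and
    adolescents through 17; females are children through 11 and adolescents
    through 16.
    """
    age = np.asarray(age_years, dtype=float)
    is_male = np.asarray(sex, dtype=object) == "male"
    child_cut = np.where(is_male, 13.0, 12.0)
    adult_cut = np.where(is_male, 18.0, 17.0)
    out = np.where(age < child_cut, "child", np.where(age < adult_cut, "adolescent", "adult"))
    return out.astype(object)


def _indicator(series: pd.Series, level: str, allowed: tuple, name: str) -> np.ndarray:
    vals = series.to_numpy(dtype=object)
    known = pd.isna(vals) | np.isin(vals.astype(str), np.array(allowed, dtype=str))
    if not known.all():
        bad = sorted({str(v) for v, k in zip(vals, known) if not k})
        raise SchemaError(f"unknown category for {name!r}: {bad}")
    return (vals == level).astype(float)


def encode_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Reference-code the baseline covariates into indicator columns.

    Reference categories: adolescent, female, location *other*,
    volume < 200 cm^3, wide/radical excision, no metastases, good histology.

    Missing volume or histology propagates as NaN in the corresponding
    indicator; all other covariates must be present.

    Returns a data frame indexed like ``cohort`` with columns
    :data:`BASELINE_TERMS`.
    """
    if cohort["age_years"].isna().any() or cohort["sex"].isna().any():
        raise SchemaError("age_years and sex must be present for every patient")

    out = pd.DataFrame(index=cohort.index)
    if len(cohort) == 0:
        for term in BASELINE_TERMS:
            out[term] = pd.Series(dtype=float)
        return out

    grp = age_group(cohort["age_years"].to_numpy(), cohort["sex"].to_numpy())
    out["child"] = (grp == "child").astype(float)
    out["adult"] = (grp == "adult").astype(float)
    out["male"] = _indicator(cohort["sex"], "male", SEX_LEVELS, "sex")
    out["loc_axial"] = _indicator(cohort["tumor_location"], "axial", LOCATION_LEVELS, "tumor_location")
    out["loc_proximal_fh"] = _indicator(
        cohort["tumor_location"], "proximal femur/humerus", LOCATION_LEVELS, "tumor_location"
    )
    vol = cohort["volume_cm3"].to_numpy(dtype=float)
    out["volume_ge200"] = np.where(np.isnan(vol), np.nan, (vol >= VOLUME_THRESHOLD).astype(float))
    out["exc_marginal"] = _indicator(cohort["excision"], "marginal", EXCISION_LEVELS, "excision")
    out["exc_intralesional"] = _indicator(
        cohort["excision"], "intralesional/unknown", EXCISION_LEVELS, "excision"
    )
    out["lung_mets"] = _indicator(cohort["lung_mets"], "yes/possible", METS_LEVELS, "lung_mets")
    out["other_mets"] = _indicator(cohort["other_mets"], "yes/possible", METS_LEVELS, "other_mets")
    hist = cohort["histology"].to_numpy(dtype=object)
    hist_ind = _indicator(cohort["histology"], "poor", HISTOLOGY_LEVELS, "histology")
    out["hist_poor"] = np.where(pd.isna(hist), np.nan, hist_ind)
    return out


def validate_cohort(cohort: pd.DataFrame, require_complete: bool = False) -> None:
    """Check schema and event-time ordering invariants; raise SchemaError."""
    missing_cols = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise SchemaError(f"cohort table missing columns: {missing_cols}")
    t_os = cohort["t_os"].to_numpy(dtype=float)
    if np.any(np.isnan(t_os)) or np.any(t_os <= 0):
        raise SchemaError("t_os must be present and > 0 for every patient")
    for col in ("t_lr", "t_nm"):
        t = cohort[col].to_numpy(dtype=float)
        present = ~np.isnan(t)
        if np.any(t[present] < 0) or np.any(t[present] > t_os[present]):
            raise SchemaError(f"{col} must satisfy 0 <= {col} <= t_os when present")
    status = cohort["os_status"].to_numpy(dtype=float)
    if not np.isin(status, (0.0, 1.0)).all():
        raise SchemaError("os_status must be 0 or 1")
    if require_complete:
        if cohort["volume_cm3"].isna().any() or cohort["histology"].isna().any():
            raise SchemaError("cohort contains missing volume or histology")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (empty string = missing) and validate the schema."""
    df = pd.read_csv(path, dtype={"sex": object, "tumor_location": object,
                                  "excision": object, "lung_mets": object,
                                  "other_mets": object, "histology": object})
    validate_cohort(df)
    return df[COHORT_COLUMNS]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
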