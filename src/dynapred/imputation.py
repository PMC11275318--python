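"""Multiple imputation of tumor volume / histological response and
Rubin's-rules pooling of supermodel coefficients.

The imputation engine is deliberately simple and fully documented rather
than a reproduction of any specific package: log tumor volume is imputed
from a Bayesian normal linear model conditional on the always-observed
covariates and the outcome (status + log follow-up time); histological
response is imputed by thresholding a latent continuous draw (probit model
on the same conditioning set).  Each of the ``m`` imputations draws new
model parameters from their approximate posterior, so between-imputation
variability is propagated and Rubin's rules apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import encode_covariates

__all__ = ["ImputationSet", "PooledFit", "impute_missing", "pool_rubin"]

# always-observed indicator columns used as imputation predictors
_PREDICTOR_TERMS = [
    "child",
    "adult",
    "male",
    "loc_axial",
    "loc_proximal_fh",
    "exc_marginal",
    "exc_intralesional",
    "lung_mets",
    "other_mets",
]


@dataclass
class ImputationSet:
    """m completed cohort tables plus provenance."""

    tables: list[pd.DataFrame]
    model: str
    seed: int

    @property
    def m(self) -> int:
        return len(self.tables)


@dataclass
class PooledFit:
    """Rubin's-rules pooled coefficients over m imputation fits."""

    terms: list[str]
    coef: np.ndarray
    within: np.ndarray  # W-bar, per term
    between: np.ndarray  # B, per term
    total: np.ndarray  # T = W-bar + (1 + 1/m) B, per term
    m: int
    df: np.ndarray = field(default=None)

    def hazard_ratio_table(self, level: float = 0.95) -> pd.DataFrame:
        se = np.sqrt(self.total)
        if self.df is not None and np.all(np.isfinite(self.df)):
            q = stats.t.ppf(0.5 + level / 2.0, self.df)
        else:
            q = np.full_like(se, stats.norm.ppf(0.5 + level / 2.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(self.coef) / se
        pval = np.where(se > 0, 2.0 * stats.norm.sf(z), np.nan)
        return pd.DataFrame(
            {
                "term": self.terms,
                "hr": np.exp(self.coef),
                "ci_low": np.exp(self.coef - q * se),
                "ci_high": np.exp(self.coef + q * se),
                "p_value": pval,
            }
        )


def _imputation_design(cohort: pd.DataFrame) -> np.ndarray:
    enc = encode_covariates(cohort)
    cols = [enc[t].to_numpy(dtype=float) for t in _PREDICTOR_TERMS]
    status = cohort["os_status"].to_numpy(dtype=float)
    log_t = np.log(cohort["t_os"].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(cohort))] + cols + [status, log_t])
    for j, name in enumerate(["intercept"] + _PREDICTOR_TERMS + ["os_status", "log_t_os"]):
        if np.isnan(X[:, j]).any():
            raise ValueError(f"imputation predictor {name!r} has missing values")
    return X


def _draw_linear_imputations(X_obs, y_obs, X_mis, rng):
    """Posterior-predictive draws from a normal linear model (flat prior)."""
    n, p = X_obs.shape
    beta_hat, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
    sigma2 = (resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    L = np.linalg.cholesky(xtx_inv + 1e-12 * np.eye(p))
    beta_star = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
    return X_mis @ beta_star + np.sqrt(sigma2) * rng.standard_normal(len(X_mis))


def _draw_probit_imputations(X_obs, y_obs, X_mis, rng):
    """Latent-threshold draws: probit fit, parameter draw, Bernoulli draw.

    Falls back to the marginal rate when the probit fit fails (e.g. perfect
    separation on tiny samples).
    """
    import statsmodels.api as sm

    try:
        with np.errstate(all="ignore"):
            res = sm.Probit(y_obs, X_obs).fit(disp=0, maxiter=100)
            cov = np.asarray(res.cov_params(), dtype=float)
            if not np.all(np.isfinite(cov)):
                raise ValueError("non-finite probit covariance")
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
            beta_star = res.params + L @ rng.standard_normal(len(res.params))
        latent = X_mis @ beta_star + rng.standard_normal(len(X_mis))
        return (latent > 0).astype(float)
    except Exception:
        rate = float(np.mean(y_obs))
        return (rng.uniform(size=len(X_mis)) < rate).astype(float)


def impute_missing(cohort: pd.DataFrame, m: int = 10, seed: int = 0) -> ImputationSet:
    """Produce ``m`` completed copies of the cohort.

    Only ``volume_cm3`` (log-normal model) and ``histology`` (probit latent
    threshold) may be missing.  With no missing values the result is ``m``
    identical copies.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    for col in cohort.columns:
        if col in ("volume_cm3", "histology", "t_lr", "t_nm"):
            continue
        if cohort[col].isna().any():
            raise ValueError(f"missingness allowed only in volume/histology, found in {col!r}")

    rng = np.random.default_rng(seed)
    X = _imputation_design(cohort)
    vol = cohort["volume_cm3"].to_numpy(dtype=float)
    hist = cohort["histology"].to_numpy(dtype=object)
    mis_v = np.isnan(vol)
    mis_h = pd.isna(hist)
    if mis_v.all():
        raise ValueError("volume_cm3 entirely missing: nothing to condition on")
    if mis_h.all():
        raise ValueError("histology entirely missing: nothing to condition on")

    tables = []
    for _ in range(m):
        done = cohort.copy()
        if mis_v.any():
            y = np.log(vol[~mis_v])
            draws = _draw_linear_imputations(X[~mis_v], y, X[mis_v], rng)
            filled = vol.copy()
            filled[mis_v] = np.exp(draws)
            done["volume_cm3"] = filled
        if mis_h.any():
            y = (hist[~mis_h] == "poor").astype(float)
            draws = _draw_probit_imputations(X[~mis_h], y, X[mis_h], rng)
            filled = hist.copy()
            filled[mis_h] = np.where(draws == 1.0, "poor", "good")
            done["histology"] = filled
        tables.append(done)
    return ImputationSet(tables=tables, model="lognormal-volume/probit-histology", seed=seed)


def pool_rubin(fits: list, robust: bool = True, complete_df: float | None = None) -> PooledFit:
    """Pool supermodel fits (or (coef, variance) pairs) by Rubin's rules.

    Pooled coefficient = mean; between-variance B = sample variance across
    fits; total T = W-bar + (1 + 1/m) B.  Degrees of freedom use the
    Barnard-Rubin small-sample adjustment when ``complete_df`` is supplied
    (or inferable as n_patients - p), falling back to the old formula
    (m - 1) / lambda^2, and to the normal reference when B = 0.
    """
    if len(fits) < 2:
        raise ValueError("pooling requires at least 2 fits")

    def unpack(f):
        if hasattr(f, "terms"):
            cov = f.cov_robust if robust else f.cov_model
            return list(f.terms), np.asarray(f.coef, dtype=float), np.diag(cov).copy()
        coef, var = f
        coef = np.asarray(coef, dtype=float)
        return [f"b{i}" for i in range(len(coef))], coef, np.asarray(var, dtype=float)

    terms0, coef0, _ = unpack(fits[0])
    coefs, variances = [], []
    for f in fits:
        terms, coef, var = unpack(f)
        if terms != terms0:
            raise ValueError("all fits must share a common term set")
        coefs.append(coef)
        variances.append(var)

    m = len(fits)
    coefs = np.vstack(coefs)
    variances = np.vstack(variances)
    pooled = coefs.mean(axis=0)
    wbar = variances.mean(axis=0)
    between = coefs.var(axis=0, ddof=1)
    total = wbar + (1.0 + 1.0 / m) * between

    if complete_df is None and hasattr(fits[0], "n_patients"):
        complete_df = max(fits[0].n_patients - len(terms0), 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (1.0 + 1.0 / m) * between / total
        df_old = (m - 1) / lam**2
        if complete_df is not None:
            df_obs = (complete_df + 1.0) / (complete_df + 3.0) * complete_df * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    df = np.where(between == 0.0, np.inf, df)

    return PooledFit(terms=terms0, coef=pooled, within=wbar, between=between,
                     total=total, m=m, df=df)
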