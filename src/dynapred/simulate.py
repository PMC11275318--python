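"""Synthetic multistate cohort generator with known ground truth.

Emulates an osteosarcoma-trial-like cohort: baseline covariates drawn from
published marginal frequencies, intermediate-event (local recurrence, new
metastatic disease) onset as covariate-dependent exponentials, and a death
hazard that is piecewise-constant at baseline, multiplied by baseline
covariate effects and by status effects from the LR/NM onset times onward.

The generative onset/censoring processes are stand-ins: the source analysis
reports effect sizes for the death hazard but no generative model for LR/NM
onset or censoring, so the defaults here are chosen to reproduce realistic
marginal event frequencies and are clearly parameterized for tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    BASELINE_TERMS,
    COHORT_COLUMNS,
    VOLUME_THRESHOLD,
    encode_covariates,
)

__all__ = [
    "SimulationTruth",
    "default_truth",
    "default_frequencies",
    "sample_baseline_covariates",
    "simulate_event_history",
    "inject_missingness",
    "generate_cohort",
]

#: marginal covariate frequencies of the emulated trial population
#: (proportions among observed values; volume/histology missingness is
#: applied separately by :func:`inject_missingness`)
DEFAULT_FREQUENCIES: dict[str, dict[str, float]] = {
    "age_group": {"adolescent": 0.498, "child": 0.224, "adult": 0.278},
    "sex": {"female": 0.412, "male": 0.588},
    "tumor_location": {"other": 0.835, "axial": 0.033, "proximal femur/humerus": 0.132},
    "volume_cat": {"<200": 0.678, ">=200": 0.322},
    "excision": {"wide/radical": 0.817, "marginal": 0.121, "intralesional/unknown": 0.062},
    "lung_mets": {"no": 0.808, "yes/possible": 0.192},
    "other_mets": {"no": 0.961, "yes/possible": 0.039},
    "histology": {"good": 0.521, "poor": 0.479},
}

#: default log hazard ratios on the death hazard (reference = all-zero profile)
DEFAULT_LOG_EFFECTS: dict[str, float] = {
    "child": math.log(0.744),
    "adult": math.log(0.949),
    "male": math.log(1.205),
    "loc_axial": math.log(2.071),
    "loc_proximal_fh": math.log(1.198),
    "volume_ge200": math.log(1.255),
    "exc_marginal": math.log(0.914),
    "exc_intralesional": math.log(1.423),
    "lung_mets": math.log(2.177),
    "other_mets": math.log(1.860),
    "hist_poor": math.log(2.371),
}

# onset hazards are covariate-dependent by default so that baseline risk
# factors also predict who develops intermediate events (as in real cohorts);
# without this, NM would act as outcome-independent noise
DEFAULT_NM_ONSET_EFFECTS = {
    "hist_poor": math.log(2.2),
    "lung_mets": math.log(2.2),
    "other_mets": math.log(1.6),
    "loc_axial": math.log(1.5),
    "volume_ge200": math.log(1.4),
}
DEFAULT_LR_ONSET_EFFECTS = {
    "hist_poor": math.log(1.8),
    "exc_intralesional": math.log(2.2),
    "loc_axial": math.log(2.0),
}


@dataclass(frozen=True)
class SimulationTruth:
    """Generative hazards and true log-effects for a synthetic cohort.

    ``baseline_death_hazard`` is piecewise constant: rate ``rates[j]`` on
    ``[cuts[j], cuts[j+1])`` with an implicit final interval to infinity.
    Status effects ``log_lr_effect`` / ``log_nm_effect`` multiply the death
    hazard from the respective onset time onward.  ``histology_time_effect``
    adds ``b1*t + b2*t**2`` to the log death hazard of poor responders,
    with ``t`` the event time in years.
    """

    baseline_cuts: tuple[float, ...] = (0.0, 1.0, 3.0, 5.0)
    baseline_rates: tuple[float, ...] = (0.012, 0.016, 0.010, 0.006)
    log_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_EFFECTS))
    log_lr_effect: float = math.log(2.634)
    log_nm_effect: float = math.log(8.558)
    histology_time_effect: tuple[float, float] = (0.0, 0.0)
    lr_hazard: float = 0.0115
    nm_hazard: float = 0.038
    lr_onset_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LR_ONSET_EFFECTS))
    nm_onset_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NM_ONSET_EFFECTS))
    censor_hazard: float = 0.135
    admin_censor_time: float = 11.0

    def __post_init__(self):
        if len(self.baseline_cuts) != len(self.baseline_rates):
            raise ValueError("baseline_cuts and baseline_rates must have equal length")
        if self.baseline_cuts[0] != 0.0 or any(
            b <= a for a, b in zip(self.baseline_cuts, self.baseline_cuts[1:])
        ):
            raise ValueError("baseline_cuts must start at 0 and increase strictly")
        if any(r < 0 for r in self.baseline_rates) or self.lr_hazard < 0 or self.nm_hazard < 0:
            raise ValueError("hazard rates must be >= 0")
        if self.censor_hazard < 0:
            raise ValueError("censor_hazard must be >= 0")
        if not self.admin_censor_time > 0:
            raise ValueError("admin_censor_time must be > 0")
        unknown = set(self.log_effects) - set(BASELINE_TERMS)
        unknown |= set(self.lr_onset_effects) - set(BASELINE_TERMS)
        unknown |= set(self.nm_onset_effects) - set(BASELINE_TERMS)
        if unknown:
            raise ValueError(f"log-effect terms not produced by encode_covariates: {sorted(unknown)}")


def default_truth(**overrides) -> SimulationTruth:
    """The default generative truth; keyword overrides replace fields."""
    return replace(SimulationTruth(), **overrides) if overrides else SimulationTruth()


def default_frequencies() -> dict[str, dict[str, float]]:
    return {k: dict(v) for k, v in DEFAULT_FREQUENCIES.items()}


def recovery_truth(**overrides) -> SimulationTruth:
    """Constant-effect truth for quantitative parameter-recovery tests.

    The landmark supermodel freezes LR/NM status at each landmark for the
    whole prediction window, so when onsets are frequent the no-event group
    at ``s`` is contaminated by within-window converters and the status
    coefficients are attenuated relative to the instantaneous generative
    effect (an inherent property of landmarking, not a bug).  Recovery is
    therefore tested in a regime where within-window conversion is rare:
    low, covariate-independent onset hazards.  The death-hazard effects are
    unchanged.
    """
    base = dict(
        # attenuation scales with exp(effect)-1, so the NM onset rate must be
        # small; the LR effect is mild, and a higher LR rate avoids the
        # small-sample bias of a near-empty LR group
        lr_hazard=0.012,
        nm_hazard=0.007,
        lr_onset_effects={},
        nm_onset_effects={},
        histology_time_effect=(0.0, 0.0),
    )
    base.update(overrides)
    return replace(SimulationTruth(), **base)


def _check_frequencies(frequencies: dict) -> None:
    for cov, probs in frequencies.items():
        p = np.array(list(probs.values()), dtype=float)
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-8):
            raise ValueError(
                f"invalid probability vector for covariate {cov!r}: values {list(probs.values())}"
            )


# age ranges (years) per group and sex used to draw a continuous age
_AGE_RANGES = {
    ("male", "child"): (2.0, 13.0),
    ("male", "adolescent"): (13.0, 18.0),
    ("male", "adult"): (18.0, 41.0),
    ("female", "child"): (2.0, 12.0),
    ("female", "adolescent"): (12.0, 17.0),
    ("female", "adult"): (17.0, 41.0),
}

# log-volume draw (cm^3): lognormal truncated to the sampled side of the
# 200 cm^3 threshold, so the dichotomous frequency is matched exactly
_LOGVOL_MEAN = 4.84
_LOGVOL_SD = 1.0


def _draw_volume(rng: np.random.Generator, ge200: np.ndarray) -> np.ndarray:
    z_cut = (math.log(VOLUME_THRESHOLD) - _LOGVOL_MEAN) / _LOGVOL_SD
    u = rng.uniform(size=ge200.shape)
    p_cut = stats.norm.cdf(z_cut)
    # inverse-CDF sampling within the truncated region
    q = np.where(ge200, p_cut + u * (1 - p_cut), u * p_cut)
    return np.exp(_LOGVOL_MEAN + _LOGVOL_SD * stats.norm.ppf(q))


def sample_baseline_covariates(
    truth: SimulationTruth,
    n: int,
    frequencies: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw ``n`` patients' baseline covariates from categorical marginals.

    Each covariate is drawn independently.  Age group is sampled from its
    marginal and converted to a continuous ``age_years`` uniform within the
    sex-specific group range; tumor volume is drawn from a truncated
    lognormal within the sampled side of the 200 cm^3 threshold.

    Returns a cohort table with outcome columns (``t_lr``/``t_nm``/``t_os``/
    ``os_status``) set to NaN — fill them with :func:`simulate_event_history`.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    freqs = frequencies if frequencies is not None else default_frequencies()
    _check_frequencies(freqs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw(cov: str) -> np.ndarray:
        levels = list(freqs[cov].keys())
        p = np.array([freqs[cov][k] for k in levels], dtype=float)
        return rng.choice(np.array(levels, dtype=object), size=n, p=p)

    sex = draw("sex")
    grp = draw("age_group")
    lo = np.array([_AGE_RANGES[(s, g)][0] for s, g in zip(sex, grp)])
    hi = np.array([_AGE_RANGES[(s, g)][1] for s, g in zip(sex, grp)])
    age = rng.uniform(lo, hi) if n else np.empty(0)

    vol_cat = draw("volume_cat")
    volume = _draw_volume(rng, vol_cat == ">=200") if n else np.empty(0)

    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "age_years": age,
            "sex": sex,
            "tumor_location": draw("tumor_location"),
            "volume_cm3": volume,
            "excision": draw("excision"),
            "lung_mets": draw("lung_mets"),
            "other_mets": draw("other_mets"),
            "histology": draw("histology"),
            "t_lr": np.full(n, np.nan),
            "t_nm": np.full(n, np.nan),
            "t_os": np.full(n, np.nan),
            "os_status": np.full(n, np.nan),
        }
    )
    return df[COHORT_COLUMNS]


def _piecewise_cumhaz_inverse(cuts, rates, target):
    """Smallest t with integral of the piecewise-constant rate reaching target."""
    acc = 0.0
    for j, start in enumerate(cuts):
        end = cuts[j + 1] if j + 1 < len(cuts) else math.inf
        seg = rates[j] * (end - start)
        if acc + seg >= target:
            if rates[j] == 0.0:
                acc += seg
                continue
            return start + (target - acc) / rates[j]
        acc += seg
    return math.inf


def _death_time(rng, cuts, rates, lp_mult, t_lr, t_nm, lr_mult, nm_mult, b1, b2, poor, horizon):
    """Draw a death time by thinning against a piecewise-constant envelope.

    The hazard is baseline(t) * lp_mult * lr_mult^{t>=t_lr} * nm_mult^{t>=t_nm}
    * exp(b1*t + b2*t^2) (poor responders only), evaluated up to ``horizon``.
    """
    breaks = sorted({*cuts, t_lr, t_nm, horizon})
    breaks = [b for b in breaks if b < horizon] + [horizon]
    t = 0.0
    for a, b in zip(breaks, breaks[1:]):
        j = np.searchsorted(cuts, a, side="right") - 1
        rate = rates[j] * lp_mult
        if a >= t_lr:
            rate *= lr_mult
        if a >= t_nm:
            rate *= nm_mult
        if poor and (b1 or b2):
            # exp(b1*t+b2*t^2) is convex in t: the max over [a,b] is at an endpoint
            env = rate * max(math.exp(b1 * a + b2 * a * a), math.exp(b1 * b + b2 * b * b))
        else:
            env = rate
        if env <= 0.0:
            continue
        t = a
        while True:
            t += rng.exponential(1.0 / env)
            if t >= b:
                break
            accept = 1.0
            if poor and (b1 or b2):
                accept = rate * math.exp(b1 * t + b2 * t * t) / env
            if rng.uniform() < accept:
                return t
    return math.inf


def simulate_event_history(
    covariates: pd.DataFrame,
    truth: SimulationTruth,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate LR/NM onset, death and censoring for each patient.

    ``covariates`` is a cohort table with baseline columns filled (as from
    :func:`sample_baseline_covariates`).  Returns a completed cohort table:
    ``t_os`` = min(death, random censoring, administrative censoring) with
    ``os_status`` set accordingly, and ``t_lr``/``t_nm`` recorded only when
    the onset occurred on or before ``t_os``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    enc = encode_covariates(covariates)
    Z = enc[BASELINE_TERMS].to_numpy(dtype=float)
    if np.isnan(Z).any():
        raise ValueError("covariates must be complete before simulation (impute or regenerate)")

    beta = np.array([truth.log_effects.get(t, 0.0) for t in BASELINE_TERMS])
    lp_mult = np.exp(Z @ beta)
    lr_mult_lp = np.exp(Z @ np.array([truth.lr_onset_effects.get(t, 0.0) for t in BASELINE_TERMS]))
    nm_mult_lp = np.exp(Z @ np.array([truth.nm_onset_effects.get(t, 0.0) for t in BASELINE_TERMS]))

    n = len(covariates)
    b1, b2 = truth.histology_time_effect
    poor = enc["hist_poor"].to_numpy() == 1.0
    lr_mult = math.exp(truth.log_lr_effect)
    nm_mult = math.exp(truth.log_nm_effect)
    cuts = list(truth.baseline_cuts)
    rates = list(truth.baseline_rates)

    t_lr = np.full(n, np.inf)
    t_nm = np.full(n, np.inf)
    if truth.lr_hazard > 0:
        t_lr = rng.exponential(1.0 / (truth.lr_hazard * lr_mult_lp))
    if truth.nm_hazard > 0:
        t_nm = rng.exponential(1.0 / (truth.nm_hazard * nm_mult_lp))

    t_cens = np.full(n, truth.admin_censor_time)
    if truth.censor_hazard > 0:
        t_cens = np.minimum(t_cens, rng.exponential(1.0 / truth.censor_hazard, size=n))

    t_death = np.empty(n)
    for i in range(n):
        t_death[i] = _death_time(
            rng, cuts, rates, lp_mult[i], t_lr[i], t_nm[i],
            lr_mult, nm_mult, b1, b2, bool(poor[i]), t_cens[i],
        )

    t_os = np.minimum(t_death, t_cens)
    # guard against zero-length follow-up from pathological parameter choices
    t_os = np.maximum(t_os, 1e-9)
    status = (t_death <= t_cens).astype(float)

    out = covariates.copy()
    out["t_os"] = t_os
    out["os_status"] = status
    out["t_lr"] = np.where(t_lr <= t_os, t_lr, np.nan)
    out["t_nm"] = np.where(t_nm <= t_os, t_nm, np.nan)
    return out


def inject_missingness(
    cohort: pd.DataFrame,
    rate_volume: float = 0.177,
    rate_histology: float = 0.027,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Mask volume and histology completely at random at the given rates."""
    if not (0.0 <= rate_volume <= 1.0 and 0.0 <= rate_histology <= 1.0):
        raise ValueError("missingness rates must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    mask_v = rng.uniform(size=n) < rate_volume
    mask_h = rng.uniform(size=n) < rate_histology
    out.loc[mask_v, "volume_cm3"] = np.nan
    out.loc[mask_h, "histology"] = np.nan
    return out


def generate_cohort(
    n: int,
    truth: SimulationTruth | None = None,
    frequencies: dict | None = None,
    missingness: tuple[float, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Convenience pipeline: covariates -> event history -> optional missingness."""
    truth = truth or default_truth()
    rng = np.random.default_rng(seed)
    cov = sample_baseline_covariates(truth, n, frequencies, seed=rng)
    cohort = simulate_event_history(cov, truth, seed=rng)
    if missingness is not None:
        cohort = inject_missingness(cohort, *missingness, seed=rng)
    return cohort
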