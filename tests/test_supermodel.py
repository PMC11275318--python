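import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from dynapred import (
    LandmarkGrid,
    apply_eligibility_filters,
    build_landmark_stack,
    encode_covariates,
    generate_cohort,
)
from dynapred.supermodel import (
    ConvergenceError,
    SupermodelFit,
    breslow_baseline,
    fit_supermodel,
    hazard_ratio_table,
)

from conftest import make_cohort


def brute_partial_loglik(stack: pd.DataFrame, terms, beta) -> float:
    """Breslow log partial likelihood by explicit risk-set enumeration."""
    beta = np.asarray(beta, dtype=float)
    Z = stack[terms].to_numpy(dtype=float)
    entry = stack["entry"].to_numpy(dtype=float)
    exit_ = stack["exit"].to_numpy(dtype=float)
    event = stack["event"].to_numpy(dtype=float) == 1.0
    ll = 0.0
    for t in np.unique(exit_[event]):
        dead = event & (exit_ == t)
        risk = (entry < t) & (t <= exit_)
        ll += Z[dead] @ beta @ np.ones(1) if Z[dead].ndim == 1 else (Z[dead] @ beta).sum()
        ll -= dead.sum() * np.log(np.exp(Z[risk] @ beta).sum())
    return float(ll)


def hand_stack(rows):
    """Minimal stack: rows of (id, entry, exit, event, x)."""
    df = pd.DataFrame(rows, columns=["id", "entry", "exit", "event", "x"])
    return df


def fake_fit(terms, coef, se=None, baseline_times=(), baseline_cumhaz=()):
    coef = np.asarray(coef, dtype=float)
    p = len(coef)
    cov = np.diag(np.asarray(se, dtype=float) ** 2) if se is not None else np.eye(p)
    return SupermodelFit(
        terms=list(terms), coef=coef, cov_model=cov, cov_robust=cov,
        baseline_times=np.asarray(baseline_times, dtype=float),
        baseline_cumhaz=np.asarray(baseline_cumhaz, dtype=float),
        n_patients=p, n_rows=p, n_events=0,
        loglik_null=0.0, loglik_model=0.0, n_iter=0, converged=True,
    )


class TestFitOracles:
    def test_single_landmark_matches_standard_cox(self):
        # supermodel on grid {0} degenerates to an ordinary proportional-
        # hazards fit on the (window-censored) cohort: lifelines oracle
        from lifelines import CoxPHFitter

        cohort, _ = apply_eligibility_filters(generate_cohort(200, seed=7))
        stack = build_landmark_stack(cohort, LandmarkGrid(landmark_times=(0.0,), window_w=5.0))
        fit = fit_supermodel(stack)

        enc = encode_covariates(cohort)
        df = enc.copy()
        df["T"] = np.minimum(cohort["t_os"], 5.0)
        df["E"] = ((cohort["os_status"] == 1.0) & (cohort["t_os"] <= 5.0)).astype(int)
        oracle = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-10})
        np.testing.assert_allclose(
            fit.coef, oracle.params_[fit.terms].to_numpy(), atol=1e-6
        )

    def test_five_row_hand_computed_likelihood(self):
        # events at t=2 (row a, x=1) and t=3 (row c, x=0); risk sets by hand:
        # R(2) = {a, b, c, e}, R(3) = {c, d}
        stack = hand_stack(
            [
                (1, 0.0, 2.0, 1.0, 1.0),   # a
                (2, 0.0, 2.5, 0.0, 0.0),   # b
                (3, 0.0, 3.0, 1.0, 0.0),   # c
                (4, 2.5, 3.5, 0.0, 1.0),   # d
                (5, 1.0, 2.0, 0.0, 1.0),   # e
            ]
        )
        fit = fit_supermodel(stack, terms=["x"])
        b = fit.coef[0]
        import math

        expected = (
            b - math.log(3 * math.exp(b) + 1)   # t=2: a,d excluded(entry 2.5); a,b,c,e
            + 0.0 - math.log(1 + math.exp(b))   # t=3: c,d
        )
        assert fit.loglik_model == pytest.approx(expected, abs=1e-10)
        assert fit.loglik_model == pytest.approx(
            brute_partial_loglik(stack, ["x"], [b]), abs=1e-10
        )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_brute_force_maximization_small_stacks(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        entry = np.round(rng.uniform(0, 1, n), 2)
        exit_ = entry + np.round(rng.uniform(0.2, 3, n), 2)
        event = (rng.uniform(size=n) < 0.6).astype(float)
        stack = pd.DataFrame(
            {
                "id": np.arange(n),
                "entry": entry,
                "exit": exit_,
                "event": event,
                "x": rng.normal(size=n).round(2),
            }
        )
        if stack["event"].sum() == 0:
            stack.loc[0, "event"] = 1.0
        fit = fit_supermodel(stack, terms=["x"])
        res = optimize.minimize_scalar(
            lambda b: -brute_partial_loglik(stack, ["x"], [b]), bounds=(-10, 10),
            method="bounded", options={"xatol": 1e-10},
        )
        assert fit.loglik_model == pytest.approx(-res.fun, abs=1e-4)

    def test_parameter_recovery_nm_effect(self):
        # constant-effect recovery truth (rare within-window conversion, see
        # recovery_truth docstring): NM multiplies the death hazard by 8.558;
        # the supermodel's nm_status coefficient recovers it within 3 robust SE
        from dynapred.simulate import recovery_truth

        cohort, _ = apply_eligibility_filters(generate_cohort(2000, recovery_truth(), seed=13))
        stack = build_landmark_stack(cohort, LandmarkGrid())
        fit = fit_supermodel(stack)
        i = fit.terms.index("nm_status")
        assert abs(fit.coef[i] - np.log(8.558)) <= 3 * fit.se()[i]


class TestFitInvariants:
    def test_model_loglik_at_least_null(self, medium_fit):
        assert medium_fit.loglik_model >= medium_fit.loglik_null
        assert medium_fit.converged

    def test_score_zero_at_optimum(self, medium_stack, medium_fit):
        # numeric directional derivatives of the brute-force PL vanish
        # (central difference cancels the quadratic curvature term)
        beta = medium_fit.coef
        rng = np.random.default_rng(0)
        for _ in range(3):
            d = rng.normal(size=len(beta))
            d /= np.linalg.norm(d)
            eps = 1e-4
            ll_plus = brute_partial_loglik(medium_stack, medium_fit.terms, beta + eps * d)
            ll_minus = brute_partial_loglik(medium_stack, medium_fit.terms, beta - eps * d)
            assert abs(ll_plus - ll_minus) / (2 * eps) < 1e-2

    def test_invariant_to_row_order_and_id_relabeling(self):
        cohort, _ = apply_eligibility_filters(generate_cohort(120, seed=3))
        stack = build_landmark_stack(cohort, LandmarkGrid.regular(0, 2, 0.5))
        fit = fit_supermodel(stack)

        rng = np.random.default_rng(1)
        shuffled = stack.sample(frac=1.0, random_state=4).reset_index(drop=True)
        relabel = dict(zip(cohort["id"], rng.permutation(cohort["id"].to_numpy())))
        shuffled["id"] = shuffled["id"].map(relabel)
        fit2 = fit_supermodel(shuffled)
        np.testing.assert_allclose(fit.coef, fit2.coef, atol=1e-8)
        np.testing.assert_allclose(fit.cov_robust, fit2.cov_robust, atol=1e-8)

    def test_covariances_symmetric_psd(self, medium_fit):
        for cov in (medium_fit.cov_model, medium_fit.cov_robust):
            np.testing.assert_allclose(cov, cov.T, atol=1e-10)
            assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_robust_approaches_model_cov_one_row_per_patient(self):
        # exact equality is an asymptotic statement (meat -> information);
        # at n=1000 independent rows the two agree to within ~25%
        cohort, _ = apply_eligibility_filters(generate_cohort(1000, seed=21))
        stack = build_landmark_stack(cohort, LandmarkGrid(landmark_times=(0.0,), window_w=5.0))
        fit = fit_supermodel(stack)
        rel = np.abs(fit.se(True) - fit.se(False)) / fit.se(False)
        assert rel.max() < 0.25

    def test_robust_inflates_variance_on_stacked_rows(self, medium_fit):
        # patients appear in up to 21 rows: naive variance is anti-conservative
        assert np.median(medium_fit.se(True) / medium_fit.se(False)) > 1.5

    def test_empty_or_eventless_stack_rejected(self):
        stack = hand_stack([(1, 0.0, 1.0, 0.0, 0.5)])
        with pytest.raises(ValueError):
            fit_supermodel(stack, terms=["x"])

    def test_complete_separation_reported(self):
        stack = hand_stack(
            [
                (1, 0.0, 1.0, 1.0, 1.0),
                (2, 0.0, 1.5, 1.0, 1.0),
                (3, 0.0, 2.0, 0.0, 0.0),
                (4, 0.0, 2.5, 0.0, 0.0),
            ]
        )
        with pytest.raises(ConvergenceError):
            fit_supermodel(stack, terms=["x"])

    def test_degenerate_columns_dropped_and_recorded(self):
        cohort = make_cohort(
            [{"t_os": 1.0, "os_status": 1.0}, {"t_os": 2.0}, {"t_os": 3.0, "os_status": 1.0},
             {"t_os": 4.0}, {"histology": "poor", "t_os": 2.5, "os_status": 1.0}]
        )
        stack = build_landmark_stack(cohort, LandmarkGrid(landmark_times=(0.0,), window_w=5.0))
        fit = fit_supermodel(stack)
        assert "lm_time" in fit.dropped_terms
        assert "lr_status" in fit.dropped_terms
        assert "hist_poor" in fit.terms


class TestBreslowBaseline:
    def test_no_events_identically_zero(self):
        stack = hand_stack([(1, 0.0, 1.0, 0.0, 0.5), (2, 0.0, 2.0, 0.0, 1.0)])
        fit = fake_fit(["x"], [0.3])
        times, cumhaz = breslow_baseline(fit, stack)
        assert len(times) == 0 and len(cumhaz) == 0

    def test_single_event_jump_is_one_over_k(self):
        # 1 event among 3 at-risk rows, zero coefficients -> jump 1/3
        stack = hand_stack(
            [(1, 0.0, 1.0, 1.0, 0.2), (2, 0.0, 2.0, 0.0, 0.4), (3, 0.0, 3.0, 0.0, 0.9)]
        )
        fit = fake_fit(["x"], [0.0])
        times, cumhaz = breslow_baseline(fit, stack)
        np.testing.assert_allclose(times, [1.0])
        np.testing.assert_allclose(cumhaz, [1.0 / 3.0])

    def test_hand_computed_jumps_with_delayed_entry(self):
        # t=1: risk {1,2}, jump 1/2; t=2.5: risk {2(exited at 2)? no, 3,4}, d=1
        stack = hand_stack(
            [
                (1, 0.0, 1.0, 1.0, 0.0),
                (2, 0.0, 2.0, 0.0, 0.0),
                (3, 1.5, 2.5, 1.0, 0.0),
                (4, 1.0, 3.0, 0.0, 0.0),
            ]
        )
        fit = fake_fit(["x"], [0.0])
        times, cumhaz = breslow_baseline(fit, stack)
        np.testing.assert_allclose(times, [1.0, 2.5])
        np.testing.assert_allclose(cumhaz, [0.5, 0.5 + 0.5])

    def test_zero_coefficients_equal_nelson_aalen(self, medium_stack):
        from lifelines import NelsonAalenFitter

        terms = ["male"]
        fit = fake_fit(terms, [0.0])
        times, cumhaz = breslow_baseline(fit, medium_stack)
        na = NelsonAalenFitter(nelson_aalen_smoothing=False)
        na.fit(
            medium_stack["exit"],
            event_observed=medium_stack["event"],
            entry=medium_stack["entry"],
        )
        oracle = na.cumulative_hazard_.loc[times, "NA_estimate"].to_numpy()
        np.testing.assert_allclose(cumhaz, oracle, rtol=1e-8)

    def test_fit_stores_matching_baseline(self, medium_fit, medium_stack):
        times, cumhaz = breslow_baseline(medium_fit, medium_stack)
        np.testing.assert_allclose(medium_fit.baseline_times, times)
        np.testing.assert_allclose(medium_fit.baseline_cumhaz, cumhaz, rtol=1e-10)
        assert medium_fit.cumhaz_at(0.0) == 0.0
        assert (np.diff(medium_fit.baseline_cumhaz) >= 0).all()


class TestHazardRatioTable:
    def test_zero_coefficient_hr_one_ci_contains_one(self):
        fit = fake_fit(["male"], [0.0], se=[0.1])
        table = hazard_ratio_table(fit)
        row = table[table["term"] == "male"].iloc[0]
        assert row["hr"] == pytest.approx(1.0)
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_closed_form_ci(self):
        fit = fake_fit(["male"], [0.5], se=[0.1])
        table = hazard_ratio_table(fit, level=0.95)
        row = table[table["term"] == "male"].iloc[0]
        assert row["ci_low"] == pytest.approx(np.exp(0.5 - 1.959964 * 0.1), abs=1e-4)
        assert row["ci_high"] == pytest.approx(np.exp(0.5 + 1.959964 * 0.1), abs=1e-4)

    def test_full_layout_terms_and_references(self, medium_fit):
        table = hazard_ratio_table(medium_fit)
        fitted_rows = table[table["term"] != ""]
        assert set(fitted_rows["term"]) == set(medium_fit.terms)
        refs = table[table["label"].str.endswith("(ref)")]
        assert (refs["hr"] == 1.0).all()
        # reporting order: constant histology effect before its time components
        labels = table["label"].tolist()
        assert labels.index("  Poor - Constant") < labels.index("  Poor - Linear time-varying effect")
        assert labels.index("  Linear t") < labels.index("  Quadratic t^2")

    def test_serialization_roundtrip(self, medium_fit, tmp_path):
        path = tmp_path / "fit.json"
        medium_fit.to_json(path)
        back = SupermodelFit.from_json(path)
        np.testing.assert_allclose(back.coef, medium_fit.coef)
        np.testing.assert_allclose(back.cov_robust, medium_fit.cov_robust)
        np.testing.assert_allclose(back.baseline_cumhaz, medium_fit.baseline_cumhaz)
        assert back.terms == medium_fit.terms
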