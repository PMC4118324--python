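"""Partial-likelihood engines against brute-force and external oracles."""

import subprocess

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

import riskmatch as rm
from riskmatch.counting import IntervalGrid, build_counting_process, exposure_columns
from riskmatch.cox import (
    ConvergenceError,
    MarginalPairCox,
    StratifiedPairCox,
    ph_assumption_check,
)
from riskmatch.matching import RiskSetMatcher
from riskmatch.simulate import simulate_cohort

from test_counting import paired_from


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the package engines)
# ---------------------------------------------------------------------------


def brute_partial_loglik(X, start, stop, event, beta, strata=None):
    """Direct enumeration of the Breslow log partial likelihood."""
    ll = 0.0
    eta = X @ beta
    for e in np.flatnonzero(event):
        t = stop[e]
        at_risk = (start < t) & (t <= stop)
        if strata is not None:
            at_risk &= strata == strata[e]
        ll += eta[e] - logsumexp(eta[at_risk])
    return ll


def brute_score_residuals(X, start, stop, event, beta):
    """Direct per-row score residuals U_i = int (x_i - xbar(t)) dM_i(t)."""
    n, p = X.shape
    r = np.exp(X @ beta)
    U = np.zeros((n, p))
    for e in np.flatnonzero(event):
        t = stop[e]
        at_risk = (start < t) & (t <= stop)
        S0 = r[at_risk].sum()
        xbar = (r[at_risk, None] * X[at_risk]).sum(axis=0) / S0
        U[e] += X[e] - xbar
        U[at_risk] -= (r[at_risk, None] / S0) * (X[at_risk] - xbar)
    return U


def arrays(table, cols):
    return (
        table[cols].to_numpy(dtype=float),
        table["start"].to_numpy(dtype=float),
        table["stop"].to_numpy(dtype=float),
        table["event"].to_numpy(),
    )


@pytest.fixture()
def toy_pairs():
    """Four overlapping pairs, two intervals, mixed events."""
    rows = [
        (0, (0, 0, 0), 5.0, 40.0, 1),
        (1, (0, 0, 0), None, 55.0, 1),
        (2, (0, 0, 0), 12.0, 70.0, 1),
        (3, (0, 0, 0), None, 80.0, 0),
        (4, (1, 0, 0), 20.0, 65.0, 1),
        (5, (1, 0, 0), None, 50.0, 1),
        (6, (1, 0, 0), 30.0, 90.0, 0),
        (7, (1, 0, 0), None, 85.0, 1),
    ]
    pair_rows = [
        (0, 0, 1, 5.0, True),
        (1, 2, 3, 12.0, True),
        (2, 4, 5, 20.0, True),
        (3, 6, 7, 30.0, True),
    ]
    paired = paired_from(rows, pair_rows)
    paired.pairs.loc[paired.pairs.pair_id >= 2, ["z1"]] = 1
    return paired


class TestAgainstBruteForce:
    def test_marginal_maximizer_matches_brute_force(self, toy_pairs):
        grid = IntervalGrid([0.0, 50.0, 100.0])
        table = build_counting_process(toy_pairs, model_family="lwa", grid=grid)
        fit = MarginalPairCox(variant="unadjusted").fit(table)
        X, start, stop, event = arrays(table, exposure_columns(table))
        res = minimize(
            lambda b: -brute_partial_loglik(X, start, stop, event, b),
            np.zeros(X.shape[1]),
            method="BFGS",
            options={"gtol": 1e-10},
        )
        np.testing.assert_allclose(fit.gamma_, res.x, atol=1e-6)

    def test_stratified_maximizer_matches_brute_force(self, toy_pairs):
        grid = IntervalGrid([0.0, 50.0, 100.0])
        table = build_counting_process(toy_pairs, model_family="hp", grid=grid)
        fit = StratifiedPairCox().fit(table)
        cols = [c for i, c in enumerate(exposure_columns(table)) if i in fit._keep]
        X, start, stop, event = arrays(table, cols)
        strata = table["pair_id"].to_numpy()
        res = minimize(
            lambda b: -brute_partial_loglik(X, start, stop, event, b, strata=strata),
            np.zeros(X.shape[1]),
            method="BFGS",
            options={"gtol": 1e-10},
        )
        np.testing.assert_allclose(fit.coef_[fit._keep], res.x, atol=1e-6)

    def test_score_residuals_match_direct_enumeration(self, toy_pairs):
        table = build_counting_process(toy_pairs, model_family="lwa")
        fit = MarginalPairCox(variant="adjusted").fit(table)
        X, start, stop, event = arrays(table, ["exposed", "z1", "z2", "z3"])
        X = X[:, [True, True, False, False]]  # z2, z3 constant -> dropped
        U = brute_score_residuals(X, start, stop, event, fit._beta_active)
        np.testing.assert_allclose(fit._engine.score_residuals(fit._beta_active), U, atol=1e-10)


class TestAgainstExternalEngines:
    def test_point_estimates_and_naive_se_match_lifelines(self, small_cfg):
        lifelines = pytest.importorskip("lifelines")
        cohort = simulate_cohort(small_cfg, seed=3)
        paired = RiskSetMatcher(method=2, random_state=5).match(cohort)
        grid = IntervalGrid([0.0, 250.0, 500.0, 750.0, 1000.0])
        table = build_counting_process(paired, model_family="lwa", grid=grid)
        fit = MarginalPairCox(variant="unadjusted").fit(table)
        df = table.copy()
        df["rowid"] = np.arange(len(df))
        ctv = lifelines.CoxTimeVaryingFitter()
        ecols = exposure_columns(table)
        ctv.fit(
            df[["rowid", "start", "stop", "event"] + ecols],
            id_col="rowid",
            event_col="event",
            start_col="start",
            stop_col="stop",
        )
        np.testing.assert_allclose(fit.gamma_, ctv.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.vcov_naive_)), ctv.standard_errors_.to_numpy(), atol=1e-5
        )

    def test_stratified_estimates_match_lifelines_strata(self, small_cfg):
        lifelines = pytest.importorskip("lifelines")
        cohort = simulate_cohort(small_cfg, seed=3)
        paired = RiskSetMatcher(method=1, random_state=5).match(cohort)
        grid = IntervalGrid([0.0, 500.0, 1000.0])
        table = build_counting_process(paired, model_family="hp", grid=grid)
        fit = StratifiedPairCox().fit(table)
        df = table.copy()
        df["rowid"] = np.arange(len(df))
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(
            df[["rowid", "start", "stop", "event", "pair_id"] + exposure_columns(table)],
            id_col="rowid",
            event_col="event",
            start_col="start",
            stop_col="stop",
            strata=["pair_id"],
        )
        np.testing.assert_allclose(fit.gamma_, ctv.params_.to_numpy(), atol=1e-5)

    def test_cluster_sandwich_matches_r_survival(self, tmp_path, small_cfg):
        cohort = simulate_cohort(small_cfg, seed=11)
        paired = RiskSetMatcher(method=2, random_state=5).match(cohort)
        grid = IntervalGrid([0.0, 300.0, 1000.0])
        table = build_counting_process(paired, model_family="lwa", grid=grid)
        fit = MarginalPairCox(variant="adjusted").fit(table)
        csv = tmp_path / "tab.csv"
        table.to_csv(csv, index=False)
        script = f"""
        library(survival)
        d <- read.csv("{csv}")
        f <- coxph(Surv(start, stop, event) ~ e1 + e2 + z1 + z2 + z3 + cluster(pair_id),
                   data = d, ties = "breslow")
        cat(coef(f), sqrt(diag(f$naive.var)), sqrt(diag(f$var)), sep = "\\n")
        """
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True, check=True
        )
        vals = np.array([float(x) for x in out.stdout.split()])
        coef_r, naive_r, robust_r = vals.reshape(3, 5)
        np.testing.assert_allclose(fit.coef_, coef_r, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.vcov_naive_)), naive_r, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.vcov_robust_)), robust_r, atol=1e-6)


class TestModelContracts:
    def test_time_fixed_and_time_dependent_coding_agree_for_method1(self, small_cfg):
        cohort = simulate_cohort(small_cfg, seed=21)
        paired = RiskSetMatcher(method=1, random_state=2).match(cohort)
        grid = IntervalGrid([0.0, 250.0, 500.0, 750.0, 1000.0])
        td = StratifiedPairCox().fit(
            build_counting_process(paired, model_family="hp", grid=grid)
        )
        tf = StratifiedPairCox().fit(
            build_counting_process(paired, model_family="hp", grid=grid, entry_at_origin=True)
        )
        np.testing.assert_allclose(td.gamma_, tf.gamma_, atol=1e-8)

    def test_unclustered_fit_only_changes_the_variance(self, small_cfg):
        cohort = simulate_cohort(small_cfg, seed=4)
        paired = RiskSetMatcher(method=2, random_state=4).match(cohort)
        table = build_counting_process(paired, model_family="lwa")
        clustered = MarginalPairCox(variant="unadjusted", robust=True).fit(table)
        plain = MarginalPairCox(variant="unadjusted", robust=False).fit(table)
        np.testing.assert_allclose(clustered.gamma_, plain.gamma_, atol=1e-12)
        np.testing.assert_allclose(clustered.vcov_naive_, plain.vcov_naive_, atol=1e-12)
        assert plain.vcov_robust_ is None and clustered.vcov_robust_ is not None

    def test_interaction_model_nests_the_adjusted_model(self, toy_pairs):
        table = build_counting_process(toy_pairs, model_family="lwa")
        adj = MarginalPairCox(variant="adjusted").fit(table)
        inter = MarginalPairCox(variant="interaction").fit(table)
        assert inter.loglik_ >= adj.loglik_ - 1e-10
        # without interaction coefficients the profile effect reduces to gamma
        assert np.allclose(adj.log_hr((1, 1, 1)), adj.gamma_)

    def test_covariate_adjustment_in_stratified_model_is_an_error(self, toy_pairs):
        table = build_counting_process(toy_pairs, model_family="hp")
        with pytest.raises(ValueError, match="stratified"):
            StratifiedPairCox().fit(table, covariates=["z1"])

    def test_monotone_likelihood_is_detected(self):
        paired = paired_from(
            [(0, (0, 0, 0), 2.0, 10.0, 1), (1, (0, 0, 0), None, 20.0, 0)],
            [(0, 0, 1, 2.0, True)],
        )
        table = build_counting_process(paired, model_family="hp")
        fit = StratifiedPairCox().fit(table)
        assert fit.diverged_ and not fit.converged_

    def test_no_events_anywhere_is_an_error(self):
        paired = paired_from(
            [(0, (0, 0, 0), 2.0, 10.0, 0), (1, (0, 0, 0), None, 20.0, 0)],
            [(0, 0, 1, 2.0, True)],
        )
        table = build_counting_process(paired, model_family="hp")
        with pytest.raises(ConvergenceError):
            StratifiedPairCox().fit(table)


class TestProportionalHazardsCheck:
    def _null_pvalues(self, n_reps=15):
        cfg = rm.hr_configuration("constant", n_per_profile=60)
        ps = []
        for seed in range(n_reps):
            cohort = simulate_cohort(cfg, seed=seed)
            paired = RiskSetMatcher(method=2, random_state=seed).match(cohort)
            table = build_counting_process(paired, model_family="lwa")
            fit = MarginalPairCox(variant="unadjusted").fit(table)
            ps.append(ph_assumption_check(table, fit)["p"].iloc[0])
        return np.array(ps)

    def test_null_calibration_under_constant_effect(self):
        ps = self._null_pvalues()
        # under proportional hazards the p-values are roughly uniform
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.05).mean() < 0.35

    def test_power_against_a_monotone_time_varying_effect(self):
        # Harrell's test correlates residuals with time, so a monotone
        # increasing exposure effect is the canonical detectable alternative
        cfg = rm.hr_configuration("increasing", n_per_profile=250)
        rejections = 0
        for seed in range(3):
            cohort = simulate_cohort(cfg, seed=seed)
            paired = RiskSetMatcher(method=2, random_state=seed).match(cohort)
            table = build_counting_process(paired, model_family="lwa")
            fit = MarginalPairCox(variant="unadjusted").fit(table)
            rejections += ph_assumption_check(table, fit)["p"].iloc[0] < 0.05
        assert rejections >= 2

    def test_too_few_events_raise(self):
        paired = paired_from(
            [(0, (0, 0, 0), 2.0, 10.0, 1), (1, (0, 0, 0), None, 20.0, 0)],
            [(0, 0, 1, 2.0, True)],
        )
        table = build_counting_process(paired, model_family="lwa")
        fit = MarginalPairCox(variant="unadjusted", max_iter=5).fit(table)
        with pytest.raises(ValueError):
            ph_assumption_check(table, fit)
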