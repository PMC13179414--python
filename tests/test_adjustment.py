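"""PIM fitting, standardization/augmentation, and sandwich inference."""

import numpy as np
import pytest
from scipy.special import expit, logit

from conftest import make_record
from helpers_oracles import (
    naive_augment,
    naive_pim_score,
    naive_standardize,
    random_records,
)
from winodds import (
    RankDeficientError,
    ScenarioSpec,
    TrialArrays,
    adjusted_inference,
    augment,
    direct_inference,
    fit_pim,
    sandwich_variance,
    score_matrix,
    simulate_trial_arrays,
    standardize,
    win_statistics,
)
from winodds.adjustment import PimFit


def fit_on(recs, p=None):
    data = TrialArrays.from_records(recs)
    X = data.covariates[:, :p] if p else None
    scores = score_matrix(data)
    return data, X, scores, fit_pim(scores, data.arm, X)


class TestFitPim:
    def test_no_covariates_closed_form(self, rng):
        """Without covariates the estimating equations solve to
        tau_A = logit(nu_direct)."""
        recs = random_records(rng, 40)
        data, _, scores, fit = fit_on(recs)
        nu = win_statistics(scores, data.arm).nu_direct
        assert fit.tau_a == pytest.approx(float(logit(nu)), abs=1e-9)
        assert fit.tau_x.size == 0

    def test_all_ties_zero_solution(self):
        recs = [
            make_record(subject_id=k, arm=k % 2, covariates=[0.1 * k],
                        terminal_time=5.0)
            for k in range(8)
        ]
        data, X, scores, fit = fit_on(recs, p=1)
        assert fit.tau_a == pytest.approx(0.0, abs=1e-10)
        assert fit.tau_x[0] == pytest.approx(0.0, abs=1e-10)

    def test_score_vanishes_at_solution(self, rng):
        """The fitted coefficients zero the estimating equations, checked
        by naive pairwise summation."""
        recs = random_records(rng, 30, p=2)
        data, X, scores, fit = fit_on(recs, p=2)
        score = naive_pim_score(scores.scores, data.arm, X, fit.beta)
        assert np.max(np.abs(score)) < 1e-7

    def test_parameter_recovery_gumbel_model(self, rng):
        """Outcomes Y = tau_A A + tau_X' X + Gumbel noise follow a logit
        PIM exactly (Gumbel differences are logistic), so the fit should
        recover the generating coefficients up to sampling error."""
        n, tau_a, tau_x = 600, 0.8, np.array([1.0, -0.5])
        A = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 2))
        y = tau_a * A + X @ tau_x + rng.gumbel(size=n)

        order = np.argsort(np.argsort(y))  # ranks; ordering rule on y
        recs = [
            make_record(subject_id=k, arm=int(A[k]), covariates=X[k],
                        terminal_time=float(order[k] + 1), terminal_event=1)
            for k in range(n)
        ]
        data = TrialArrays.from_records(recs)
        scores = score_matrix(data)  # death-only data: plain ordering of y
        fit = fit_pim(scores, data.arm, data.covariates)
        assert fit.converged
        assert fit.tau_a == pytest.approx(tau_a, abs=0.35)
        assert np.allclose(fit.tau_x, tau_x, atol=0.35)

    def test_constant_covariate_rank_error(self, rng):
        recs = random_records(rng, 20, p=1)
        for r in recs:
            r.covariates = np.array([1.0])
        data = TrialArrays.from_records(recs)
        with pytest.raises(RankDeficientError):
            fit_pim(score_matrix(data), data.arm, data.covariates)


class TestStandardizeAugment:
    def test_zero_coefficients_give_half(self, rng):
        # tau = 0 makes every pair term expit(0) = 1/2
        fit = PimFit(tau_a=0.0, tau_x=np.zeros(2), n_iter=0, converged=True,
                     max_score=0.0)
        X = rng.standard_normal((15, 2))
        assert standardize(fit, X) == pytest.approx(0.5)

    def test_matches_naive_double_loop(self, rng):
        recs = random_records(rng, 30, p=2)
        data, X, scores, fit = fit_on(recs, p=2)
        assert standardize(fit, X) == pytest.approx(
            naive_standardize(fit.tau_a, fit.tau_x, X), rel=1e-12
        )
        assert augment(scores, data.arm, fit, X) == pytest.approx(
            naive_augment(scores.scores, data.arm, fit.tau_a, fit.tau_x, X),
            rel=1e-12,
        )

    def test_stand_equals_aug(self, rng):
        for n, p in [(40, 1), (60, 2)]:
            recs = random_records(rng, n, p=p)
            data, X, scores, fit = fit_on(recs, p=p)
            assert standardize(fit, X) == pytest.approx(
                augment(scores, data.arm, fit, X), abs=1e-9
            )

    def test_constant_h_collapses_to_direct(self, rng):
        """The augmentation weights sum to zero, so any constant pair
        function contributes nothing."""
        recs = random_records(rng, 25)
        data = TrialArrays.from_records(recs)
        scores = score_matrix(data)
        nu_direct = win_statistics(scores, data.arm).nu_direct
        fit = PimFit(0.0, np.zeros(0), 0, True, 0.0)
        for c in (0.0, 0.3, 0.9):
            H = np.full((25, 25), c)
            nu = augment(scores, data.arm, fit, None, h_matrix=H)
            assert nu == pytest.approx(nu_direct, abs=1e-12)


class TestSandwichVariance:
    def test_matches_direct_ustat_variance_without_covariates(self):
        """With no covariates both estimators target the same asymptotic
        variance; the two estimates agree up to O(1/n) factors."""
        data = simulate_trial_arrays(ScenarioSpec(scenario="A", n=1000, seed=5))
        scores = score_matrix(data)
        fit = fit_pim(scores, data.arm, None)
        se_sand = np.sqrt(sandwich_variance(scores, data.arm, fit, None))
        se_direct = direct_inference(scores, data.arm).se_nu
        assert se_sand == pytest.approx(se_direct, rel=0.02)

    def test_positive_on_generic_data(self, rng):
        recs = random_records(rng, 40, p=1)
        data, X, scores, fit = fit_on(recs, p=1)
        assert sandwich_variance(scores, data.arm, fit, X) > 0


class TestAdjustedInference:
    def test_empty_adjustment_collapses_to_direct(self, rng):
        recs = random_records(rng, 40, p=2)
        data = TrialArrays.from_records(recs)
        scores = score_matrix(data)
        est = adjusted_inference(data, adjustment=[], scores=scores)
        direct = direct_inference(scores, data.arm)
        assert est.result.nu_hat == pytest.approx(direct.nu_hat, abs=1e-9)
        assert est.pim.tau_a == pytest.approx(float(logit(direct.nu_hat)), abs=1e-9)

    def test_arm_swap_symmetry(self):
        data = simulate_trial_arrays(ScenarioSpec(scenario="A", n=200, seed=3))
        est = adjusted_inference(data, adjustment=[0, 1])
        flipped = TrialArrays(
            arm=1 - data.arm,
            terminal_time=data.terminal_time,
            terminal_event=data.terminal_event,
            nonfatal_time=data.nonfatal_time,
            nonfatal_event=data.nonfatal_event,
            covariates=data.covariates,
        )
        est_f = adjusted_inference(flipped, adjustment=[0, 1])
        assert est_f.result.nu_hat == pytest.approx(1 - est.result.nu_hat, abs=1e-9)
        assert abs(est_f.result.z) == pytest.approx(abs(est.result.z), rel=1e-6)

    def test_ci_theta_monotone_map(self):
        data = simulate_trial_arrays(ScenarioSpec(scenario="A", n=150, seed=9))
        res = adjusted_inference(data, adjustment=[0]).result
        lo, hi = res.ci_nu
        assert res.ci_theta == (
            pytest.approx(lo / (1 - lo)),
            pytest.approx(hi / (1 - hi)),
        )

    def test_adjustment_reduces_se_with_prognostic_covariates(self):
        """Monte-Carlo sanity: adjusting for all ten covariates of the
        equal-influence scenario should not cost precision."""
        ses_direct, ses_adj = [], []
        for rep in range(10):
            rng = np.random.default_rng(np.random.SeedSequence([42, rep]))
            data = simulate_trial_arrays(ScenarioSpec(scenario="A", n=300), rng)
            scores = score_matrix(data)
            ses_direct.append(direct_inference(scores, data.arm).se_nu)
            ses_adj.append(
                adjusted_inference(data, adjustment=list(range(10)),
                                   scores=scores).se_nu
            )
        assert np.mean(ses_adj) < np.mean(ses_direct)

    def test_bootstrap_variance_method_runs(self):
        data = simulate_trial_arrays(ScenarioSpec(scenario="A", n=120, seed=21))
        est = adjusted_inference(
            data, adjustment=[0], variance_method="bootstrap", n_boot=40, rng=7
        )
        assert est.se_nu > 0
        assert est.result.extra["variance_method"] == "bootstrap"
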