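"""The four ETT estimators against closed-form and simulation oracles."""

import numpy as np
import pandas as pd
import pytest

import ettmachine as em
from ettmachine.cohort import CohortTable
from ettmachine.estimators import (
    fit_outcome_model,
    fit_propensity,
    matching_ett,
    substitution_ett,
    tmle_ett,
    unadjusted_difference,
)
from ettmachine.glm import expit
from ettmachine.inference import eif_values
from ettmachine.preprocess import expand_missingness
from ettmachine.simulate import generate_cohort
from ettmachine.superlearner import glm_only_library
from tests.conftest import saturated_toy_fits


def binary_cohort(y1, y0):
    n1, n0 = len(y1), len(y0)
    df = pd.DataFrame({
        "site_large": [1] * n1 + [0] * n0,
        "y": np.concatenate([y1, y0]).astype(float),
    })
    return CohortTable(df, outcomes={"y": "binary"})


class TestUnadjusted:
    def test_mortality_proportions_example(self):
        """21.1% of 551 large vs 21.7% of 691 small: difference about
        -0.0066 with a CI straddling zero."""
        y1 = np.r_[np.ones(round(0.211 * 551)), np.zeros(551 - round(0.211 * 551))]
        y0 = np.r_[np.ones(round(0.217 * 691)), np.zeros(691 - round(0.217 * 691))]
        est = unadjusted_difference(binary_cohort(y1, y0), "y")
        assert est.psi == pytest.approx(-0.0066, abs=0.002)
        assert est.ci_lo < 0 < est.ci_hi

    def test_identical_groups(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        est = unadjusted_difference(binary_cohort(y, y), "y")
        assert est.psi == 0.0
        assert est.ci_lo <= 0 <= est.ci_hi

    def test_degenerate_perfect_separation(self):
        est = unadjusted_difference(binary_cohort(np.ones(50), np.zeros(60)), "y")
        assert est.psi == 1.0 and est.se == 0.0


class TestOutcomeModel:
    def test_saturated_fit_reproduces_stratum_means(self, toy_frames):
        X, S, y = toy_frames
        qfit, _ = saturated_toy_fits(X, S, y)
        for s in (0, 1):
            for w in (0.0, 1.0):
                emp = y[(S == s) & (X["w"].to_numpy() == w)].mean()
                pred = qfit.predict(pd.DataFrame({"w": [w]}), s)[0]
                assert pred == pytest.approx(emp, abs=1e-10)

    def test_observed_site_evaluation_equals_fitted_values(self, toy_frames):
        X, S, y = toy_frames
        qfit = fit_outcome_model(X, S, y, method="regression")
        eta = qfit.beta[0] + qfit.beta[1] * S + X.to_numpy() @ qfit.beta[2:]
        np.testing.assert_allclose(qfit.predict(X, S), expit(eta), atol=1e-12)

    def test_no_site_effect_mechanism_gives_equal_counterfactuals(self):
        """Under a null mechanism the two counterfactual predictions agree:
        mean |Q(1,C) - Q(0,C)| < 0.02 at n=5000 (median of 10 seeds)."""
        cfg = em.null_config(n_patients=5000)
        gaps = []
        for seed in range(10):
            coh = generate_cohort(cfg, seed=100 + seed)
            d = expand_missingness(coh)
            y, S = coh.outcome_values("overall_mortality"), coh.site
            qfit = fit_outcome_model(d.df, S, y, method="regression")
            gaps.append(np.mean(np.abs(qfit.predict(d.df, 1) - qfit.predict(d.df, 0))))
        assert np.median(gaps) < 0.02

    def test_unknown_method_rejected(self, toy_frames):
        X, S, y = toy_frames
        with pytest.raises(ValueError):
            fit_outcome_model(X, S, y, method="deep-net")


class TestPropensity:
    def test_randomized_site_gives_flat_scores(self):
        cfg = em.null_config(n_patients=5000)
        for mm in cfg.missingness:  # S independent of everything observed
            mm.site_coefficient = 0.0
        coh = generate_cohort(cfg, seed=11)
        d = expand_missingness(coh)
        gfit = fit_propensity(d.df, coh.site, method="superlearner",
                              library=glm_only_library(), seed=0)
        assert np.std(gfit.g) < 0.05
        assert abs(np.mean(gfit.g) - coh.site.mean()) < 0.02

    def test_truncation(self, toy_frames):
        X, S, _ = toy_frames
        gfit = fit_propensity(X, S, method="regression", delta=0.4)
        assert gfit.g.min() >= 0.4 and gfit.g.max() <= 0.6

    def test_duplication_invariance(self, toy_frames):
        X, S, _ = toy_frames
        g1 = fit_propensity(X, S, method="regression").g
        X2 = pd.concat([X, X], ignore_index=True)
        S2 = np.concatenate([S, S])
        g2 = fit_propensity(X2, S2, method="regression").g
        np.testing.assert_allclose(g2[: len(S)], g1, atol=1e-8)

    def test_constant_site_errors(self, toy_frames):
        X, _, _ = toy_frames
        with pytest.raises(ValueError):
            fit_propensity(X, np.ones(len(X)), method="regression")


class TestSubstitution:
    def test_perfect_counterfactual_prediction_gives_zero(self, toy_frames):
        X, S, y = toy_frames

        class Oracle:
            method = "oracle"
            columns = list(X.columns)

            def predict(self, design, s):
                return y[: len(design)]

        # Q(0, C_i) = Y_i for every treated row => psi-hat = 0
        est = substitution_ett(X, S, y, Oracle(), label="oracle")
        assert est.psi == pytest.approx(0.0, abs=1e-15)

    def test_saturated_toy_equals_plugin_formula(self, toy_frames):
        X, S, y = toy_frames
        qfit, _ = saturated_toy_fits(X, S, y)
        w = X["w"].to_numpy()
        pw1 = w[S == 1].mean()
        plug = sum(
            (y[(S == 1) & (w == wi)].mean() - y[(S == 0) & (w == wi)].mean()) * p
            for wi, p in ((1.0, pw1), (0.0, 1 - pw1))
        )
        est = substitution_ett(X, S, y, qfit)
        assert est.psi == pytest.approx(plug, abs=1e-10)


class TestTMLE:
    def test_saturated_toy_is_fixed_point(self, toy, toy_frames):
        """With saturated nuisance fits the targeting step does not move the
        nonparametric MLE: both fluctuation coefficients vanish at the first
        iteration and the estimate equals the plug-in."""
        X, S, y = toy_frames
        qfit, gfit = saturated_toy_fits(X, S, y)
        plug = substitution_ett(X, S, y, qfit).psi
        est, state = tmle_ett(X, S, y, qfit, gfit)
        assert abs(state.eps_history[0][0]) < 1e-5
        assert abs(state.eps_history[0][1]) < 1e-5
        assert est.psi == pytest.approx(plug, abs=1e-6)

    def test_estimating_equation_solved(self, default_cohort, default_design):
        y, S = default_cohort.outcome_values("overall_mortality"), default_cohort.site
        qfit = fit_outcome_model(default_design.df, S, y, method="regression")
        gfit = fit_propensity(default_design.df, S, method="regression")
        est, state = tmle_ett(default_design.df, S, y, qfit, gfit, tol=1e-5)
        assert state.converged
        assert abs(eif_values(state).mean()) < 1e-4  # 10 * tol

    def test_row_order_invariance(self, default_cohort, default_design):
        y, S = default_cohort.outcome_values("overall_mortality"), default_cohort.site
        X = default_design.df
        qfit = fit_outcome_model(X, S, y, method="regression")
        gfit = fit_propensity(X, S, method="regression")
        psi = tmle_ett(X, S, y, qfit, gfit)[0].psi
        perm = np.random.default_rng(0).permutation(len(y))
        Xp = X.iloc[perm].reset_index(drop=True)
        qp = fit_outcome_model(Xp, S[perm], y[perm], method="regression")
        gp = fit_propensity(Xp, S[perm], method="regression")
        psi_p = tmle_ett(Xp, S[perm], y[perm], qp, gp)[0].psi
        assert psi_p == pytest.approx(psi, abs=1e-9)

    def test_affine_relabeling_of_continuous_outcome(self, default_cohort, default_design):
        """Scaling/shifting a continuous outcome scales the ETT accordingly:
        the bounded transform and back-transform commute with affine maps."""
        y = default_cohort.outcome_values("plasma_units")
        S = default_cohort.site
        X = default_design.df

        def run(yv):
            q = fit_outcome_model(X, S, yv, method="regression",
                                  outcome_type="continuous")
            g = fit_propensity(X, S, method="regression")
            return tmle_ett(X, S, yv, q, g)[0].psi

        base = run(y)
        scaled = run(3.0 * y + 5.0)
        assert scaled == pytest.approx(3.0 * base, rel=1e-6)

    def test_nonconvergence_warns(self, toy_frames):
        X, S, y = toy_frames
        qfit = fit_outcome_model(X, S, y, method="regression")
        gfit = fit_propensity(X, S, method="regression")
        with pytest.warns(UserWarning, match="did not converge"):
            est, state = tmle_ett(X, S, y, qfit, gfit, tol=1e-16, max_iter=1)
        assert not state.converged
        assert np.isnan(est.se)


class TestMatching:
    def gfix(self, g, S):
        from ettmachine.estimators import PropensityFit

        return PropensityFit(g=np.asarray(g, dtype=float), delta=0.0,
                             sigma_g=float(np.std(g, ddof=1)),
                             columns=["g"])

    def test_equidistant_tie_averages_both_controls(self):
        S = np.array([1, 0, 0])
        y = np.array([1.0, 0.0, 1.0])
        g = [0.50, 0.48, 0.52]
        est, matched = matching_ett(S, y, self.gfix(g, S), caliper_sd=10.0)
        assert len(matched.matches[0]) == 2
        assert est.psi == pytest.approx(1.0 - 0.5)

    def test_caliper_discard(self):
        S = np.array([1, 1, 0, 0])
        y = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([0.90, 0.50, 0.505, 0.495])
        gfit = self.gfix(g, S)
        est, matched = matching_ett(S, y, gfit, caliper_sd=0.05)
        assert est.n_discarded == 1
        assert 0 in matched.discarded_idx
        # every surviving match respects the caliper, no treated self-matches
        for i, tied in zip(matched.treated_idx, matched.matches):
            assert all(S[j] == 0 for j in tied)
            assert all(abs(g[i] - g[j]) <= matched.caliper + 1e-15 for j in tied)

    def test_identical_score_outcome_multisets_give_zero(self):
        rng = np.random.default_rng(2)
        g_half = rng.uniform(0.2, 0.8, 100)
        y_half = rng.random(100).round()
        S = np.r_[np.ones(100), np.zeros(100)].astype(int)
        g = np.r_[g_half, g_half]
        y = np.r_[y_half, y_half]
        est, _ = matching_ett(S, y, self.gfix(g, S), caliper_sd=1.0)
        assert est.psi == pytest.approx(0.0, abs=1e-12)

    def test_all_discarded_errors(self):
        S = np.array([1, 0, 0])
        y = np.array([1.0, 0.0, 0.0])
        g = np.array([0.9, 0.1, 0.12])
        with pytest.raises(ValueError):
            matching_ett(S, y, self.gfix(g, S), caliper_sd=0.001)


def test_estimators_agree_on_randomized_well_specified_mechanism():
    """With a randomized site model (no confounding) and a correctly
    specifiable outcome model, all four estimators land within 2 max(SE) of
    the Monte-Carlo truth at n=5000."""
    cfg = em.null_config(n_patients=5000, randomized=True)
    for om in cfg.outcomes:
        if om.name == "overall_mortality":
            om.site_coefficient = -0.35
    truth = em.true_ett(cfg, "overall_mortality", n_mc=300_000, seed=50)
    coh = generate_cohort(cfg, seed=51)
    d = expand_missingness(coh)
    y, S = coh.outcome_values("overall_mortality"), coh.site
    qfit = fit_outcome_model(d.df, S, y, method="regression")
    gfit = fit_propensity(d.df, S, method="regression")
    un = unadjusted_difference(coh, "overall_mortality")
    sub = substitution_ett(d.df, S, y, qfit)
    tm, _ = tmle_ett(d.df, S, y, qfit, gfit)
    ma, _ = matching_ett(S, y, gfit)
    max_se = max(un.se, tm.se, ma.se)
    for est in (un, sub, tm, ma):
        assert abs(est.psi - truth.ett) < 2 * max_se, est.estimator
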