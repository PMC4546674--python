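"""Counterfactual residuals, loess smoothing, subgrouping, balance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ettmachine as em
from ettmachine.cohort import CohortTable
from ettmachine.diagnostics import (
    LoessCurve,
    ResidualSet,
    compare_subgroups,
    counterfactual_residuals,
    loess_curves,
    loess_smooth,
    matched_balance,
    partition_by_divergence,
    risk_histogram,
)
from ettmachine.estimators import (
    fit_outcome_model,
    fit_propensity,
    matching_ett,
    substitution_ett,
)
from ettmachine.preprocess import DesignMatrix, expand_missingness


@pytest.fixture(scope="module")
def fitted_default(default_cohort, default_design):
    y = default_cohort.outcome_values("overall_mortality")
    S = default_cohort.site
    qfit = fit_outcome_model(default_design.df, S, y, method="regression")
    return qfit


class TestResiduals:
    @pytest.mark.parametrize("outcome,method", [
        ("overall_mortality", "regression"),
        ("mof", "regression"),
        ("plasma_units", "regression"),
    ])
    def test_treated_mean_residual_equals_substitution_estimate(
            self, default_cohort, default_design, outcome, method):
        y = default_cohort.outcome_values(outcome)
        S = default_cohort.site
        otype = default_cohort.outcomes[outcome]
        qfit = fit_outcome_model(default_design.df, S, y, method=method,
                                 outcome_type=otype)
        qmort = fit_outcome_model(
            default_design.df, S,
            default_cohort.outcome_values("overall_mortality"), method="regression")
        res = counterfactual_residuals(default_cohort, default_design, outcome,
                                       qfit, qmort)
        sub = substitution_ett(default_design.df, S, y, qfit)
        assert res.residual[res.site == 1].mean() == pytest.approx(sub.psi, abs=1e-12)

    def test_binary_residual_bounds(self, default_cohort, default_design, fitted_default):
        res = counterfactual_residuals(default_cohort, default_design,
                                       "overall_mortality", fitted_default,
                                       fitted_default)
        assert res.residual.min() >= -1.0 and res.residual.max() <= 1.0

    def test_perfect_linear_predictor_gives_zero_residuals(self):
        """Continuous outcome exactly linear in the design with no site term:
        the regression fit reproduces it and every residual vanishes."""
        rng = np.random.default_rng(0)
        n = 200
        x = rng.normal(size=n)
        s = rng.integers(0, 2, n)
        y = 2.0 + 1.5 * x
        df = pd.DataFrame({"site_large": s, "y": y, "x": x})
        coh = CohortTable(df, outcomes={"y": "continuous"},
                          covariates={"x": "continuous"})
        d = expand_missingness(coh)
        qfit = fit_outcome_model(d.df, s, y, method="regression",
                                 outcome_type="continuous")
        res = counterfactual_residuals(coh, d, "y", qfit, qfit)
        np.testing.assert_allclose(res.residual, 0.0, atol=1e-9)

    def test_pure_function_of_inputs(self, default_cohort, default_design, fitted_default):
        a = counterfactual_residuals(default_cohort, default_design,
                                     "overall_mortality", fitted_default, fitted_default)
        b = counterfactual_residuals(default_cohort, default_design,
                                     "overall_mortality", fitted_default, fitted_default)
        np.testing.assert_array_equal(a.residual, b.residual)
        np.testing.assert_array_equal(a.risk, b.risk)


class TestLoess:
    def test_constant_reproduced(self):
        rng = np.random.default_rng(1)
        x = rng.random(100)
        curve = loess_smooth(x, np.full(100, 0.7), span=0.5)
        np.testing.assert_allclose(curve.value, 0.7, atol=1e-8)

    def test_linear_exactness(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.random(200))
        y = 2.0 - 3.0 * x
        curve = loess_smooth(x, y, span=0.4)
        interior = (curve.grid > x.min() + 0.05) & (curve.grid < x.max() - 0.05)
        np.testing.assert_allclose(curve.value[interior], 2.0 - 3.0 * curve.grid[interior],
                                   atol=1e-6)

    def test_recovers_smooth_signal(self):
        rng = np.random.default_rng(3)
        x = rng.random(2000)
        y = np.sin(6 * x) + 0.3 * rng.normal(size=2000)
        curve = loess_smooth(x, y, span=0.3)
        interior = (curve.grid > 0.05) & (curve.grid < 0.95)
        assert np.max(np.abs(curve.value[interior] - np.sin(6 * curve.grid[interior]))) < 0.1

    def test_span_validation(self):
        with pytest.raises(ValueError):
            loess_smooth(np.arange(20.0), np.arange(20.0), span=1.5)


def _residual_set(x, r, site=None):
    n = len(x)
    site = np.ones(n, dtype=int) if site is None else site
    return ResidualSet(outcome="y", ids=np.arange(n), site=site,
                       residual=np.asarray(r, dtype=float),
                       risk=np.asarray(x, dtype=float))


class TestPartition:
    def test_null_curve_gives_empty_region(self):
        grid = np.linspace(0, 1, 100)
        curve = LoessCurve(grid=grid, value=np.zeros(100),
                           band_half_width=np.full(100, 0.05), span=0.75)
        res = _residual_set(np.linspace(0, 1, 50), np.zeros(50))
        part = partition_by_divergence(curve, res, threshold=0.05)
        assert part.cutoff is None
        assert len(part.flagged_ids) == 0
        assert len(part.unflagged_ids) == 50

    def test_step_curve_cutoff(self):
        grid = np.linspace(0, 1, 101)
        value = np.where(grid >= 0.5, 0.2, 0.0)
        curve = LoessCurve(grid=grid, value=value,
                           band_half_width=np.full(101, 0.01), span=0.75)
        res = _residual_set(np.linspace(0, 1, 80),
                            np.where(np.linspace(0, 1, 80) >= 0.5, 0.3, -0.1))
        part = partition_by_divergence(curve, res, threshold=0.05)
        assert part.cutoff == pytest.approx(0.5, abs=1e-12)
        flagged_x = res.risk[np.isin(res.ids, part.flagged_ids)]
        assert flagged_x.min() >= 0.5
        # sign split inside the flagged region
        assert len(part.flagged_positive_ids) + len(part.flagged_negative_ids) \
            == len(part.flagged_ids)

    def test_noisy_step_location_recovered(self):
        """Median location error across 20 seeded replicates is within one
        grid cell of the true change point."""
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.random(2000)
            r = np.where(x >= 0.6, 0.25, 0.0) + 0.2 * rng.normal(size=2000)
            res = _residual_set(x, r)
            curve = loess_smooth(x, r, span=0.3)
            part = partition_by_divergence(curve, res, threshold=0.125)
            assert part.cutoff is not None
            errors.append(abs(part.cutoff - 0.6))
        cell = (curve.grid[-1] - curve.grid[0]) / (len(curve.grid) - 1)
        assert np.median(errors) <= cell + 1e-12


class TestCompareSubgroups:
    @staticmethod
    def cohort_and_partition(df, flagged_mask):
        coh = CohortTable(df, outcomes={"y": "binary"},
                          covariates={"x": "continuous", "b": "binary"})
        ids = coh.df["patient_id"].to_numpy()
        from ettmachine.diagnostics import SubgroupPartition

        part = SubgroupPartition(
            cutoff=0.5, site_value=1,
            flagged_ids=ids[flagged_mask], unflagged_ids=ids[~flagged_mask],
            flagged_positive_ids=ids[flagged_mask], flagged_negative_ids=ids[:0])
        return coh, part

    def test_identical_subgroups_null_pvalues(self):
        rng = np.random.default_rng(5)
        half = pd.DataFrame({
            "site_large": 1, "y": rng.integers(0, 2, 100).astype(float),
            "x": rng.normal(size=100), "b": rng.integers(0, 2, 100).astype(float),
        })
        df = pd.concat([half, half], ignore_index=True)
        coh, part = self.cohort_and_partition(df, np.r_[np.ones(100), np.zeros(100)] == 1)
        table = compare_subgroups(coh, part)
        assert (table["p_value"] > 0.999).all()

    def test_chi_square_against_closed_form(self):
        """2x2 table (30,70 / 70,30): chi-square = 32 without continuity
        correction, p ~ 1.5e-8."""
        b = np.r_[np.ones(30), np.zeros(70), np.ones(70), np.zeros(30)]
        df = pd.DataFrame({"site_large": 1, "y": 0.0, "x": 0.0, "b": b})
        df["x"] = np.random.default_rng(0).normal(size=200)
        coh, part = self.cohort_and_partition(df, np.r_[np.ones(100), np.zeros(100)] == 1)
        row = compare_subgroups(coh, part).set_index("variable").loc["b"]
        assert row["statistic"] == pytest.approx(32.0, abs=1e-9)
        assert row["p_value"] == pytest.approx(stats.chi2.sf(32.0, 1), rel=1e-9)

    def test_large_mean_shift_detected(self):
        rng = np.random.default_rng(6)
        x = np.r_[rng.normal(0, 1, 100), rng.normal(3, 1, 100)]
        df = pd.DataFrame({"site_large": 1, "y": 0.0, "x": x,
                           "b": rng.integers(0, 2, 200).astype(float)})
        coh, part = self.cohort_and_partition(df, np.r_[np.ones(100), np.zeros(100)] == 1)
        row = compare_subgroups(coh, part).set_index("variable").loc["x"]
        assert row["p_value"] < 1e-6
        assert row["test"] == "Welch t"


class TestMatchedBalance:
    def test_perfectly_paired_controls_zero_smd(self):
        rng = np.random.default_rng(7)
        n = 60
        X_t = rng.normal(size=(n, 3))
        X = np.vstack([X_t, X_t])  # controls identical to treated
        S = np.r_[np.ones(n), np.zeros(n)].astype(int)
        design = DesignMatrix(pd.DataFrame(X, columns=list("abc")),
                              continuous_cols=list("abc"))
        y = rng.normal(size=2 * n)
        g = np.r_[rng.uniform(0.3, 0.7, n)]
        g = np.r_[g, g]
        from ettmachine.estimators import PropensityFit

        gfit = PropensityFit(g=g, delta=0.0, sigma_g=float(np.std(g, ddof=1)),
                             columns=list("abc"))
        _, matched = matching_ett(S, y, gfit, caliper_sd=1.0)
        report = matched_balance(matched, design, S)
        np.testing.assert_allclose(report.smd["smd_post"], 0.0, atol=1e-10)

    def test_matching_improves_balance_on_confounded_mechanism(self):
        """Post-match mean |SMD| is below pre-match in >= 90% of 50
        replicates of the confounded default mechanism."""
        from ettmachine.superlearner import glm_only_library

        cfg = em.default_config(n_patients=800)
        improved = 0
        for rep in range(50):
            coh = em.generate_cohort(cfg, seed=600 + rep)
            d = expand_missingness(coh)
            S = coh.site
            gfit = fit_propensity(d.df, S, method="regression")
            y = coh.outcome_values("overall_mortality")
            _, matched = matching_ett(S, y, gfit)
            report = matched_balance(matched, d, S)
            improved += (report.smd["smd_post"].abs().mean()
                         < report.smd["smd_pre"].abs().mean())
        assert improved >= 45

    def test_clusters_not_aligned_with_site_when_balanced(self):
        """Two well-separated covariate clusters each mixing both site labels:
        the 2-cluster cut is independent of site (chi-square p > 0.05)."""
        rng = np.random.default_rng(8)
        n = 40
        centers = np.r_[np.zeros(n), np.full(n, 8.0)]
        X = centers[:, None] + rng.normal(size=(2 * n, 2)) * 0.3
        S = np.tile([1, 0], n)  # site alternates within each cluster
        design = DesignMatrix(pd.DataFrame(X, columns=["u", "v"]),
                              continuous_cols=["u", "v"])
        from ettmachine.estimators import MatchedSet

        treated = np.flatnonzero(S == 1)
        controls = np.flatnonzero(S == 0)
        matched = MatchedSet(
            treated_idx=treated,
            matches=[np.array([c]) for c in controls],
            discarded_idx=np.array([], dtype=int), caliper=1.0,
            control_weight={int(c): 1.0 for c in controls})
        report = matched_balance(matched, design, S)
        assert report.cluster_site_p > 0.05
        assert len(np.unique(report.cluster_labels)) == 2


class TestRiskHistogram:
    def test_point_mass_lands_in_single_bin(self):
        res = _residual_set(np.full(77, 0.5), np.zeros(77))
        hist = risk_histogram(res, bins=10)
        counts = hist["count_site_1"].to_numpy()
        assert counts.sum() == 77 and (counts > 0).sum() == 1

    def test_counts_conserved_per_site(self, default_cohort, default_design, fitted_default):
        res = counterfactual_residuals(default_cohort, default_design,
                                       "overall_mortality", fitted_default, fitted_default)
        hist = risk_histogram(res, bins=15)
        assert hist["count_site_1"].sum() == (res.site == 1).sum()
        assert hist["count_site_0"].sum() == (res.site == 0).sum()

    def test_uniform_scores_fill_bins_multinomially(self):
        rng = np.random.default_rng(9)
        res = _residual_set(rng.random(10_000), np.zeros(10_000))
        hist = risk_histogram(res, bins=10)
        sd = np.sqrt(10_000 * 0.1 * 0.9)
        assert np.all(np.abs(hist["count_site_1"] - 1000) < 4 * sd)
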