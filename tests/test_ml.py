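"""Two-level maximum likelihood: estimation, fit statistics, verdicts."""

import numpy as np
import pytest

import ccmtmm as cc
from ccmtmm.exceptions import ConfigError
from ccmtmm.ml import SrmrInputs


@pytest.fixture(scope="module")
def big_fit():
    """One well-powered fit: 500 targets, 10 + 10 raters."""
    spec = cc.aut_study_spec("dttl")
    truth = cc.aut_study_estimates("dttl-ml")
    raters = {"cleverness": [f"a{k}" for k in range(10)],
              "creative_quality": [f"b{k}" for k in range(10)]}
    scores, _ = cc.simulate_ratings(cc.SimulationConfig(
        spec=spec, params=truth, n_targets=500, raters=raters, seed=2024))
    fit = cc.fit_ml(scores, spec)
    return spec, truth, scores, fit


class TestFitMl:
    def test_recovers_generating_parameters(self, big_fit):
        spec, truth, _, fit = big_fit
        layout = cc.ParameterLayout(spec)
        est = layout.flatten(fit.estimates)
        true_vec = layout.flatten(truth)
        assert fit.converged
        # every estimate within 4 standard errors of the generating value
        z = np.abs(est - true_vec) / fit.se
        assert np.all(np.isfinite(fit.se))
        assert np.nanmax(z) < 4.0

    def test_chi2_and_indices_are_sane(self, big_fit):
        _, _, _, fit = big_fit
        assert fit.df == 13
        assert fit.chi2 >= 0
        assert fit.rmsea < 0.05           # model-true data
        assert fit.srmr_within < 0.05 and fit.srmr_between < 0.08
        # gradient norm is absolute on a log-likelihood of order 1e4
        assert fit.grad_norm < 0.05

    def test_target_and_rater_permutation_invariance(self, big_fit):
        spec, _, scores, fit = big_fit
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(scores.data))
        shuffled = cc.ScoreTable(scores.data.iloc[perm], scale=scores.scale)
        fit2 = cc.fit_ml(shuffled, spec, compute_se=False)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)
        layout = cc.ParameterLayout(spec)
        np.testing.assert_allclose(layout.flatten(fit2.estimates),
                                   layout.flatten(fit.estimates), atol=1e-5)

    def test_robust_se_available_and_comparable(self, big_fit):
        spec, _, scores, fit = big_fit
        fit_r = cc.fit_ml(scores, spec, robust_se=True)
        assert fit_r.robust_se is not None
        ratio = fit_r.robust_se / fit_r.se
        ok = np.isfinite(ratio)
        assert ok.mean() > 0.9
        assert np.nanmedian(ratio[ok]) == pytest.approx(1.0, abs=0.35)

    def test_saturated_single_construct_has_zero_chi2(self):
        """1 construct x 3 indicators: 15 statistics, 15 parameters."""
        spec = cc.MTMMModelSpec(variant="dttl", constructs=["c"],
                                indicators={"c": ["i1", "i2", "i3"]})
        truth = cc.ParameterSet(
            spec, mu={"c": [3.0, 3.1, 2.9]}, lam_T={"c": [1.0, 0.7, 0.6]},
            var_eps={"c": [0.3, 0.25, 0.3]}, Sigma_T=[[0.5]],
            Sigma_OM=0.2 * np.eye(2) + 0.05, lam_UM={"c": [1.0, 0.8, 0.9]},
            var_UM=[0.2])
        scores, _ = cc.simulate_ratings(cc.SimulationConfig(
            spec=spec, params=truth, n_targets=300,
            raters={"c": [f"r{k}" for k in range(5)]}, seed=5))
        fit = cc.fit_ml(scores, spec, compute_se=False)
        assert cc.dttl_degrees_of_freedom(spec) == 0
        assert fit.chi2 == pytest.approx(0.0, abs=0.02)
        assert fit.rmsea == 0.0

    def test_zero_unique_method_variance_recovered_at_boundary(self):
        """With no unique-method variance its shared-covariance trace vanishes.

        At var_UM = 0 the unique-method loadings are unidentified (the
        likelihood is flat along lam -> 0 with var_UM trading against the
        reference residual), so the identified functional is the
        unique-method contribution to the *shared* within-row covariances
        lam_i * lam_j * var_UM (i != j), which must be recovered as zero.
        """
        spec = cc.MTMMModelSpec(variant="dttl", constructs=["c"],
                                indicators={"c": ["i1", "i2", "i3"]})
        truth = cc.ParameterSet(
            spec, mu={"c": [3.0, 3.0, 3.0]}, lam_T={"c": [1.0, 0.8, 0.7]},
            var_eps={"c": [0.3, 0.3, 0.3]}, Sigma_T=[[0.5]],
            Sigma_OM=0.15 * np.eye(2), lam_UM={"c": [1.0, 1.0, 1.0]},
            var_UM=[0.0])
        scores, _ = cc.simulate_ratings(cc.SimulationConfig(
            spec=spec, params=truth, n_targets=250,
            raters={"c": [f"r{k}" for k in range(6)]}, seed=8))
        fit = cc.fit_ml(scores, spec, compute_se=False)
        lam = fit.estimates.lam_UM["c"]
        v = fit.estimates.var_UM[0]
        shared = np.abs(np.outer(lam, lam) * v)
        np.fill_diagonal(shared, 0.0)
        assert shared.max() < 0.02
        # and the implied within matrix stays near the diagonal truth
        mom = cc.model_implied_moments(spec, fit.estimates)
        within = mom.Sigma_interaction + mom.Sigma_eps
        np.testing.assert_allclose(within, np.diag([0.3, 0.3, 0.3]), atol=0.05)

    def test_cross_classified_variant_rejected(self, study_scores_dttl):
        scores, _, _ = study_scores_dttl
        with pytest.raises(ConfigError, match="dttl"):
            cc.fit_ml(scores, cc.aut_study_spec("dtcc"))


class TestFitIndices:
    def test_exact_fit_limit(self):
        rmsea, _, _, p = cc.fit_indices(13.0, 13, 1414)
        assert rmsea == 0.0 and p > 0.4

    def test_published_rmsea_formula(self):
        """The N in the RMSEA denominator is the number of level-1 rows."""
        rmsea, _, _, p = cc.fit_indices(207.954, 13, 1414)
        assert round(rmsea, 3) == 0.103
        assert p < 0.001

    def test_zero_df_defines_rmsea_zero(self):
        rmsea, _, _, p = cc.fit_indices(0.0, 0, 1000)
        assert rmsea == 0.0 and p == 1.0

    def test_perfect_moments_give_zero_srmr(self):
        obs = {"c": np.array([[0.4, 0.1], [0.1, 0.3]])}
        between = np.array([[0.5, 0.2], [0.2, 0.4]])
        inputs = SrmrInputs(observed_within=obs, implied_within=obs,
                            observed_between=between, implied_between=between)
        _, sw, sb, _ = cc.fit_indices(5.0, 4, 100, inputs)
        assert sw == 0.0 and sb == 0.0

    def test_negative_df_rejected(self):
        with pytest.raises(ConfigError):
            cc.fit_indices(1.0, -1, 10)


def _fit_like(chi2, df, p_value, rmsea, srmr_w, srmr_b):
    return cc.MLFit(estimates=None, se=np.array([]), se_names=[], loglik=0.0,
                    loglik_saturated=0.0, chi2=chi2, df=df, p_value=p_value,
                    rmsea=rmsea, srmr_within=srmr_w, srmr_between=srmr_b,
                    converged=True, grad_norm=0.0, n_targets=202, n_rows=1414,
                    n_iter=1)


class TestEvaluateFit:
    def test_all_good(self):
        v = cc.evaluate_fit(_fit_like(10, 13, 0.2, 0.04, 0.03, 0.03))
        assert v.overall == "good" and not v.conflicts

    def test_published_conflicting_verdict(self):
        """Exact-fit test and RMSEA reject while both SRMRs look good."""
        v = cc.evaluate_fit(_fit_like(207.954, 13, 1e-6, 0.103, 0.013, 0.040))
        assert v.labels["chi2"] == "reject"
        assert v.labels["rmsea"] == "reject"
        assert v.labels["srmr_within"] == "good"
        assert v.labels["srmr_between"] == "good"
        assert v.overall == "conflicting" and v.conflicts

    def test_cutoffs_are_inclusive(self):
        v = cc.evaluate_fit(_fit_like(10, 13, 0.7, 0.08, 0.05, 0.08))
        assert v.labels["rmsea"] == "acceptable"
        assert v.labels["srmr_within"] == "good"
        assert v.labels["srmr_between"] == "acceptable"
        assert v.overall == "acceptable"
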