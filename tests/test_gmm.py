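import math

import numpy as np
import pytest

from gphurdle.gmm import (
    GMMSpec,
    fit_gmm,
    gmm_asymptotic_variance,
    gmm_objective,
    make_weight,
    moment_dim,
    moment_matrix,
    moment_vector,
    sample_moments,
)
from gphurdle.likelihood import fit_ml
from gphurdle.neldermead import NMConfig
from gphurdle.regression import CountDataset, ThetaVector
from gphurdle.simulate import generate, earlike_preset
from tests.conftest import RECOVERY_TRUTH, recovery_scenario

FIT_CFG = NMConfig(eps=1e-7, max_iter=3000)


def scalar_dataset(y):
    return CountDataset(np.array([y]), np.ones((1, 1)), np.ones((1, 1)))


class TestMomentVector:
    def test_zero_when_residuals_vanish(self):
        h = moment_vector(2.0, np.array([1.0, 3.0]), None, g1_i=2.0, g2_i=4.0)
        np.testing.assert_array_equal(h, np.zeros(4))

    def test_scalar_covariate_oracle(self):
        """With w=1/2, mu=1, alpha=0 the residuals use the summation-oracle
        g1 and g2 of the single-cell hurdle law."""
        theta = ThetaVector(0.0, np.array([0.0]), np.array([0.0]))
        ds = scalar_dataset(3)
        h_n, feasible = sample_moments(ds, theta)
        assert feasible
        g1 = 0.5 / (1.0 - math.exp(-1.0))
        # oracle second raw moment: truncated Poisson(1) has E[Y^2|Y>0] = 2/(1-e^-1)
        g2 = 0.5 * 2.0 / (1.0 - math.exp(-1.0))
        np.testing.assert_allclose(h_n, [3 - g1, 3 - g1, 9 - g2, 9 - g2], rtol=1e-9)

    def test_n_one_equals_single_vector(self):
        theta = ThetaVector(0.1, np.array([0.2]), np.array([-0.1]))
        ds = scalar_dataset(2)
        from gphurdle.regression import moment_g1_g2

        g1, g2, _ = moment_g1_g2(theta, ds)
        h = moment_vector(2.0, np.array([1.0, 1.0]), theta, g1[0], g2[0])
        h_n, _ = sample_moments(ds, theta)
        np.testing.assert_allclose(h_n, h)

    def test_duplication_invariance(self, recovery_dataset):
        theta = ThetaVector.unpack(RECOVERY_TRUTH, 2, 2)
        h1, _ = sample_moments(recovery_dataset, theta)
        doubled = CountDataset(
            np.concatenate([recovery_dataset.y] * 2),
            np.vstack([recovery_dataset.x_design] * 2),
            np.vstack([recovery_dataset.z_design] * 2),
        )
        h2, _ = sample_moments(doubled, theta)
        np.testing.assert_allclose(h1, h2, rtol=1e-12)

    def test_lln_rate(self):
        """|h_n| at the truth shrinks roughly like n^{-1/2}."""
        theta = ThetaVector.unpack(RECOVERY_TRUTH, 2, 2)
        norms = {}
        for n in (500, 8000):
            vals = [
                np.linalg.norm(sample_moments(generate(recovery_scenario(seed=s, n=n)), theta)[0])
                for s in range(8)
            ]
            norms[n] = np.mean(vals)
        assert norms[8000] < norms[500]
        assert norms[8000] < norms[500] / 2.0  # expected factor 4, allow slack


class TestObjectiveAndWeights:
    def test_objective_is_quadratic_form(self, recovery_dataset):
        theta = ThetaVector.unpack(RECOVERY_TRUTH, 2, 2)
        h_n, _ = sample_moments(recovery_dataset, theta)
        assert gmm_objective(recovery_dataset, theta) == pytest.approx(float(h_n @ h_n))

    def test_identity_weight_dimension(self, recovery_dataset):
        W = make_weight(recovery_dataset, ThetaVector.unpack(RECOVERY_TRUTH, 2, 2))
        assert W.shape == (8, 8)
        np.testing.assert_array_equal(W, np.eye(8))

    def test_fixed_weight_must_be_psd(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            GMMSpec(weight_strategy="fixed", W=np.array([[1.0, 0.0], [0.0, -1.0]]))

    def test_shared_covariates_make_sigma_singular(self):
        """x = z duplicates moment rows; the two-step weight must fall back
        to a pseudo-inverse without error."""
        ds = generate(earlike_preset(seed=2))
        ml = fit_ml("gphr", ds, nm_config=FIT_CFG)
        H, _ = moment_matrix(ds, ml.theta_hat)
        Sigma = H.T @ H / ds.n
        assert np.linalg.matrix_rank(Sigma, tol=1e-8) <= Sigma.shape[0] // 2
        W = make_weight(ds, ml.theta_hat, strategy="two_step")
        assert np.all(np.isfinite(W))

    def test_infeasible_theta_penalized(self, recovery_dataset):
        bad = ThetaVector(-5.0, np.array([2.0, 0.0]), np.zeros(2))
        assert gmm_objective(recovery_dataset, bad) == pytest.approx(1e10)


class TestFitGMM:
    def test_descent_from_init(self, recovery_dataset):
        ml = fit_ml("gphr", recovery_dataset, nm_config=FIT_CFG)
        fit = fit_gmm(recovery_dataset, init=ml.theta_hat, nm_config=FIT_CFG)
        q_init = gmm_objective(recovery_dataset, ml.theta_hat)
        assert fit.objective <= q_init + 1e-12

    def test_quasi_aic_labelled(self, recovery_dataset):
        ml = fit_ml("gphr", recovery_dataset, nm_config=FIT_CFG)
        fit = fit_gmm(recovery_dataset, init=ml.theta_hat, nm_config=FIT_CFG)
        assert fit.aic_kind == "quasi"
        assert fit.aic == pytest.approx(-2.0 * fit.loglik + 2.0 * fit.n_params)

    def test_two_step_runs_and_descends(self, recovery_dataset):
        ml = fit_ml("gphr", recovery_dataset, nm_config=FIT_CFG)
        spec = GMMSpec(weight_strategy="two_step")
        fit = fit_gmm(recovery_dataset, init=ml.theta_hat, spec=spec, nm_config=FIT_CFG)
        assert fit.converged and np.all(np.isfinite(fit.packed()))

    def test_augmented_zero_moment_dimension(self, recovery_dataset):
        spec = GMMSpec(augment_zero_moment=True)
        theta = ThetaVector.unpack(RECOVERY_TRUTH, 2, 2)
        h_n, _ = sample_moments(recovery_dataset, theta, spec=spec)
        assert len(h_n) == moment_dim("gphr", recovery_dataset, spec) == 10


class TestMonteCarloProperties:
    def test_two_step_efficiency_and_sandwich_calibration(self):
        """Re-weighting by the inverse moment covariance is more efficient
        than the identity weight, and the sandwich variance predicts the
        estimator's sampling spread.

        Second-moment conditions are heavy-tailed at this sample size, so
        both checks use robust (median-based) spread: occasional divergent
        two-step replicates make raw variances uninformative (see the
        methods note).
        """
        R, n = 60, 2000
        identity_est, two_step_est = [], []
        for r in range(R):
            ds = generate(recovery_scenario(seed=r, n=n))
            ml = fit_ml("gphr", ds, nm_config=FIT_CFG)
            identity_est.append(fit_gmm(ds, init=ml.theta_hat, nm_config=FIT_CFG).packed())
            two_step_est.append(
                fit_gmm(
                    ds, init=ml.theta_hat,
                    spec=GMMSpec(weight_strategy="two_step"), nm_config=FIT_CFG,
                ).packed()
            )
        mad = lambda E: np.median(np.abs(E - np.median(E, axis=0)), axis=0)
        spread_id = mad(np.array(identity_est))
        spread_2s = mad(np.array(two_step_est))
        assert spread_2s.sum() <= 1.10 * spread_id.sum(), (spread_2s, spread_id)

        # sandwich prediction vs Monte-Carlo spread of the identity-weight
        # estimator (robust sd = 1.4826 * MAD), componentwise within 1.5x
        ds = generate(recovery_scenario(seed=999, n=n))
        diag = gmm_asymptotic_variance(ds, ThetaVector.unpack(RECOVERY_TRUTH, 2, 2))
        pred_sd = np.sqrt(np.diag(diag.Gamma_hat) / n)
        ratio = (1.4826 * spread_id) / pred_sd
        assert np.all((ratio > 1 / 1.5) & (ratio < 1.5)), ratio


class TestAsymptoticVariance:
    def test_sandwich_simplifies_under_efficient_weight(self, recovery_dataset):
        """With W = Sigma^-1 the sandwich collapses to (G' Sigma^-1 G)^-1."""
        ml = fit_ml("gphr", recovery_dataset, nm_config=FIT_CFG)
        spec = GMMSpec(weight_strategy="two_step")
        fit = fit_gmm(recovery_dataset, init=ml.theta_hat, spec=spec, nm_config=FIT_CFG)
        diag = gmm_asymptotic_variance(recovery_dataset, fit.theta_hat, spec=spec)
        W = np.linalg.pinv(diag.Sigma_hat, rcond=1e-10, hermitian=True)
        simple = np.linalg.pinv(diag.G.T @ W @ diag.G, rcond=1e-10)
        np.testing.assert_allclose(diag.Gamma_hat, simple, atol=1e-8 * max(1.0, np.abs(simple).max()))

    def test_shared_covariates_underidentification_surfaced(self):
        ds = generate(earlike_preset(seed=4))
        ml = fit_ml("gphr", ds, nm_config=FIT_CFG)
        diag = gmm_asymptotic_variance(ds, ml.theta_hat)
        assert diag.jacobian_rank < len(ml.packed())

    def test_distinct_covariates_fully_identified(self, recovery_dataset):
        theta = ThetaVector.unpack(RECOVERY_TRUTH, 2, 2)
        diag = gmm_asymptotic_variance(recovery_dataset, theta)
        assert diag.jacobian_rank == len(RECOVERY_TRUTH)
        assert np.all(np.diag(diag.Gamma_hat) >= 0)
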