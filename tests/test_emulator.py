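"""Gaussian-process emulator: kernel, fitting, prediction, serialization."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioemu.emulator import GaussianProcessEmulator, correlation_matrix, _regressors

HYPOTHESIS = dict(deadline=None, max_examples=25, derandomize=True)


class TestCorrelationMatrix:
    def test_unit_at_zero_distance(self):
        x = np.array([[0.2, 0.4, 0.1, 0.9, 0.5, 0.3]])
        assert correlation_matrix(x, x, np.ones(6))[0, 0] == pytest.approx(1.0)

    def test_one_correlation_length_away(self):
        delta = np.array([0.5, 1, 1, 1, 1, 1])
        x1 = np.zeros((1, 6))
        x2 = np.zeros((1, 6))
        x2[0, 0] = 0.5
        assert correlation_matrix(x1, x2, delta)[0, 0] == pytest.approx(np.exp(-1.0))

    def test_positive_definite_with_nugget(self):
        rng = np.random.default_rng(1)
        x = rng.random((50, 6))
        c = correlation_matrix(x, x, np.full(6, 0.5)) + 1e-8 * np.eye(50)
        assert np.linalg.eigvalsh(c).min() > 0

    @given(seed=st.integers(0, 1000))
    @settings(**HYPOTHESIS)
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((8, 6))
        c = correlation_matrix(x, x, rng.uniform(0.1, 3.0, 6))
        assert np.allclose(c, c.T)
        assert np.all(c > 0) and np.all(c <= 1.0 + 1e-15)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(np.zeros((2, 6)), np.zeros((2, 6)), np.zeros(6))


class TestFit:
    def test_linear_function_recovered_by_mean(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 6))
        y = 2.0 + 3.0 * X[:, 0]
        em = GaussianProcessEmulator(n_restarts=3, random_state=0).fit(X, y)
        assert em.beta_[0] == pytest.approx(2.0, abs=1e-4)
        assert em.beta_[1] == pytest.approx(3.0, abs=1e-4)
        assert np.allclose(em.beta_[2:], 0.0, atol=1e-4)
        xs = rng.random((10, 6))
        assert np.allclose(em.predict(xs), 2.0 + 3.0 * xs[:, 0], atol=1e-6)

    def test_interpolates_design_points(self):
        rng = np.random.default_rng(3)
        X = rng.random((10, 6))
        y = np.sin(2 * X[:, 0]) + X[:, 1] ** 2
        em = GaussianProcessEmulator(
            n_restarts=3, estimate_nugget=False, nugget=1e-8,
            delta_bounds=(0.1, 2.0),
        ).fit(X, y)
        pred, sd = em.predict(X, return_std=True)
        assert np.max(np.abs(pred - y)) < 1e-6 * np.ptp(y)
        # at a design point the variance collapses to the nugget floor:
        # sigma2*(1+ng - 1/(1+ng)) ~ 2*ng*sigma2
        assert np.all(sd**2 <= 2.2 * em.nugget_ * em.sigma2_ + 1e-12)

    def test_gls_matches_independent_formula(self):
        """Brute-force linear-algebra oracle on a 5-point toy problem."""
        rng = np.random.default_rng(4)
        X = rng.random((12, 6))
        y = rng.normal(size=12)
        delta = np.full(6, 0.8)
        nugget = 1e-8
        em = GaussianProcessEmulator()
        em.nugget_ = nugget
        H = _regressors(X)
        _, beta, ssq, _, _, _, _ = em._gls(delta, nugget, X, y, H)
        # independent dense-inverse computation
        A = correlation_matrix(X, X, delta) + nugget * np.eye(12)
        Ainv = np.linalg.inv(A)
        beta_direct = np.linalg.solve(H.T @ Ainv @ H, H.T @ Ainv @ y)
        resid = y - H @ beta_direct
        ssq_direct = resid @ Ainv @ resid
        assert np.allclose(beta, beta_direct, atol=1e-8)
        assert ssq == pytest.approx(ssq_direct, rel=1e-8)

    def test_requires_enough_points_and_unique_rows(self):
        X = np.random.default_rng(0).random((7, 6))
        with pytest.raises(ValueError):
            GaussianProcessEmulator().fit(X, np.ones(7))
        X10 = np.vstack([X, X[:3]])
        with pytest.raises(ValueError):
            GaussianProcessEmulator().fit(X10, np.ones(10))


class TestPredict:
    def test_reverts_to_mean_function_far_away(self):
        rng = np.random.default_rng(5)
        X = 0.1 * rng.random((20, 6))
        y = 1.0 + X[:, 0] + 0.1 * np.sin(20 * X[:, 1])
        em = GaussianProcessEmulator(n_restarts=3, delta_bounds=(0.01, 0.2),
                                     estimate_nugget=False).fit(X, y)
        far = np.full((1, 6), 50.0)
        mean, sd = em.predict(far, return_std=True)
        h = np.concatenate([[1.0], far[0]])
        assert mean[0] == pytest.approx(h @ em.beta_, rel=1e-6)
        prior_sd = np.sqrt(em.sigma2_ * (1 + em.nugget_))
        assert sd[0] >= prior_sd  # at least prior level (plus mean uncertainty)

    def test_coordinate_permutation_equivariance(self, toy_surface):
        f, X, em = toy_surface
        perm = [3, 1, 0, 5, 4, 2]
        em_p = GaussianProcessEmulator(n_restarts=1, random_state=0,
                                       estimate_nugget=False)
        # refit with permuted columns but identical hyperparameters
        payload = json.loads(em.to_json())
        payload["X"] = np.array(payload["X"])[:, perm].tolist()
        payload["delta"] = np.array(payload["delta"])[perm].tolist()
        em_p = GaussianProcessEmulator.from_json(json.dumps(payload))
        xs = np.random.default_rng(6).random((15, 6))
        assert np.allclose(em.predict(xs), em_p.predict(xs[:, perm] @ np.eye(6)),
                           atol=1e-8)

    def test_extra_design_point_never_inflates_variance(self):
        """At fixed hyperparameters, conditioning on one more run can only
        reduce predictive uncertainty (on the correlation scale)."""
        rng = np.random.default_rng(7)
        X = rng.random((31, 6))
        y = np.sin(3 * X[:, 0]) + X[:, 1] * X[:, 2]
        small = GaussianProcessEmulator(n_restarts=3, estimate_nugget=False).fit(
            X[:30], y[:30]
        )
        payload = json.loads(small.to_json())
        payload["X"], payload["y"] = X.tolist(), y.tolist()
        bigger = GaussianProcessEmulator.from_json(json.dumps(payload))
        xs = rng.random((50, 6))
        _, s1 = small.predict(xs, return_std=True)
        _, s2 = bigger.predict(xs, return_std=True)
        assert np.all(s2**2 / bigger.sigma2_ <= s1**2 / small.sigma2_ + 1e-8)

    def test_heldout_calibration(self, toy_surface):
        """~95% of standardized errors within +/-2 for a well-specified fit."""
        f, X, em = toy_surface
        xs = np.random.default_rng(8).random((400, 6))
        mean, sd = em.predict(xs, return_std=True)
        z = (f(xs) - mean) / sd
        frac = np.mean(np.abs(z) < 2.0)
        assert 0.88 <= frac <= 1.0

    def test_delta_recovery_from_known_process(self):
        """Hyperparameter search recovers generating correlation lengths
        within a factor of two at n=200."""
        rng = np.random.default_rng(9)
        X = rng.random((200, 6))
        true_delta = np.array([0.3, 0.6, 1.0, 0.4, 2.0, 0.8])
        C = correlation_matrix(X, X, true_delta) + 1e-10 * np.eye(200)
        L = np.linalg.cholesky(C)
        y = 5.0 + X @ np.array([1.0, -2.0, 0.5, 0.0, 1.0, 0.0]) + 2.0 * (
            L @ rng.standard_normal(200)
        )
        em = GaussianProcessEmulator(n_restarts=5, random_state=0,
                                     estimate_nugget=False).fit(X, y)
        ratio = em.delta_ / true_delta
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, toy_surface, tmp_path):
        _, X, em = toy_surface
        path = tmp_path / "emulator.json"
        em.to_json(path)
        back = GaussianProcessEmulator.from_json(path)
        xs = np.random.default_rng(10).random((20, 6))
        m1, c1 = em.predict(xs, return_cov=True)
        m2, c2 = back.predict(xs, return_cov=True)
        assert np.allclose(m1, m2, atol=1e-10)
        assert np.allclose(c1, c2, atol=1e-10)
        assert back.delta_ == pytest.approx(em.delta_)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(11)
        X = rng.random((25, 6))
        y = np.cos(4 * X[:, 0]) + X[:, 1]
        em1 = GaussianProcessEmulator(n_restarts=4, random_state=3).fit(X, y)
        em2 = GaussianProcessEmulator(n_restarts=4, random_state=3).fit(X, y)
        assert np.array_equal(em1.delta_, em2.delta_)
        assert em1.sigma2_ == em2.sigma2_
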