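"""Gaussian-process emulator with a linear mean and Gaussian covariance.

One emulator is fitted per scalar simulator output.  The statistical
model is the standard computer-experiment formulation: given design
inputs X (n x p, here p = 6) and outputs y,

    f(x) | beta, sigma2, delta ~ GP( h(x)' beta, sigma2 * c(x, x') ),
    h(x) = (1, x_1, ..., x_p)',     q = p + 1 regressors,
    c(x, x') = exp( -sum_j ((x_j - x'_j) / delta_j)^2 ),

with the weak prior p(beta, sigma2) proportional to 1/sigma2.  beta and
sigma2 are marginalised analytically; the correlation lengths delta are
set to the mode of their concentrated log posterior, found by bounded
multi-start quasi-Newton search in log space.  The posterior predictive
is Student-t with n - q degrees of freedom; with the design sizes used
here (n - q ~ 200) it is reported as a Gaussian whose covariance uses
the sigma2 estimate on the t scale (divisor n - q - 2), which is also
the convention required by the Mahalanobis-distance reference
distribution used in validation.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
from scipy.linalg import cho_solve
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConditioningError

__all__ = [
    "GaussianProcessEmulator",
    "correlation_matrix",
    "fit_emulator",
    "predict",
]


def correlation_matrix(x1: np.ndarray, x2: np.ndarray, delta) -> np.ndarray:
    """Gaussian (squared-exponential) correlation between two point sets.

    Entries are exp(-sum_j ((x1_ij - x2_kj)/delta_j)^2), in (0, 1].
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0) or not np.all(np.isfinite(delta)):
        raise ValueError("correlation lengths must be positive and finite")
    u1 = x1 / delta
    u2 = x2 / delta
    d2 = (
        np.sum(u1**2, axis=1)[:, None]
        + np.sum(u2**2, axis=1)[None, :]
        - 2.0 * (u1 @ u2.T)
    )
    return np.exp(-np.maximum(d2, 0.0))


def _regressors(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(x)
    return np.hstack([np.ones((x.shape[0], 1)), x])


class GaussianProcessEmulator(RegressorMixin, BaseEstimator):
    """GP emulator of one simulator output (linear mean, Gaussian kernel).

    Parameters
    ----------
    delta_bounds : (float, float)
        Search bounds for each correlation length on the normalized input
        scale.
    n_restarts : int
        Number of starting points of the hyperparameter search (the first
        start is all-ones; the rest are Latin-hypercube draws in log
        space, reproducible via ``random_state``).
    nugget : float
        Jitter added to the correlation diagonal.  With
        ``estimate_nugget=True`` (default) it is the starting value of a
        jointly MAP-estimated noise fraction, which absorbs the small
        numerical noise of the simulator outputs (integration grid,
        coupling-scan resolution) and keeps predictive variances
        calibrated; with ``estimate_nugget=False`` it is fixed and only
        escalated by factors of 10 up to ``max_nugget`` if the Cholesky
        factorisation fails.
    output_name : str, optional
        Label carried through to serialized emulators and reports.

    Attributes (after fit)
    ----------------------
    beta_ : (q,) generalised-least-squares mean coefficients
    delta_ : (p,) correlation lengths at the posterior mode
    sigma2_ : scalar variance estimate (divisor n - q - 2)
    nugget_ : jitter actually used
    X_, y_ : the design data
    """

    def __init__(
        self,
        delta_bounds=(0.03, 30.0),
        n_restarts: int = 10,
        nugget: float = 1e-8,
        max_nugget: float = 1e-4,
        estimate_nugget: bool = True,
        nugget_bounds=(1e-12, 1.0),
        random_state: int = 0,
        output_name: Optional[str] = None,
    ):
        self.delta_bounds = delta_bounds
        self.n_restarts = n_restarts
        self.nugget = nugget
        self.max_nugget = max_nugget
        self.estimate_nugget = estimate_nugget
        self.nugget_bounds = nugget_bounds
        self.random_state = random_state
        self.output_name = output_name

    # -- internal linear algebra -------------------------------------------

    def _gls(self, delta, nugget, X, y, H):
        """Cholesky of A and the GLS quantities for fixed delta.

        Returns (L, beta, resid_ssq, logdet_A, logdet_G, Ainv_resid, Ginv).
        """
        n = X.shape[0]
        A = correlation_matrix(X, X, delta)
        A[np.diag_indices_from(A)] += nugget
        L = np.linalg.cholesky(A)
        Ainv_H = cho_solve((L, True), H)
        Ainv_y = cho_solve((L, True), y)
        G = H.T @ Ainv_H
        Gc = np.linalg.cholesky(G)
        beta = cho_solve((Gc, True), H.T @ Ainv_y)
        resid = y - H @ beta
        Ainv_resid = cho_solve((L, True), resid)
        ssq = float(resid @ Ainv_resid)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(L))))
        logdet_G = 2.0 * float(np.sum(np.log(np.diag(Gc))))
        Ginv = cho_solve((Gc, True), np.eye(G.shape[0]))
        return L, beta, ssq, logdet_A, logdet_G, Ainv_resid, Ginv

    def _neg_log_posterior(self, params, X, y, H):
        n, q = H.shape
        p = X.shape[1]
        delta = np.exp(params[:p])
        nugget = np.exp(params[p]) if params.size > p else self.nugget_
        try:
            _, _, ssq, logdet_A, logdet_G, _, _ = self._gls(delta, nugget, X, y, H)
        except np.linalg.LinAlgError:
            return 1e300
        if ssq <= 0:
            return 1e300
        return 0.5 * ((n - q) * np.log(ssq) + logdet_A + logdet_G)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        q = p + 1
        if y.shape[0] != n:
            raise ValueError("X and y row counts differ")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        if n <= q:
            raise ValueError(f"need more than {q} design points, got {n}")
        if np.unique(X, axis=0).shape[0] != n:
            raise ValueError("duplicate design points")

        H = _regressors(X)
        lo, hi = np.log(self.delta_bounds[0]), np.log(self.delta_bounds[1])

        # nugget escalation: find the smallest jitter that factorises
        nugget = self.nugget
        while True:
            try:
                self.nugget_ = nugget
                self._gls(np.ones(p), nugget, X, y, H)
                break
            except np.linalg.LinAlgError:
                nugget *= 10.0
                if nugget > self.max_nugget:
                    raise ConditioningError(
                        "correlation matrix ill-conditioned even at max nugget"
                    )

        rng = np.random.default_rng(self.random_state)
        bounds = [(lo, hi)] * p
        if self.estimate_nugget:
            nlo, nhi = np.log(self.nugget_bounds[0]), np.log(self.nugget_bounds[1])
            bounds.append((nlo, nhi))
            starts = [np.concatenate([np.zeros(p), [np.log(self.nugget_)]])]
        else:
            starts = [np.zeros(p)]
        if self.n_restarts > 1:
            from scipy.stats import qmc

            lhs = qmc.LatinHypercube(d=len(bounds), seed=rng)
            extra = lhs.random(self.n_restarts - 1)
            blo = np.array([b[0] for b in bounds])
            bhi = np.array([b[1] for b in bounds])
            if self.estimate_nugget:
                # keep nugget starts in a plausibly small range
                bhi[-1] = min(bhi[-1], np.log(1e-2))
            starts.extend(blo + (bhi - blo) * extra)

        best = None
        for x0 in starts:
            res = minimize(
                self._neg_log_posterior, np.asarray(x0), args=(X, y, H),
                method="L-BFGS-B", bounds=bounds,
            )
            if best is None or res.fun < best.fun - 1e-9 or (
                abs(res.fun - best.fun) <= 1e-9
                and np.linalg.norm(res.x[:p]) < np.linalg.norm(best.x[:p])
            ):
                best = res
        self.delta_ = np.exp(best.x[:p])
        if self.estimate_nugget:
            self.nugget_ = float(np.exp(best.x[p]))
        self.log_posterior_ = -float(best.fun)

        L, beta, ssq, _, _, Ainv_resid, Ginv = self._gls(
            self.delta_, self.nugget_, X, y, H
        )
        self.X_ = X
        self.y_ = y
        self.H_ = H
        self.n_, self.q_ = n, q
        self.beta_ = beta
        self.sigma2_ = ssq / (n - q - 2)
        self._L = L
        self._Ainv_resid = Ainv_resid
        self._Ginv = Ginv
        self._Ainv_H = cho_solve((L, True), H)
        return self

    def predict(self, X, return_std: bool = False, return_cov: bool = False):
        """Posterior predictive mean, optionally with SD or full covariance."""
        check_is_fitted(self, "beta_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Hs = _regressors(X)
        t = correlation_matrix(X, self.X_, self.delta_)
        mean = Hs @ self.beta_ + t @ self._Ainv_resid
        if not (return_std or return_cov):
            return mean
        R = Hs - t @ self._Ainv_H
        Ainv_t = cho_solve((self._L, True), t.T)
        if return_cov:
            C = correlation_matrix(X, X, self.delta_)
            C[np.diag_indices_from(C)] += self.nugget_
            cov = self.sigma2_ * (C - t @ Ainv_t + R @ self._Ginv @ R.T)
            cov = 0.5 * (cov + cov.T)
            d = np.diag(cov).copy()
            np.fill_diagonal(cov, np.clip(d, 0.0, None))  # 1e-10-level jitter only
            return mean, cov
        var = self.sigma2_ * (
            1.0 + self.nugget_
            - np.einsum("ij,ji->i", t, Ainv_t)
            + np.einsum("ij,jk,ik->i", R, self._Ginv, R)
        )
        return mean, np.sqrt(np.clip(var, 0.0, None))

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None):
        check_is_fitted(self, "beta_")
        payload = {
            "output_name": self.output_name,
            "params": self.get_params(),
            "delta": self.delta_.tolist(),
            "beta": self.beta_.tolist(),
            "sigma2": self.sigma2_,
            "nugget": self.nugget_,
            "log_posterior": self.log_posterior_,
            "X": self.X_.tolist(),
            "y": self.y_.tolist(),
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return None

    @classmethod
    def from_json(cls, source) -> "GaussianProcessEmulator":
        """Rebuild a fitted emulator from :meth:`to_json` output.

        The cached factorisations are recomputed from the stored design
        and hyperparameters (no re-optimisation).
        """
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        em = cls(**payload["params"])
        em.output_name = payload["output_name"]
        X = np.array(payload["X"])
        y = np.array(payload["y"])
        H = _regressors(X)
        em.nugget_ = payload["nugget"]
        em.delta_ = np.array(payload["delta"])
        L, beta, ssq, _, _, Ainv_resid, Ginv = em._gls(em.delta_, em.nugget_, X, y, H)
        em.X_, em.y_, em.H_ = X, y, H
        em.n_, em.q_ = X.shape[0], X.shape[1] + 1
        em.beta_ = beta
        em.sigma2_ = ssq / (em.n_ - em.q_ - 2)
        em.log_posterior_ = payload["log_posterior"]
        em._L, em._Ainv_resid, em._Ginv = L, Ainv_resid, Ginv
        em._Ainv_H = cho_solve((L, True), H)
        return em


def fit_emulator(x, y, config: Optional[dict] = None) -> GaussianProcessEmulator:
    """Functional wrapper: fit a :class:`GaussianProcessEmulator`."""
    return GaussianProcessEmulator(**(config or {})).fit(x, y)


def predict(em: GaussianProcessEmulator, xstar):
    """Posterior predictive mean and full covariance at new inputs."""
    return em.predict(xstar, return_cov=True)
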