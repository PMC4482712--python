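"""NIPALS partial-least-squares regression baseline.

The comparison emulator: the eight biomarker outputs are regressed on
the six conductance inputs with PLS, giving an 8 x 6 table of
standardized regression coefficients whose signs show the direction of
each input-output association and whose magnitudes rank input
importance.  Before the regression, APD90 and maximum dV/dt are
log-transformed (in natural units) and every column is Z-scored; the
log-then-Z-score order is required since Z-scores can be negative.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .design import DesignSet, INPUT_NAMES, OUTPUT_NAMES
from .errors import CardioEmuError, DegenerateOutputError, TransformError

__all__ = ["NIPALSPLSRegression", "PLSModel", "nipals_pls", "pls_sensitivity"]

#: output columns log-transformed before Z-scoring
LOG_OUTPUTS = ("apd90", "max_dvdt")


class NIPALSPLSRegression(RegressorMixin, BaseEstimator):
    """Multi-response PLS regression via the NIPALS algorithm.

    Deterministic: each component's score iteration starts from the
    (current, deflated) Y column of maximal variance and stops when the
    score vector changes by less than ``tol`` (relative).  Data are
    centered internally; scaling is the caller's responsibility.

    Attributes (after fit): ``x_weights_`` (p x k), ``x_loadings_``
    (p x k), ``y_loadings_`` (m x k), ``x_scores_`` (n x k), and
    ``coefficients_`` (p x m) mapping centered X to centered Y.
    """

    def __init__(self, n_components: int = 6, tol: float = 1e-10,
                 max_iter: int = 500):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, Y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        if Y.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        if self.n_components > min(n - 1, p):
            raise ValueError("n_components too large for the data")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        E = X - self.x_mean_
        F = Y - self.y_mean_
        if np.any(E.std(axis=0) == 0):
            raise DegenerateOutputError("constant input column")

        k = self.n_components
        W = np.empty((p, k))
        P = np.empty((p, k))
        Q = np.empty((Y.shape[1], k))
        Tm = np.empty((n, k))
        for a in range(k):
            u = F[:, int(np.argmax(F.var(axis=0)))]
            t_old = None
            for _ in range(self.max_iter):
                w = E.T @ u / (u @ u)
                w /= np.linalg.norm(w)
                t = E @ w
                q = F.T @ t / (t @ t)
                qn = np.linalg.norm(q)
                if qn == 0:
                    break
                u = F @ q / (q @ q)
                if t_old is not None and np.linalg.norm(t - t_old) <= self.tol * np.linalg.norm(t):
                    break
                t_old = t
            else:
                raise CardioEmuError(
                    f"NIPALS did not converge in {self.max_iter} iterations"
                )
            pvec = E.T @ t / (t @ t)
            E = E - np.outer(t, pvec)
            F = F - np.outer(t, q)
            W[:, a], P[:, a], Q[:, a], Tm[:, a] = w, pvec, q, t
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = Q
        self.x_scores_ = Tm
        # B = W (P'W)^-1 Q' maps centered X to centered Y
        self.coefficients_ = W @ np.linalg.solve(P.T @ W, Q.T)
        return self

    def predict(self, X):
        check_is_fitted(self, "coefficients_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean_) @ self.coefficients_ + self.y_mean_


@dataclass
class PLSModel:
    """Fitted PLS baseline plus the column transforms that produced it."""

    estimator: NIPALSPLSRegression
    coefficients: pd.DataFrame       # inputs x outputs, Z-score scale
    n_components: int
    log_columns: tuple
    x_scale: np.ndarray
    y_scale: np.ndarray

    @property
    def x_weights(self):
        return self.estimator.x_weights_

    @property
    def x_loadings(self):
        return self.estimator.x_loadings_

    @property
    def y_loadings(self):
        return self.estimator.y_loadings_


def nipals_pls(x, y, n_components: int = 6) -> NIPALSPLSRegression:
    """Fit a :class:`NIPALSPLSRegression` on already-transformed matrices."""
    return NIPALSPLSRegression(n_components=n_components).fit(x, y)


def _zscore(M, label):
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateOutputError(f"constant {label} column")
    return (M - M.mean(axis=0)) / sd, sd


def pls_sensitivity(ds: DesignSet, n_components: int = 6) -> PLSModel:
    """The 8 x 6 PLS coefficient analysis of a design set.

    Log-transforms APD90 and max dV/dt, Z-scores every column, fits
    NIPALS PLS and returns the (input x output) coefficient table;
    positive entries mean the output increases with the input.
    """
    X = ds.x.copy()
    Y = ds.y.copy()
    if np.isnan(Y).any():
        raise TransformError("design set contains missing outputs")
    for name in LOG_OUTPUTS:
        jcol = OUTPUT_NAMES.index(name)
        if np.any(Y[:, jcol] <= 0):
            raise TransformError(f"log transform of non-positive {name}")
        Y[:, jcol] = np.log(Y[:, jcol])
    Xz, x_sd = _zscore(X, "input")
    Yz, y_sd = _zscore(Y, "output")
    est = nipals_pls(Xz, Yz, n_components=n_components)
    coefs = pd.DataFrame(est.coefficients_, index=list(INPUT_NAMES),
                         columns=list(OUTPUT_NAMES))
    return PLSModel(estimator=est, coefficients=coefs,
                    n_components=n_components, log_columns=LOG_OUTPUTS,
                    x_scale=x_sd, y_scale=y_sd)
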