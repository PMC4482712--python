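"""Uncertainty and variance-based sensitivity analysis through the emulator.

With independent normal inputs x_j ~ N(mu_j, v_j) and the emulator's
squared-exponential kernel / linear mean, every integral needed for
uncertainty analysis (output mean and variance under input uncertainty),
mean-effect curves and main-effect (first-order Sobol) indices is a
product of one-dimensional Gaussian integrals and is evaluated in closed
form.  Monte Carlo counterparts (through either the emulator mean or the
simulator itself) are provided as cross-checks.

Quantities reported:

* ``e_mean``  = E*[E{f(X)}]    - emulator expectation of the output mean
* ``var_mean``= Var*[E{f(X)}]  - posterior (code) uncertainty about it
* ``e_var``   = E*[Var{f(X)}]  - expected output variance under input
  uncertainty
* mean effect M_w(s) = E*[E{f(X) | x_w = s}]
* main effect index  = Var[M_w(x_w)] / Var[E*{f(X)}], the fraction of
  output variance removed by learning x_w, computed on the posterior-mean
  surface (both numerator and denominator), so that indices of an
  exactly-additive surface sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_solve
from scipy.stats import gaussian_kde

from .biomarkers import extract_ap_biomarkers
from .design import InputSpace
from .emulator import GaussianProcessEmulator
from .errors import DegenerateOutputError
from .lr1991 import Conductances, StimulusProtocol, run_s1_protocol

__all__ = [
    "InputDistribution",
    "UAResult",
    "SAResult",
    "uncertainty_analysis",
    "propagate_distribution",
    "mean_effect",
    "main_effect_index",
    "main_effect_indices",
    "mc_oracle",
]


@dataclass(frozen=True)
class InputDistribution:
    """Independent (product-form) normal distribution on the normalized
    input scale.  The study default is mean 0.5, variance 0.04 for every
    input."""

    mean: np.ndarray = field(default_factory=lambda: np.full(6, 0.5))
    var: np.ndarray = field(default_factory=lambda: np.full(6, 0.04))

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "var", np.asarray(self.var, dtype=float))
        if self.mean.shape != self.var.shape:
            raise ValueError("mean and var must have equal length")
        if np.any(self.var < 0):
            raise ValueError("variances must be nonnegative")

    @classmethod
    def varying_one(cls, w: int, var_w: float, d: int = 6,
                    fixed_var: float = 1e-4, mean: float = 0.5):
        """All inputs effectively fixed (tiny variance) except input ``w``."""
        var = np.full(d, fixed_var)
        var[w] = var_w
        return cls(mean=np.full(d, mean), var=var)

    def sample(self, n: int, rng) -> np.ndarray:
        return rng.normal(self.mean, np.sqrt(self.var), size=(n, self.mean.size))


@dataclass(frozen=True)
class UAResult:
    e_mean: float
    var_mean: float
    e_var: float

    @property
    def cov(self) -> float:
        """Coefficient of variation sqrt(E*[Var f]) / E*[E f] (fraction)."""
        return float(np.sqrt(max(self.e_var, 0.0)) / abs(self.e_mean))


@dataclass(frozen=True)
class SAResult:
    grid: np.ndarray
    curves: np.ndarray          # (d, len(grid)) mean-effect curves
    indices: np.ndarray         # (d,) main effect indices
    sum_of_indices: float


# ---------------------------------------------------------------------------
# closed-form Gaussian integrals of the kernel against the input measure

def _oneD_factors(em: GaussianProcessEmulator, dist: InputDistribution):
    """Per-design-point, per-coordinate integrals of the kernel.

    F1[i, j] = int exp(-(x - X_ij)^2 / d_j^2) N(x; mu_j, v_j) dx
    M1[i, j] = corresponding first-moment ratio (posterior mean of x)
    """
    X, d2 = em.X_, em.delta_**2
    v, mu = dist.var, dist.mean
    denom = d2 + 2.0 * v
    F1 = (d2 / denom) ** 0.5 * np.exp(-((X - mu) ** 2) / denom)
    M1 = (mu * d2 + 2.0 * v * X) / denom
    return F1, M1


def _pair_factor(em, dist, j):
    """F2[i, l] for coordinate j: int of the product of two kernel terms."""
    Xj = em.X_[:, j]
    d2 = em.delta_[j] ** 2
    v, mu = dist.var[j], dist.mean[j]
    diff = Xj[:, None] - Xj[None, :]
    mid = 0.5 * (Xj[:, None] + Xj[None, :])
    u = (1.0 + 4.0 * v / d2) ** -0.5
    return u * np.exp(-(diff**2) / (2.0 * d2) - (mid - mu) ** 2 / (0.5 * d2 + 2.0 * v))


def _integrals(em: GaussianProcessEmulator, dist: InputDistribution):
    """T (n,), U (scalar), Q (n, q), P (n, n), S (q, q), R_h (q,)."""
    F1, M1 = _oneD_factors(em, dist)
    T = np.prod(F1, axis=1)
    U = float(np.prod((1.0 + 4.0 * dist.var / em.delta_**2) ** -0.5))
    Q = np.hstack([T[:, None], T[:, None] * M1])
    P = np.ones((em.n_, em.n_))
    for j in range(em.X_.shape[1]):
        P *= _pair_factor(em, dist, j)
    mu, v = dist.mean, dist.var
    S = np.empty((em.q_, em.q_))
    S[0, 0] = 1.0
    S[0, 1:] = mu
    S[1:, 0] = mu
    S[1:, 1:] = np.outer(mu, mu) + np.diag(v)
    R_h = np.concatenate([[1.0], mu])
    return T, U, Q, P, S, R_h


def uncertainty_analysis(
    em: GaussianProcessEmulator, dist: InputDistribution
) -> UAResult:
    """Analytic uncertainty analysis of one output under input uncertainty."""
    T, U, Q, P, S, R_h = _integrals(em, dist)
    e = em._Ainv_resid
    beta = em.beta_
    e_mean = float(R_h @ beta + T @ e)

    Ainv_T = cho_solve((em._L, True), T)
    r = R_h - T @ em._Ainv_H
    var_mean = em.sigma2_ * float(U - T @ Ainv_T + r @ em._Ginv @ r)

    int_m2 = float(beta @ S @ beta + 2.0 * (e @ Q @ beta) + e @ P @ e)
    Ainv_P = cho_solve((em._L, True), P)
    AH = em._Ainv_H
    Omega = S - Q.T @ AH - AH.T @ Q + AH.T @ P @ AH
    int_v = em.sigma2_ * float(
        1.0 + em.nugget_ - np.trace(Ainv_P) + np.trace(em._Ginv @ Omega)
    )
    e_var = int_m2 + int_v - e_mean**2 - var_mean
    return UAResult(e_mean=e_mean,
                    var_mean=max(var_mean, 0.0),
                    e_var=max(e_var, 0.0))


def _posterior_mean_variance(em, dist) -> float:
    """Variance of the posterior-mean surface under the input measure."""
    T, _, Q, P, S, R_h = _integrals(em, dist)
    e, beta = em._Ainv_resid, em.beta_
    e_mean = float(R_h @ beta + T @ e)
    int_m2 = float(beta @ S @ beta + 2.0 * (e @ Q @ beta) + e @ P @ e)
    return max(int_m2 - e_mean**2, 0.0)


def mean_effect(
    em: GaussianProcessEmulator,
    w: int,
    grid,
    dist: InputDistribution,
) -> np.ndarray:
    """Mean-effect curve of input ``w``: E*[E{f(x) | x_w = s}] over the grid.

    The remaining inputs are integrated out in closed form against their
    normal distribution.
    """
    grid = np.asarray(grid, dtype=float)
    F1, _ = _oneD_factors(em, dist)
    T = np.prod(F1, axis=1)
    k = T / F1[:, w]  # product of all coordinates except w
    e, beta = em._Ainv_resid, em.beta_
    alpha = beta[0] + float(np.delete(beta[1:], w) @ np.delete(dist.mean, w))
    d2 = em.delta_[w] ** 2
    G = np.exp(-((grid[:, None] - em.X_[None, :, w]) ** 2) / d2)
    return alpha + beta[1 + w] * grid + G @ (k * e)


def main_effect_index(
    em: GaussianProcessEmulator, w: int, dist: InputDistribution
) -> float:
    """Fraction of output variance attributable to input ``w`` alone."""
    return float(main_effect_indices(em, dist).indices[w])


def main_effect_indices(
    em: GaussianProcessEmulator,
    dist: InputDistribution,
    grid_size: int = 101,
) -> SAResult:
    """All main-effect indices of one emulator plus mean-effect curves.

    The variance of each mean-effect curve and the total output variance
    are both evaluated in closed form on the posterior-mean surface; the
    shortfall of the summed indices from one measures interaction
    effects.  ``grid_size`` controls only the curves returned for
    plotting, not the indices.
    """
    d = em.X_.shape[1]
    var_total = _posterior_mean_variance(em, dist)
    if var_total <= 0:
        raise DegenerateOutputError("output variance is zero under the input measure")

    F1, M1 = _oneD_factors(em, dist)
    T = np.prod(F1, axis=1)
    e, beta = em._Ainv_resid, em.beta_
    R_h = np.concatenate([[1.0], dist.mean])
    e_mean = float(R_h @ beta + T @ e)

    grid = np.linspace(0.0, 1.0, grid_size)
    curves = np.empty((d, grid_size))
    indices = np.empty(d)
    for w in range(d):
        curves[w] = mean_effect(em, w, grid, dist)
        k = T / F1[:, w]
        bw = beta[1 + w]
        alpha = beta[0] + float(np.delete(beta[1:], w) @ np.delete(dist.mean, w))
        mu_w, v_w = dist.mean[w], dist.var[w]
        # E[(alpha + bw s)^2]
        lin = (alpha + bw * mu_w) ** 2 + bw**2 * v_w
        # cross terms: 2 sum_i e_i k_i int (alpha + bw s) g_i(s) dN(s)
        cross = 2.0 * float(e @ (alpha * T + bw * T * M1[:, w]))
        # quadratic kernel term
        F2w = _pair_factor(em, dist, w)
        quad = float((k * e) @ F2w @ (k * e))
        second_moment = lin + cross + quad
        indices[w] = max(second_moment - e_mean**2, 0.0) / var_total
    return SAResult(grid=grid, curves=curves, indices=indices,
                    sum_of_indices=float(indices.sum()))


# ---------------------------------------------------------------------------
# Monte Carlo counterparts

@dataclass
class PropagationResult:
    samples: np.ndarray
    kde: gaussian_kde


def propagate_distribution(
    em: GaussianProcessEmulator,
    dist: InputDistribution,
    n_samples: int = 2000,
    seed: Optional[int] = None,
    include_predictive_noise: bool = False,
) -> PropagationResult:
    """Sample the input distribution through the emulator.

    Evaluates the posterior predictive mean at each draw (optionally
    adding predictive noise) and returns the samples with a Gaussian
    kernel density estimate.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(seed)
    x = dist.sample(n_samples, rng)
    if include_predictive_noise:
        mean, sd = em.predict(x, return_std=True)
        out = rng.normal(mean, sd)
    else:
        out = em.predict(x)
    return PropagationResult(samples=out, kde=gaussian_kde(out))


def mc_oracle(
    space: InputSpace,
    p: StimulusProtocol,
    dist: InputDistribution,
    n_samples: int,
    seed: Optional[int] = None,
    method: str = "rl",
) -> np.ndarray:
    """Direct simulator Monte Carlo: draw inputs, run the S1 protocol,
    return the six AP biomarkers per draw (n x 6 array).

    Draws whose natural conductances would be non-positive are redrawn
    (truncation at physical positivity); simulator failures propagate.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((n_samples, 6))
    for i in range(n_samples):
        while True:
            x = dist.sample(1, rng)[0]
            g_nat = space.denormalize(x)
            if np.all(g_nat > 0):
                break
        g = Conductances.from_array(g_nat)
        trace = run_s1_protocol(g, p, method=method)
        bm = extract_ap_biomarkers(trace)
        out[i] = bm.as_array()[:6]
    return out
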