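"""Emulator validation against held-out simulator runs.

Pointwise agreement is summarised by standardized errors (prediction
error over predictive SD) and jointly by the Mahalanobis distance under
the full predictive covariance.  When the emulator is an adequate model
of the simulator, the Mahalanobis distance follows a scaled-F reference
distribution with mean m (the number of test points) and variance
2m(m + n - q - 2)/(n - q - 4); a fit is flagged as passing when the
observed distance lies within two reference SDs of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .emulator import GaussianProcessEmulator
from .errors import ConditioningError

__all__ = [
    "ValidationReport",
    "standardized_errors",
    "mahalanobis_distance",
    "md_reference_moments",
    "validate_emulator",
]


@dataclass(frozen=True)
class ValidationReport:
    standardized_errors: np.ndarray
    md: float
    md_ref_mean: float
    md_ref_sd: float

    @property
    def passed(self) -> bool:
        return abs(self.md - self.md_ref_mean) <= 2.0 * self.md_ref_sd


def standardized_errors(em: GaussianProcessEmulator, xtest, ytest) -> np.ndarray:
    """(y - predictive mean) / predictive SD, elementwise."""
    ytest = np.asarray(ytest, dtype=float).ravel()
    mean, sd = em.predict(xtest, return_std=True)
    if np.any(sd <= 0):
        raise ConditioningError("zero predictive variance at a test point")
    return (ytest - mean) / sd


def mahalanobis_distance(
    em: GaussianProcessEmulator, xtest, ytest, diagonal: bool = False
) -> float:
    """Squared prediction error weighted by the predictive covariance.

    ``diagonal=True`` ignores predictive correlations (sum of squared
    standardized errors) and is exposed as a diagnostic variant only.
    """
    ytest = np.asarray(ytest, dtype=float).ravel()
    if diagonal:
        z = standardized_errors(em, xtest, ytest)
        return float(z @ z)
    mean, cov = em.predict(xtest, return_cov=True)
    resid = ytest - mean
    try:
        factor = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(f"singular predictive covariance: {exc}") from exc
    return float(resid @ cho_solve(factor, resid))


def md_reference_moments(m: int, n: int, q: int) -> tuple:
    """Mean and SD of the Mahalanobis-distance reference distribution.

    Derived from MD ~ m(n-q-2)/(n-q) * F(m, n-q): the mean is exactly m
    and the variance 2m(m + n - q - 2)/(n - q - 4).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n - q <= 4:
        raise ValueError("reference variance undefined: need n - q > 4")
    mean = float(m)
    var = 2.0 * m * (m + n - q - 2.0) / (n - q - 4.0)
    return mean, float(np.sqrt(var))


def validate_emulator(
    em: GaussianProcessEmulator, xtest, ytest
) -> ValidationReport:
    """Full validation report for one emulator on held-out data."""
    z = standardized_errors(em, xtest, ytest)
    md = mahalanobis_distance(em, xtest, ytest)
    m = np.asarray(ytest).ravel().shape[0]
    ref_mean, ref_sd = md_reference_moments(m, em.n_, em.q_)
    return ValidationReport(
        standardized_errors=z, md=md, md_ref_mean=ref_mean, md_ref_sd=ref_sd
    )
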