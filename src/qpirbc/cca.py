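"""Canonical correlation analysis between 2-D phase statistics and 3-D
morphology.

Given standardized variable sets X (n x p) and Y (n x q), CCA finds pairs of
coefficient vectors (a_i, b_i) maximising corr(X a_i, Y b_i), each pair
uncorrelated with all earlier ones; there are k = min(p, q) pairs.  The
solver whitens the cross-covariance: with symmetric inverse square roots of
the within-set covariances, the singular values of

    K = Sxx^(-1/2) Sxy Syy^(-1/2)

are the canonical correlations and the rotated singular vectors the
coefficients.  Within-set loadings (correlations between each original
variable and its own set's variates) support interpretation, and the shared
variance of a pair is rho^2.  Population (divisor-n) covariances are used
throughout, matching the standardization convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: ridge added to a numerically singular within-set covariance
RIDGE_EPS = 1e-8


@dataclass
class CCAResult:
    correlations: np.ndarray  # k, non-increasing, in [0, 1]
    coeff_x: np.ndarray  # p x k
    coeff_y: np.ndarray  # q x k
    variates_x: np.ndarray  # n x k
    variates_y: np.ndarray  # n x k
    loadings_x: np.ndarray  # p x k
    loadings_y: np.ndarray  # q x k
    shared_variance: np.ndarray  # k, = rho^2

    def to_dict(self) -> dict:
        return {
            "correlations": self.correlations.tolist(),
            "shared_variance": self.shared_variance.tolist(),
            "coeff_x": self.coeff_x.tolist(),
            "coeff_y": self.coeff_y.tolist(),
            "loadings_x": self.loadings_x.tolist(),
            "loadings_y": self.loadings_y.tolist(),
        }


def standardize(matrix: np.ndarray, column_names=None) -> np.ndarray:
    """Center each column and scale to unit population variance.

    Raises on constant columns, naming the offender.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with n >= 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population scaling (ddof=0)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        name = column_names[bad[0]] if column_names is not None else f"column {bad[0]}"
        raise ValidationError(f"constant column cannot be standardized: {name}")
    return (X - mean) / sd


def _inv_sqrt_psd(S: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root, with a ridge on near-singular input."""
    w, V = np.linalg.eigh(S)
    if w.min() < 1e-10 * max(w.max(), 1.0):
        logger.warning(
            "within-set covariance nearly singular (min eig %.3e); adding ridge %g",
            float(w.min()),
            RIDGE_EPS,
        )
        w = w + RIDGE_EPS
    return V @ np.diag(1.0 / np.sqrt(w)) @ V.T


def cca_fit(X: np.ndarray, Y: np.ndarray) -> CCAResult:
    """Fit CCA via SVD of the whitened cross-covariance.

    Inputs are standardized internally (population convention).  Requires
    n > p + q.  The sign of each pair is fixed so the x-variable with the
    largest absolute loading has a positive loading.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValidationError("X and Y must be 2-D with equal row counts")
    n, p = X.shape
    q = Y.shape[1]
    if n <= p + q:
        raise ValidationError(f"need n > p + q = {p + q}, got n = {n}")
    Xs = standardize(X)
    Ys = standardize(Y)
    Sxx = Xs.T @ Xs / n
    Syy = Ys.T @ Ys / n
    Sxy = Xs.T @ Ys / n
    Wx = _inv_sqrt_psd(Sxx)
    Wy = _inv_sqrt_psd(Syy)
    K = Wx @ Sxy @ Wy
    U, s, Vt = np.linalg.svd(K)
    k = min(p, q)
    corr = np.clip(s[:k], 0.0, 1.0)
    a = Wx @ U[:, :k]
    b = Wy @ Vt.T[:, :k]
    Uvar = Xs @ a
    Wvar = Ys @ b
    loadings_x = _column_correlations(Xs, Uvar)
    loadings_y = _column_correlations(Ys, Wvar)
    # sign convention: largest-|loading| x variable positive in each pair
    for i in range(k):
        j = int(np.argmax(np.abs(loadings_x[:, i])))
        if loadings_x[j, i] < 0:
            a[:, i] *= -1
            b[:, i] *= -1
            Uvar[:, i] *= -1
            Wvar[:, i] *= -1
            loadings_x[:, i] *= -1
            loadings_y[:, i] *= -1
    return CCAResult(
        correlations=corr,
        coeff_x=a,
        coeff_y=b,
        variates_x=Uvar,
        variates_y=Wvar,
        loadings_x=loadings_x,
        loadings_y=loadings_y,
        shared_variance=corr ** 2,
    )


def _column_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between every column of A and every column of B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = Ac.std(axis=0)
    sb = Bc.std(axis=0)
    if np.any(sb == 0):
        raise ValidationError("zero-variance variate")
    if np.any(sa == 0):
        raise ValidationError("zero-variance variable")
    return (Ac.T @ Bc) / A.shape[0] / np.outer(sa, sb)


def within_set_loadings(original: np.ndarray, variates: np.ndarray) -> np.ndarray:
    """Correlation of each original variable with each variate of its set."""
    original = np.asarray(original, dtype=float)
    variates = np.asarray(variates, dtype=float)
    if original.shape[0] != variates.shape[0]:
        raise ValidationError("original and variates must have equal row counts")
    return _column_correlations(original, variates)


def shared_variance(correlations: np.ndarray) -> np.ndarray:
    """Element-wise square of canonical correlations."""
    c = np.asarray(correlations, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ParameterError("canonical correlations must lie in [0, 1]")
    return c ** 2
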