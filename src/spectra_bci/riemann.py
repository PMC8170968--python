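"""Riemannian geometry of SPD covariance matrices and tangent-space mapping.

Covariance matrices of spatially filtered trials live on the manifold of
symmetric positive-definite (SPD) matrices.  Under the affine-invariant
metric the distance between two SPD matrices A, B is

    delta_R(A, B) = || log(A^{-1/2} B A^{-1/2}) ||_F ,

the Karcher (Frechet) mean of a set is the point minimizing the sum of
squared distances, and the tangent-space map at the mean Sigma sends each
trial covariance Sigma_i to the Euclidean vector

    s_i = upper( log( Sigma^{-1/2} Sigma_i Sigma^{-1/2} ) ),

where upper(.) vectorizes the upper triangle (row-major, diagonal
included) with off-diagonal entries multiplied by sqrt(2) so that
|| s_i ||_2 = delta_R(Sigma, Sigma_i).  For d filtered channels the
tangent vector has d(d+1)/2 entries (21 for d = 6).

All matrix functions go through symmetric eigendecompositions with an
eigenvalue floor of 1e-12; batched helpers operate on stacks of matrices
for speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPDError",
    "RiemannianMean",
    "trial_covariance",
    "riemannian_mean",
    "riemannian_distance",
    "log_map",
    "tangent_vector",
    "tangent_vectors",
    "upper_vectorize",
    "spd_power",
    "spd_logm",
    "spd_expm",
]

_EIG_FLOOR = 1e-12


class SPDError(ValueError):
    """Raised when an input is not symmetric positive-definite."""


@dataclass
class RiemannianMean:
    """Karcher mean with convergence diagnostics."""

    Sigma: np.ndarray
    iterations_used: int
    final_gradient_norm: float
    converged: bool


def _check_spd(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise SPDError(f"{name} must be square, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise SPDError(f"{name} is not symmetric")
    eigvals = np.linalg.eigvalsh(M)
    if eigvals[0] <= 0:
        raise SPDError(f"{name} is not positive definite (min eig {eigvals[0]:g})")
    return 0.5 * (M + M.T)


def spd_power(M: np.ndarray, power: float) -> np.ndarray:
    """Matrix power of a stack of SPD matrices via eigendecomposition."""
    w, V = np.linalg.eigh(M)
    w = np.maximum(w, _EIG_FLOOR)
    return (V * (w[..., None, :] ** power)) @ np.swapaxes(V, -1, -2)


def spd_logm(M: np.ndarray) -> np.ndarray:
    """Matrix logarithm of a stack of SPD matrices."""
    w, V = np.linalg.eigh(M)
    w = np.maximum(w, _EIG_FLOOR)
    return (V * np.log(w)[..., None, :]) @ np.swapaxes(V, -1, -2)


def spd_expm(M: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of symmetric matrices."""
    w, V = np.linalg.eigh(M)
    return (V * np.exp(w)[..., None, :]) @ np.swapaxes(V, -1, -2)


def trial_covariance(Z: np.ndarray) -> np.ndarray:
    """Trace-normalized covariance of a filtered trial: Z Z^T / tr(Z Z^T).

    When the window is shorter than the channel count the covariance is
    rank-deficient; a small relative ridge keeps it SPD.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2:
        raise ValueError("expected a d x L matrix")
    cov = Z @ Z.T
    trace = np.trace(cov)
    if trace <= 0:
        raise ValueError("all-zero trial: covariance undefined")
    cov = cov / trace
    d = cov.shape[0]
    if np.linalg.eigvalsh(cov)[0] < _EIG_FLOOR:
        cov = cov + 1e-9 / d * np.eye(d)
    return 0.5 * (cov + cov.T)


def _whiten(Sigma: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Congruence-transform ``others`` by Sigma^{-1/2} on both sides."""
    inv_sqrt = spd_power(Sigma, -0.5)
    return inv_sqrt @ others @ inv_sqrt


def riemannian_mean(
    Sigmas, tol: float = 1e-8, max_iter: int = 50
) -> RiemannianMean:
    """Karcher mean under the affine-invariant metric.

    Fixed-point iteration with unit step, initialized at the arithmetic
    mean::

        Sigma <- Sigma^{1/2} exp( mean_i log(Sigma^{-1/2} Sigma_i Sigma^{-1/2}) ) Sigma^{1/2}

    stopping when the Frobenius norm of the mean log (the Riemannian
    gradient) drops to ``tol`` or after ``max_iter`` iterations (then a
    warning is emitted and ``converged`` is False).
    """
    stack = np.stack([_check_spd(S, f"Sigmas[{i}]") for i, S in enumerate(Sigmas)])
    if stack.shape[0] == 1:
        return RiemannianMean(stack[0], 0, 0.0, True)
    Sigma = stack.mean(axis=0)
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        log_mean = spd_logm(_whiten(Sigma, stack)).mean(axis=0)
        grad_norm = float(np.linalg.norm(log_mean, "fro"))
        if grad_norm <= tol:
            return RiemannianMean(Sigma, it - 1, grad_norm, True)
        sqrt = spd_power(Sigma, 0.5)
        Sigma = sqrt @ spd_expm(log_mean) @ sqrt
        Sigma = 0.5 * (Sigma + Sigma.T)
    warnings.warn(
        f"Karcher mean did not reach tol={tol:g} in {max_iter} iterations "
        f"(gradient norm {grad_norm:g})",
        RuntimeWarning,
    )
    return RiemannianMean(Sigma, max_iter, grad_norm, False)


def log_map(Sigma: np.ndarray, Sigma_i: np.ndarray) -> np.ndarray:
    """Logarithmic map of Sigma_i at Sigma:
    ``Sigma^{1/2} log(Sigma^{-1/2} Sigma_i Sigma^{-1/2}) Sigma^{1/2}``."""
    Sigma = _check_spd(Sigma, "Sigma")
    Sigma_i = _check_spd(Sigma_i, "Sigma_i")
    sqrt = spd_power(Sigma, 0.5)
    inner = spd_logm(_whiten(Sigma, Sigma_i[None])[0])
    out = sqrt @ inner @ sqrt
    return 0.5 * (out + out.T)


def upper_vectorize(S: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle vectorization with sqrt(2) off-diagonal.

    Isometric: the Euclidean norm of the vector equals the Frobenius norm
    of the symmetric matrix.  Supports stacks (..., d, d).
    """
    S = np.asarray(S)
    d = S.shape[-1]
    iu, ju = np.triu_indices(d)
    weights = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return S[..., iu, ju] * weights


def tangent_vector(Sigma: np.ndarray | RiemannianMean, Sigma_i: np.ndarray) -> np.ndarray:
    """Tangent-space coordinates of Sigma_i at the reference Sigma.

    ``upper(Sigma^{-1/2} Log_Sigma(Sigma_i) Sigma^{-1/2})
    = upper(log(Sigma^{-1/2} Sigma_i Sigma^{-1/2}))``; the 2-norm of the
    result is the affine-invariant distance delta_R(Sigma, Sigma_i).
    """
    if isinstance(Sigma, RiemannianMean):
        Sigma = Sigma.Sigma
    Sigma = _check_spd(Sigma, "Sigma")
    Sigma_i = _check_spd(Sigma_i, "Sigma_i")
    whitened_log = spd_logm(_whiten(Sigma, Sigma_i[None])[0])
    return upper_vectorize(whitened_log)


def tangent_vectors(Sigma: np.ndarray | RiemannianMean, Sigmas: np.ndarray) -> np.ndarray:
    """Batched tangent-space map: (n, d, d) -> (n, d(d+1)/2)."""
    if isinstance(Sigma, RiemannianMean):
        Sigma = Sigma.Sigma
    whitened_logs = spd_logm(_whiten(np.asarray(Sigma), np.asarray(Sigmas)))
    return upper_vectorize(whitened_logs)


def riemannian_distance(Sigma: np.ndarray, Sigma_i: np.ndarray) -> float:
    """Affine-invariant distance between two SPD matrices."""
    Sigma = _check_spd(Sigma, "Sigma")
    Sigma_i = _check_spd(Sigma_i, "Sigma_i")
    w, _ = np.linalg.eigh(_whiten(Sigma, Sigma_i[None])[0])
    w = np.maximum(w, _EIG_FLOOR)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))
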