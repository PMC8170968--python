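"""Temporal delay windows, CSSP channel stacking, and CSP spatial filtering.

An epoch of ``T`` samples is cut into ``n`` windows of equal length
``L = T - (n-1) * tau``, window ``i`` starting at offset ``(i-1) * tau``
(0-based: ``i*tau`` for ``i = 0..n-1``).  Common spatio-spectral pattern
(CSSP) trials are built by stacking every ordered window pair ``(i, i+j)``
as extra channels, which delay-embeds the signal and adds spectral
resolution to the spatial filters.

CSP itself solves the generalized eigenproblem

    C+ w = lambda (C+ + C-) w

on the class-mean trace-normalized covariances and keeps the ``m``
eigenvectors of largest and ``m`` of smallest eigenvalue: the directions
along which one class's variance is maximal relative to the other's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as _linalg

__all__ = [
    "WindowSpec",
    "ProcessId",
    "SpatialFilterBank",
    "make_windows",
    "make_cssp_windows",
    "cssp_process_ids",
    "trial_covariances",
    "class_mean_covariances",
    "learn_csp",
    "csp_from_covariances",
    "apply_filters",
    "csp_features",
]

# relative ridge added when a covariance is (near-)singular, e.g. for CSSP
# stacks with tau = 0 or very short windows
_EPS_RIDGE = 1e-9
_SINGULAR_TOL = 1e-12


@dataclass(frozen=True)
class WindowSpec:
    """Delay-window layout: ``n_windows`` windows offset by ``tau`` samples."""

    n_windows: int = 3
    tau: int = 10
    window_len_s: float = 2.0

    def validate(self, n_samples: int) -> None:
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if (self.n_windows - 1) * self.tau >= n_samples:
            raise ValueError(
                f"(n-1)*tau = {(self.n_windows - 1) * self.tau} leaves no "
                f"samples in an epoch of {n_samples}"
            )

    def window_length(self, n_samples: int) -> int:
        return n_samples - (self.n_windows - 1) * self.tau


@dataclass(frozen=True)
class ProcessId:
    """Identity of one feature-extraction process.

    ``kind`` is ``"csp_tsm"`` (single window ``window_i``) or
    ``"cssp_tsm"`` (channel stack of windows ``window_i`` and
    ``window_j``, ``window_j > window_i``).  Indices are 0-based.
    """

    kind: str
    window_i: int
    window_j: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("csp_tsm", "cssp_tsm"):
            raise ValueError(f"unknown process kind {self.kind!r}")
        if self.kind == "csp_tsm" and self.window_j is not None:
            raise ValueError("csp_tsm process has no second window")
        if self.kind == "cssp_tsm":
            if self.window_j is None or self.window_j <= self.window_i:
                raise ValueError("cssp_tsm needs window_j > window_i")

    def __str__(self) -> str:
        if self.kind == "csp_tsm":
            return f"csp_tsm[w{self.window_i}]"
        return f"cssp_tsm[w{self.window_i},w{self.window_j}]"


@dataclass
class SpatialFilterBank:
    """Learned CSP projection.

    ``W`` has shape (channels_in, 2m): the first ``m`` columns are the
    eigenvectors of largest generalized eigenvalue (class +1 variance
    maximizers), the last ``m`` those of smallest (class -1 maximizers).
    Columns satisfy ``W.T @ (C+ + C-) @ W = I``.
    """

    W: np.ndarray
    eigvals: np.ndarray
    m: int

    @property
    def channels_in(self) -> int:
        return self.W.shape[0]

    @property
    def n_filters(self) -> int:
        return self.W.shape[1]


def make_windows(epoch: np.ndarray, spec: WindowSpec) -> list[np.ndarray]:
    """Cut an epoch (C x T) into ``n`` equal-length delayed windows."""
    epoch = np.asarray(epoch)
    T = epoch.shape[-1]
    spec.validate(T)
    L = spec.window_length(T)
    if L <= 0:
        raise ValueError("window length <= 0")
    return [epoch[..., i * spec.tau:i * spec.tau + L] for i in range(spec.n_windows)]


def cssp_process_ids(n_windows: int) -> list[ProcessId]:
    """All ``n (n-1) / 2`` ordered window pairs, (0,1), (0,2), ..., (1,2), ..."""
    return [
        ProcessId("cssp_tsm", i, j)
        for i in range(n_windows - 1)
        for j in range(i + 1, n_windows)
    ]


def make_cssp_windows(
    windows: list[np.ndarray],
) -> list[tuple[ProcessId, np.ndarray]]:
    """Stack every window pair channel-wise into 2C x L CSSP trials.

    With fewer than 2 windows there are no pairs and the list is empty.
    """
    shapes = {w.shape for w in windows}
    if len(shapes) > 1:
        raise ValueError(f"windows differ in shape: {sorted(shapes)}")
    out = []
    for pid in cssp_process_ids(len(windows)):
        stacked = np.concatenate(
            [windows[pid.window_i], windows[pid.window_j]], axis=-2
        )
        out.append((pid, stacked))
    return out


def trial_covariances(trials: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariances X X^T / tr(X X^T), batched."""
    trials = np.asarray(trials, dtype=np.float64)
    covs = trials @ np.swapaxes(trials, -1, -2)
    traces = np.trace(covs, axis1=-2, axis2=-1)
    if np.any(traces <= 0):
        raise ValueError("all-zero trial: covariance undefined")
    return covs / traces[..., None, None]


def _regularize(cov: np.ndarray) -> np.ndarray:
    """Ridge a covariance whose smallest eigenvalue is numerically zero."""
    tr = np.trace(cov)
    eigmin = _linalg.eigvalsh(cov, subset_by_index=(0, 0))[0]
    if eigmin < _SINGULAR_TOL * tr:
        cov = cov + _EPS_RIDGE * tr / cov.shape[0] * np.eye(cov.shape[0])
    return cov


def class_mean_covariances(
    trials: np.ndarray | list[np.ndarray], labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class means of trace-normalized trial covariances (C+, C-)."""
    labels = np.asarray(labels)
    if isinstance(trials, list):
        trials = np.stack(trials)
    if trials.ndim != 3:
        raise ValueError("expected trials as (n, C, L)")
    if not np.isfinite(trials).all():
        raise ValueError("non-finite trial data")
    pos = labels == 1
    neg = labels == -1
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    covs = trial_covariances(trials)
    return covs[pos].mean(axis=0), covs[neg].mean(axis=0)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Sign convention: first nonzero component of each filter positive."""
    W = W.copy()
    for k in range(W.shape[1]):
        col = W[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            W[:, k] = -col
    return W


def csp_from_covariances(
    cov_pos: np.ndarray, cov_neg: np.ndarray, m: int
) -> SpatialFilterBank:
    """CSP filters from the two class-mean covariances.

    Solves ``C+ w = lambda (C+ + C-) w`` and returns the ``m`` top and
    ``m`` bottom eigenvectors (top block in descending, bottom block in
    ascending eigenvalue order), normalized so that
    ``W.T (C+ + C-) W = I``.
    """
    cov_pos = np.asarray(cov_pos, dtype=np.float64)
    cov_neg = np.asarray(cov_neg, dtype=np.float64)
    d = cov_pos.shape[0]
    if cov_pos.shape != (d, d) or cov_neg.shape != (d, d):
        raise ValueError("covariances must be square and same size")
    if 2 * m > d:
        raise ValueError(f"2m = {2 * m} filters exceed dimension {d}")
    cov_pos = _regularize(0.5 * (cov_pos + cov_pos.T))
    cov_neg = _regularize(0.5 * (cov_neg + cov_neg.T))
    composite = _regularize(cov_pos + cov_neg)
    # ascending eigenvalues
    eigvals, eigvecs = _linalg.eigh(cov_pos, composite)
    top = np.argsort(eigvals)[::-1][:m]          # descending
    bottom = np.argsort(eigvals)[:m]             # ascending
    order = np.concatenate([top, bottom])
    W = _fix_signs(eigvecs[:, order])
    return SpatialFilterBank(W=W, eigvals=eigvals[order], m=m)


def learn_csp(
    trials: np.ndarray | list[np.ndarray], labels: np.ndarray, m: int = 3
) -> SpatialFilterBank:
    """Learn CSP filters from labelled trials (n, C, L)."""
    cov_pos, cov_neg = class_mean_covariances(trials, labels)
    return csp_from_covariances(cov_pos, cov_neg, m)


def apply_filters(bank: SpatialFilterBank, X: np.ndarray) -> np.ndarray:
    """Project trial(s) through the filter bank: ``Z = W^T X``.

    Accepts a single C x L trial or a batch (n, C, L).
    """
    X = np.asarray(X)
    if X.shape[-2] != bank.channels_in:
        raise ValueError(
            f"trial has {X.shape[-2]} channels, bank expects {bank.channels_in}"
        )
    return np.swapaxes(bank.W, 0, 1) @ X


def csp_features(Z: np.ndarray) -> np.ndarray:
    """Normalized log-variance features of the filtered signal.

    ``f_k = log(var(Z_k) / sum_j var(Z_j))`` with sample variance
    (denominator L-1), so ``sum_k exp(f_k) = 1``.  Works on a single
    2m x L matrix or a batch (n, 2m, L).
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[-1] < 2:
        raise ValueError("need at least 2 samples to estimate variance")
    variances = Z.var(axis=-1, ddof=1)
    if np.any(variances <= 0):
        warnings.warn("zero-variance filtered row; flooring", RuntimeWarning)
        variances = np.maximum(variances, np.finfo(float).tiny)
    return np.log(variances / variances.sum(axis=-1, keepdims=True))
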