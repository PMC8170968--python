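"""Feature-extraction processes, fusion, Fisher-score ranking, selection.

With ``n = 3`` delay windows there are six processes: one CSP-TSM process
per window and one CSSP-TSM process per window pair.  Each fitted process
yields ``2m`` log-variance CSP features plus ``d(d+1)/2`` tangent-space
features of the filtered-trial covariance (27 = 6 + 21 for the default
``m = 3``), for a fused total of 6 x 27 = 162 features.  Features are
ranked by Fisher score and the top ``r`` are kept; both the ranking and
the Riemannian reference means are computed on training trials only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .riemann import RiemannianMean, riemannian_mean, tangent_vectors, trial_covariance
from .spatial import (
    ProcessId,
    SpatialFilterBank,
    WindowSpec,
    apply_filters,
    cssp_process_ids,
    csp_features,
    learn_csp,
    make_windows,
)

__all__ = [
    "ProcessModel",
    "FeatureMatrix",
    "FScoreTable",
    "SelectionConfig",
    "process_ids",
    "fit_process",
    "transform_process",
    "assemble_features",
    "transform_features",
    "f_score",
    "f_scores",
    "rank_features",
    "select_top_r",
]


@dataclass
class ProcessModel:
    """One fitted CSP-TSM / CSSP-TSM process: filters + Riemannian mean."""

    process: ProcessId
    window_spec: WindowSpec
    bank: SpatialFilterBank
    mean: RiemannianMean

    @property
    def n_features(self) -> int:
        d = self.bank.n_filters
        return d + d * (d + 1) // 2


@dataclass
class FeatureMatrix:
    """Fused trials x features matrix with per-column provenance.

    ``columns[k]`` is ``(ProcessId, kind, local_index)`` where kind is
    ``"csp"`` or ``"tsm"`` and local_index counts within the block.
    """

    values: np.ndarray
    columns: list[tuple[ProcessId, str, int]]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column metadata length does not match matrix")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        header = "\t".join(
            f"{pid}:{kind}{local}" for pid, kind, local in self.columns
        )
        np.savetxt(path, self.values, delimiter="\t", header=header, comments="")


@dataclass
class FScoreTable:
    """Fisher scores with their descending ranking (ties by index)."""

    scores: np.ndarray
    n_pos: int
    n_neg: int
    ranking: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # stable sort of -scores: descending scores, ascending index on ties
        self.ranking = np.argsort(-self.scores, kind="stable")


@dataclass(frozen=True)
class SelectionConfig:
    """Number of top-ranked features to keep (default 10)."""

    r: int = 10

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("r must be >= 1")


def process_ids(n_windows: int) -> list[ProcessId]:
    """Fixed process order: CSP-TSM per window, then CSSP-TSM per pair."""
    singles = [ProcessId("csp_tsm", i) for i in range(n_windows)]
    return singles + cssp_process_ids(n_windows)


def _process_input(trials: np.ndarray, process: ProcessId, spec: WindowSpec) -> np.ndarray:
    """Window (and possibly channel-stack) a trial batch for one process."""
    windows = make_windows(trials, spec)
    if process.kind == "csp_tsm":
        return windows[process.window_i]
    return np.concatenate(
        [windows[process.window_i], windows[process.window_j]], axis=-2
    )


def fit_process(
    trials: np.ndarray,
    labels: np.ndarray,
    process: ProcessId,
    window_spec: WindowSpec,
    m: int = 3,
) -> ProcessModel:
    """Fit one process on training trials (n, C, T).

    Learns the CSP bank on the process's windows, filters the training
    trials, and computes the Riemannian mean of their covariances (the
    tangent-space reference used for unseen trials).
    """
    X = _process_input(np.asarray(trials), process, window_spec)
    bank = learn_csp(X, labels, m=m)
    Z = apply_filters(bank, X)
    covs = np.stack([trial_covariance(z) for z in Z])
    mean = riemannian_mean(covs)
    return ProcessModel(process=process, window_spec=window_spec, bank=bank, mean=mean)


def transform_process(model: ProcessModel, trials: np.ndarray) -> np.ndarray:
    """Extract the 2m CSP + d(d+1)/2 TSM features for each trial."""
    X = _process_input(np.asarray(trials), model.process, model.window_spec)
    Z = apply_filters(model.bank, X)
    csp = csp_features(Z)
    covs = np.stack([trial_covariance(z) for z in Z])
    tsm = tangent_vectors(model.mean, covs)
    return np.concatenate([csp, tsm], axis=1)


def assemble_features(
    trials: np.ndarray,
    labels: np.ndarray,
    window_spec: WindowSpec,
    m: int = 3,
) -> tuple[FeatureMatrix, list[ProcessModel]]:
    """Fit every process and fuse their features.

    For ``n`` windows the matrix has ``(n + n(n-1)/2) * (2m + 2m(2m+1)/2)``
    columns: 162 for the defaults ``n = 3``, ``m = 3``.
    """
    trials = np.asarray(trials)
    labels = np.asarray(labels)
    models: list[ProcessModel] = []
    blocks: list[np.ndarray] = []
    columns: list[tuple[ProcessId, str, int]] = []
    for pid in process_ids(window_spec.n_windows):
        model = fit_process(trials, labels, pid, window_spec, m=m)
        block = transform_process(model, trials)
        models.append(model)
        blocks.append(block)
        d = model.bank.n_filters
        columns.extend((pid, "csp", k) for k in range(d))
        columns.extend((pid, "tsm", k) for k in range(d * (d + 1) // 2))
    values = np.concatenate(blocks, axis=1)
    return FeatureMatrix(values=values, columns=columns, labels=labels), models


def transform_features(models: list[ProcessModel], trials: np.ndarray) -> np.ndarray:
    """Feature matrix of unseen trials under already-fitted processes."""
    return np.concatenate(
        [transform_process(model, np.asarray(trials)) for model in models], axis=1
    )


def _score_columns(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 samples")
    overall = values.mean(axis=0)
    numerator = (pos.mean(axis=0) - overall) ** 2 + (neg.mean(axis=0) - overall) ** 2
    denominator = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = numerator / denominator
    degenerate = denominator == 0
    if degenerate.any():
        separating = degenerate & (numerator > 0)
        if separating.any():
            warnings.warn(
                "feature(s) with zero within-class variance and distinct class "
                "means: Fisher score set to +inf (perfectly separating)",
                RuntimeWarning,
            )
        scores[degenerate] = np.where(separating[degenerate], np.inf, 0.0)
    return scores


def f_score(column: np.ndarray, labels: np.ndarray) -> float:
    """Fisher score of a single feature column.

    Squared deviations of the class means from the overall mean, divided
    by the sum of the within-class sample variances (N-1 denominators).
    Zero when the class distributions coincide; grows quadratically with
    the class-mean separation.
    """
    column = np.asarray(column, dtype=np.float64)
    return float(_score_columns(column[:, None], labels)[0])


def f_scores(features: FeatureMatrix | np.ndarray, labels: np.ndarray | None = None) -> FScoreTable:
    """Fisher scores of every column, with descending ranking."""
    if isinstance(features, FeatureMatrix):
        values = features.values
        if labels is None:
            labels = features.labels
    else:
        values = np.asarray(features, dtype=np.float64)
    if labels is None:
        raise ValueError("labels required")
    labels = np.asarray(labels)
    scores = _score_columns(values, labels)
    return FScoreTable(
        scores=scores,
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == -1).sum()),
    )


def rank_features(features, labels=None) -> np.ndarray:
    """Convenience: feature indices in descending Fisher-score order."""
    return f_scores(features, labels).ranking


def select_top_r(table: FScoreTable, cfg: SelectionConfig = SelectionConfig()) -> np.ndarray:
    """Indices of the ``r`` best-scoring features (ties to lower index)."""
    n = len(table.scores)
    if n == 0:
        raise ValueError("empty score table")
    r = cfg.r
    if r > n:
        warnings.warn(f"r={r} exceeds {n} features; clamping", RuntimeWarning)
        r = n
    return table.ranking[:r].copy()
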