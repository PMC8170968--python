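"""End-to-end training, delay selection, cross-validated evaluation.

The full predictor chains: preprocessing (CAR + 7-30 Hz Butterworth +
0.5-2.5 s epoch), ``n = 3`` delay windows, six CSP-TSM/CSSP-TSM feature
processes, Fisher-score selection of the top ``r = 10`` of 162 features,
z-scoring with training statistics, and an RBF-kernel SVM.  The window
delay ``tau`` is subject-dependent: it is chosen by an inner stratified
cross-validation over a grid of 1..10% of the sampling rate, on training
data only, with ties resolved to the smallest delay.  Evaluation follows
a repeated stratified k-fold protocol (10 x 10-fold by default) reporting
the classification error rate and Cohen's kappa.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .containers import TrialSet
from .features import (
    FScoreTable,
    ProcessModel,
    SelectionConfig,
    assemble_features,
    f_scores,
    select_top_r,
    transform_features,
)
from .preprocessing import FilterSpec, preprocess_trials
from .spatial import WindowSpec

__all__ = [
    "PipelineConfig",
    "SpectraModel",
    "FoldResult",
    "CVReport",
    "default_tau_grid",
    "train_spectra",
    "predict",
    "select_tau",
    "cross_validate",
    "stratified_folds",
    "error_rate",
    "cohen_kappa",
    "kappa_strength",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the predictor, with protocol defaults.

    ``tau_grid`` of None means 1..round(0.1 * fs) samples, resolved once
    the sampling rate is known.  ``svm_gamma`` of None applies the rule
    ``1 / (r * mean feature variance)`` on the standardized training
    features (i.e. approximately ``1 / r``).
    """

    band: tuple[float, float] = (7.0, 30.0)
    filter_order: int = 4
    zero_phase: bool = True
    epoch_window: tuple[float, float] = (0.5, 2.5)
    n_windows: int = 3
    window_len_s: float = 2.0
    m_pairs: int = 3
    r: int = 10
    tau_grid: tuple[int, ...] | None = None
    svm_c: float = 1.0
    svm_gamma: float | None = None
    outer_repeats: int = 10
    outer_folds: int = 10
    inner_folds: int = 10
    seed: int = 0

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            low=self.band[0],
            high=self.band[1],
            order=self.filter_order,
            zero_phase=self.zero_phase,
        )

    def resolve_tau_grid(self, fs: float) -> tuple[int, ...]:
        if self.tau_grid is not None:
            grid = tuple(int(t) for t in self.tau_grid)
        else:
            grid = tuple(range(1, int(round(0.1 * fs)) + 1))
        if not grid or any(t < 1 for t in grid):
            raise ValueError("tau grid must be nonempty with all taus >= 1")
        return grid


@dataclass
class SpectraModel:
    """A fully fitted predictor, sufficient for single-trial prediction."""

    config: PipelineConfig
    tau: int
    window_spec: WindowSpec
    process_models: list[ProcessModel]
    score_table: FScoreTable
    selected: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    svm: SVC


@dataclass
class FoldResult:
    repeat: int
    fold: int
    n_test: int
    error: float
    kappa: float
    tau: int
    selected: list[int]


@dataclass
class CVReport:
    """Repeated stratified k-fold results with aggregates."""

    folds: list[FoldResult]
    seed: int

    @property
    def errors(self) -> np.ndarray:
        return np.array([f.error for f in self.folds])

    @property
    def kappas(self) -> np.ndarray:
        return np.array([f.kappa for f in self.folds])

    @property
    def mean_error(self) -> float:
        return float(self.errors.mean())

    @property
    def sd_error(self) -> float:
        return float(self.errors.std(ddof=1)) if len(self.folds) > 1 else 0.0

    @property
    def mean_kappa(self) -> float:
        return float(self.kappas.mean())

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mean_error_pct": self.mean_error,
            "sd_error_pct": self.sd_error,
            "mean_kappa": self.mean_kappa,
            "folds": [
                {
                    "repeat": f.repeat,
                    "fold": f.fold,
                    "n_test": f.n_test,
                    "error_pct": f.error,
                    "kappa": f.kappa,
                    "tau": f.tau,
                    "selected_features": list(map(int, f.selected)),
                }
                for f in self.folds
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def default_tau_grid(fs: float) -> tuple[int, ...]:
    """Delays of 1..10% of the sampling rate, in samples."""
    return tuple(range(1, int(round(0.1 * fs)) + 1))


def _as_arrays(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, TrialSet):
        return trials.data, trials.labels
    raise TypeError("expected a TrialSet")


def train_spectra(
    data: np.ndarray, labels: np.ndarray, cfg: PipelineConfig, tau: int
) -> SpectraModel:
    """Fit the full predictor on preprocessed trials (n, C, T) at a given tau."""
    data = np.asarray(data)
    labels = np.asarray(labels)
    window_spec = WindowSpec(
        n_windows=cfg.n_windows, tau=int(tau), window_len_s=cfg.window_len_s
    )
    fm, models = assemble_features(data, labels, window_spec, m=cfg.m_pairs)
    table = f_scores(fm)
    selected = select_top_r(table, SelectionConfig(r=min(cfg.r, fm.n_features)))
    X = fm.values[:, selected]
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    if cfg.svm_gamma is not None:
        gamma = cfg.svm_gamma
    else:
        mean_var = float(Xs.var(axis=0).mean())
        gamma = 1.0 / (Xs.shape[1] * mean_var) if mean_var > 0 else 1.0
    svm = SVC(C=cfg.svm_c, kernel="rbf", gamma=gamma)
    svm.fit(Xs, labels)
    return SpectraModel(
        config=cfg,
        tau=int(tau),
        window_spec=window_spec,
        process_models=models,
        score_table=table,
        selected=selected,
        scaler_mean=mean,
        scaler_scale=scale,
        svm=svm,
    )


def predict(model: SpectraModel, data: np.ndarray) -> np.ndarray:
    """Predict +1/-1 for preprocessed trials; accepts a single C x T trial."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    X = transform_features(model.process_models, data)[:, model.selected]
    Xs = (X - model.scaler_mean) / model.scaler_scale
    return model.svm.predict(Xs).astype(np.int64)


def stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-stratified fold assignment: per-class shuffle then round-robin.

    Returns ``k`` disjoint test-index arrays covering all trials, with the
    per-class counts across folds differing by at most one.
    """
    labels = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (1, -1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls:+d} has {len(idx)} trials; need at least {k} "
                f"for {k}-fold stratified CV"
            )
        idx = rng.permutation(idx)
        for pos, trial in enumerate(idx):
            folds[pos % k].append(int(trial))
    return [np.sort(np.array(f)) for f in folds]


def _pick_tau(grid, mean_errors) -> int:
    """Smallest tau achieving the minimum mean inner-CV error."""
    grid = list(grid)
    mean_errors = np.asarray(mean_errors, dtype=float)
    best = mean_errors.min()
    candidates = [t for t, e in zip(grid, mean_errors) if e <= best]
    return int(min(candidates))


def select_tau(
    data: np.ndarray,
    labels: np.ndarray,
    cfg: PipelineConfig,
    fs: float,
    seed: int | None = None,
) -> int:
    """Choose the window delay by inner stratified cross-validation.

    Runs the full train/predict pipeline for every tau in the grid on
    ``cfg.inner_folds`` stratified folds of the (training) data and
    returns the tau of minimum mean error; ties go to the smallest tau,
    which also keeps single-trial processing cheap.
    """
    grid = cfg.resolve_tau_grid(fs)
    if len(grid) == 1:
        return grid[0]
    data = np.asarray(data)
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    folds = stratified_folds(labels, cfg.inner_folds, rng)
    all_idx = np.arange(len(labels))
    mean_errors = []
    for tau in grid:
        errors = []
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            model = train_spectra(data[train_idx], labels[train_idx], cfg, tau)
            pred = predict(model, data[test_idx])
            errors.append(error_rate(labels[test_idx], pred))
        mean_errors.append(float(np.mean(errors)))
    return _pick_tau(grid, mean_errors)


def cross_validate(
    trials: TrialSet,
    cfg: PipelineConfig = PipelineConfig(),
    preprocess: bool = True,
) -> CVReport:
    """Repeated stratified k-fold evaluation with nested tau selection.

    Preprocessing (CAR, band-pass, epoch crop) is per-trial and applied
    once up front; everything that depends on more than one trial
    (spatial filters, Riemannian means, Fisher scores, scaler, SVM, tau)
    is fitted inside each training fold only.
    """
    if preprocess:
        trials = preprocess_trials(
            trials, cfg.filter_spec(), epoch_window=cfg.epoch_window
        )
    data, labels = _as_arrays(trials)
    n_per_class = min(int((labels == 1).sum()), int((labels == -1).sum()))
    if n_per_class < cfg.outer_folds:
        raise ValueError(
            f"need at least {cfg.outer_folds} trials per class, got {n_per_class}"
        )
    results: list[FoldResult] = []
    all_idx = np.arange(len(labels))
    for repeat in range(cfg.outer_repeats):
        rng = np.random.default_rng(cfg.seed + repeat)
        folds = stratified_folds(labels, cfg.outer_folds, rng)
        for fold_i, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            inner_seed = cfg.seed + 1000 * (repeat + 1) + fold_i
            tau = select_tau(
                data[train_idx], labels[train_idx], cfg, trials.fs, seed=inner_seed
            )
            model = train_spectra(data[train_idx], labels[train_idx], cfg, tau)
            pred = predict(model, data[test_idx])
            results.append(
                FoldResult(
                    repeat=repeat,
                    fold=fold_i,
                    n_test=len(test_idx),
                    error=error_rate(labels[test_idx], pred),
                    kappa=cohen_kappa(labels[test_idx], pred),
                    tau=tau,
                    selected=[int(i) for i in model.selected],
                )
            )
    return CVReport(folds=results, seed=cfg.seed)


def error_rate(true: np.ndarray, predicted: np.ndarray) -> float:
    """Percentage of trials classified incorrectly."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.size == 0:
        raise ValueError("empty label arrays")
    if true.shape != predicted.shape:
        raise ValueError("length mismatch")
    return float(100.0 * np.mean(true != predicted))


def cohen_kappa(true: np.ndarray, predicted: np.ndarray) -> float:
    """Chance-corrected agreement kappa = (p_a - p_e) / (1 - p_e).

    ``p_a`` is the observed agreement proportion and ``p_e`` the expected
    agreement from the confusion-matrix marginals.  Perfect agreement
    gives 1 by convention even when ``p_e = 1``; a degenerate ``p_e = 1``
    with imperfect agreement gives 0 with a warning.
    """
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.size == 0:
        raise ValueError("empty label arrays")
    if true.shape != predicted.shape:
        raise ValueError("length mismatch")
    n = true.size
    p_a = float(np.mean(true == predicted))
    if p_a == 1.0:
        return 1.0
    p_e = 0.0
    for cls in (1, -1):
        p_e += (np.sum(true == cls) / n) * (np.sum(predicted == cls) / n)
    if p_e >= 1.0:
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 0",
                      RuntimeWarning)
        return 0.0
    return float((p_a - p_e) / (1.0 - p_e))


_STRENGTH_BANDS = [
    (0.20, "Poor"),
    (0.40, "Fair"),
    (0.60, "Moderate"),
    (0.80, "Good"),
    (1.00, "Very Good"),
]


def kappa_strength(kappa: float) -> str:
    """Qualitative strength of agreement for a kappa value.

    Bands: < 0.20 Poor, 0.21-0.40 Fair, 0.41-0.60 Moderate, 0.61-0.80
    Good, 0.81-1.0 Very Good.  Values falling in the printed gaps (e.g.
    0.205) are assigned by rounding to 2 decimals first.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    rounded = round(kappa, 2)
    for upper, label in _STRENGTH_BANDS:
        if rounded <= upper:
            return label
    return "Very Good"
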