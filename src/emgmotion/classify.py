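"""Soft-margin RBF-SVM window classifier with GA hyperparameter tuning.

The classifier solves the usual soft-margin problem (penalty ``C`` on the
slack variables) with the radial basis kernel

    kappa(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 delta^2)),

parameterized internally by scikit-learn's ``gamma = 1 / (2 delta^2)``;
exact conversion helpers are provided both ways.  Multiclass decisions use
one-vs-one voting.  Feature columns are standardized (z-score fit on the
training data only) before the kernel — RBF distances need comparable
scales — with a flag to disable scaling.

Hyperparameters (C, delta) are tuned by a small real-coded genetic
algorithm on a log10 scale with tournament selection, blend crossover,
Gaussian mutation and elitism; the fitness is mean stratified
cross-validation accuracy on folds fixed per run, and the default
parameters (C = 1, gamma = 1/num_features) are seeded into the initial
population as a warm start, so the tuned result can never undercut the
default on the same folds.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ConfigError, DomainError, ValidationError
from .features import FeatureMatrix


def delta_to_gamma(delta: float) -> float:
    """Kernel width delta -> scikit-learn gamma = 1/(2 delta^2)."""
    if delta <= 0:
        raise ConfigError(f"delta must be positive, got {delta}")
    return 1.0 / (2.0 * delta * delta)


def gamma_to_delta(gamma: float) -> float:
    """scikit-learn gamma -> kernel width delta = 1/sqrt(2 gamma)."""
    if gamma <= 0:
        raise ConfigError(f"gamma must be positive, got {gamma}")
    return 1.0 / np.sqrt(2.0 * gamma)


def rbf_kernel_matrix(x: np.ndarray, z: np.ndarray, delta: float) -> np.ndarray:
    """Gram matrix of the RBF kernel exp(-||x-z||^2 / (2 delta^2))."""
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    sq = (
        (x**2).sum(axis=1)[:, None]
        + (z**2).sum(axis=1)[None, :]
        - 2.0 * x @ z.T
    )
    return np.exp(-np.maximum(sq, 0.0) / (2.0 * delta * delta))


@dataclasses.dataclass(frozen=True)
class SVMParams:
    """Soft-margin penalty C and RBF kernel width delta."""

    C: float = 1.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.delta <= 0:
            raise ConfigError(f"C and delta must be positive, got C={self.C}, delta={self.delta}")

    @property
    def gamma(self) -> float:
        return delta_to_gamma(self.delta)

    @classmethod
    def from_gamma(cls, C: float, gamma: float) -> "SVMParams":
        return cls(C=C, delta=gamma_to_delta(gamma))

    @classmethod
    def default_for(cls, n_features: int, C: float = 1.0) -> "SVMParams":
        """The conventional library default: gamma = 1/num_features."""
        return cls.from_gamma(C=C, gamma=1.0 / n_features)


@dataclasses.dataclass
class SVMModel:
    """A trained multiclass RBF-SVM plus the metadata to validate inputs."""

    params: SVMParams
    classes: tuple[str, ...]
    feature_names: tuple[str, ...] | None
    pipeline: Pipeline

    @property
    def svc(self) -> SVC:
        return self.pipeline.named_steps["svc"]


@dataclasses.dataclass
class GAConfig:
    """Genetic-algorithm settings for (C, delta) search (log10 scale)."""

    pop_size: int = 30
    generations: int = 40
    C_range: tuple[float, float] = (1e-3, 1e3)
    delta_range: tuple[float, float] = (1e-2, 1e4)
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_sigma: float = 0.25  # in log10 units
    tournament_k: int = 3
    cv_folds: int = 5
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("C_range", "delta_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ConfigError(f"{name} must satisfy 0 < low < high, got {(lo, hi)}")
        for name in ("crossover_rate", "mutation_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")
        if self.pop_size < 1 or self.generations < 1:
            raise ConfigError("pop_size and generations must be >= 1")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")


@dataclasses.dataclass
class EvalReport:
    """Confusion matrix and the derived per-class metrics.

    ``per_class`` maps each class to precision, recall and F1 (zero when a
    denominator vanishes).  When produced by repeated cross-validation,
    ``accuracy_mean``/``accuracy_sd`` summarize overall accuracy across
    repeats and ``per_class_accuracy`` the per-class recall across repeats
    (mean +- sd), matching the usual "xx.xx +- x.xx%" reporting style.
    """

    classes: tuple[str, ...]
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    overall_accuracy: float
    accuracy_mean: float | None = None
    accuracy_sd: float | None = None
    per_class_accuracy: dict[str, tuple[float, float]] | None = None
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        out = {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
        }
        if self.accuracy_mean is not None:
            out["accuracy_mean"] = self.accuracy_mean
            out["accuracy_sd"] = self.accuracy_sd
        if self.per_class_accuracy is not None:
            out["per_class_accuracy"] = {
                k: list(v) for k, v in self.per_class_accuracy.items()
            }
        if self.notes:
            out["notes"] = list(self.notes)
        return out


def _as_array(X: FeatureMatrix | np.ndarray) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(X, FeatureMatrix):
        return X.values, X.feature_names
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("feature input must be 2-D")
    return arr, None


def train_svm(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[str],
    params: SVMParams | None = None,
    scale: bool = True,
) -> SVMModel:
    """Fit the one-vs-one soft-margin RBF-SVM.

    Deterministic given a fixed row order.  ``scale=False`` drops the
    z-score step and feeds raw features to the kernel.
    """
    arr, names = _as_array(X)
    y = np.asarray(y)
    if len(y) != arr.shape[0]:
        raise ValidationError(f"{arr.shape[0]} rows but {len(y)} labels")
    if not np.isfinite(arr).all():
        raise ValidationError("feature matrix contains non-finite values")
    classes = tuple(dict.fromkeys(y.tolist()))  # preserve first-seen order
    if len(classes) < 2:
        raise DomainError("training needs at least two classes")
    params = params or SVMParams.default_for(arr.shape[1])
    steps = []
    if scale:
        steps.append(("scaler", StandardScaler()))
    steps.append(
        (
            "svc",
            SVC(
                C=params.C,
                kernel="rbf",
                gamma=params.gamma,
                decision_function_shape="ovr",
            ),
        )
    )
    pipe = Pipeline(steps)
    pipe.fit(arr, y)
    return SVMModel(
        params=params,
        classes=tuple(str(c) for c in pipe.named_steps["svc"].classes_),
        feature_names=names,
        pipeline=pipe,
    )


def predict_windows(model: SVMModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """One label per row; validates feature width (and names when known)."""
    arr, names = _as_array(X)
    n_expected = model.svc.n_features_in_
    if arr.shape[1] != n_expected:
        raise ValidationError(
            f"feature width mismatch: model expects {n_expected} columns, "
            f"got {arr.shape[1]}"
        )
    if (
        names is not None
        and model.feature_names is not None
        and names != model.feature_names
    ):
        raise ValidationError(
            "feature columns differ from the model's training columns"
        )
    return model.pipeline.predict(arr)


def decision_scores(model: SVMModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-class decision values (one-vs-rest aggregation of the ovo votes)."""
    arr, _ = _as_array(X)
    scores = model.pipeline.decision_function(arr)
    if scores.ndim == 1:  # binary: expand to two columns
        scores = np.column_stack([-scores, scores])
    return scores


def confusion_and_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str],
) -> EvalReport:
    """Confusion counts plus per-class precision / recall / F1.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R); a
    vanishing denominator yields 0 with a note in the report.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    classes = tuple(classes)
    known = set(classes)
    stray = sorted({*y_true.tolist(), *y_pred.tolist()} - known)
    if stray:
        raise ValidationError(f"labels {stray} not in declared classes {classes}")
    cm = confusion_matrix(y_true, y_pred, labels=list(classes))
    per_class: dict[str, dict[str, float]] = {}
    notes = []
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        if tp + fp == 0 or tp + fn == 0:
            notes.append(f"{cls}: empty precision/recall denominator, metric set to 0")
        f1 = f1_score(precision, recall)
        per_class[cls] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
        }
    overall = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return EvalReport(
        classes=classes,
        confusion=cm,
        per_class=per_class,
        overall_accuracy=overall,
        notes=tuple(notes),
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def cross_validate(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[str],
    params: SVMParams | None = None,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    scale: bool = True,
) -> EvalReport:
    """Repeated stratified k-fold evaluation.

    Folds are re-randomized per repeat from ``seed``.  Reports mean +- sd
    of overall accuracy and of per-class accuracy (recall) across repeats,
    plus the confusion matrix pooled over every held-out prediction.
    """
    arr, _ = _as_array(X)
    y = np.asarray(y)
    classes = tuple(dict.fromkeys(y.tolist()))
    if folds < 2:
        raise DomainError("folds must be >= 2")
    counts = {c: int((y == c).sum()) for c in classes}
    small = {c: n for c, n in counts.items() if n < folds}
    if small:
        raise DomainError(
            f"classes smaller than fold count {folds}: {small}"
        )
    params = params or SVMParams.default_for(arr.shape[1])
    acc_per_repeat = []
    class_acc: dict[str, list[float]] = {c: [] for c in classes}
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=(seed + rep) % 2**31
        )
        y_pred = np.empty_like(y)
        for train_idx, test_idx in skf.split(arr, y):
            model = train_svm(arr[train_idx], y[train_idx], params, scale=scale)
            y_pred[test_idx] = predict_windows(model, arr[test_idx])
        acc_per_repeat.append(float((y_pred == y).mean()))
        for c in classes:
            mask = y == c
            class_acc[c].append(float((y_pred[mask] == c).mean()))
        pooled_true.append(y)
        pooled_pred.append(y_pred)
    report = confusion_and_metrics(
        np.concatenate(pooled_true), np.concatenate(pooled_pred), classes
    )
    report.accuracy_mean = float(np.mean(acc_per_repeat))
    report.accuracy_sd = float(np.std(acc_per_repeat))
    report.per_class_accuracy = {
        c: (float(np.mean(v)), float(np.std(v))) for c, v in class_acc.items()
    }
    return report


def _cv_fitness(
    arr: np.ndarray,
    y: np.ndarray,
    params: SVMParams,
    fold_indices: list[tuple[np.ndarray, np.ndarray]],
    scale: bool,
) -> float:
    """Mean held-out accuracy over pre-computed folds."""
    accs = []
    for train_idx, test_idx in fold_indices:
        model = train_svm(arr[train_idx], y[train_idx], params, scale=scale)
        pred = predict_windows(model, arr[test_idx])
        accs.append(float((pred == y[test_idx]).mean()))
    return float(np.mean(accs))


def ga_optimize(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[str],
    ga: GAConfig | None = None,
    scale: bool = True,
) -> tuple[SVMParams, list[float]]:
    """Tune (C, delta) by a real-coded GA; returns best params and the
    per-generation best-fitness curve (non-decreasing, by elitism).

    Chromosomes are (log10 C, log10 delta).  Cross-validation folds are
    drawn once per run from ``ga.seed`` and shared by every fitness
    evaluation, so candidate comparisons (including against the warm-start
    default) are on identical data splits.
    """
    ga = ga or GAConfig()
    arr, _ = _as_array(X)
    y = np.asarray(y)
    rng = np.random.default_rng(ga.seed)
    skf = StratifiedKFold(n_splits=ga.cv_folds, shuffle=True, random_state=ga.seed % 2**31)
    fold_indices = list(skf.split(arr, y))

    lo = np.log10([ga.C_range[0], ga.delta_range[0]])
    hi = np.log10([ga.C_range[1], ga.delta_range[1]])

    def clip(genome: np.ndarray) -> np.ndarray:
        return np.clip(genome, lo, hi)

    def to_params(genome: np.ndarray) -> SVMParams:
        return SVMParams(C=10.0 ** genome[0], delta=10.0 ** genome[1])

    cache: dict[tuple[float, float], float] = {}

    def fitness(genome: np.ndarray) -> float:
        key = (round(float(genome[0]), 9), round(float(genome[1]), 9))
        if key not in cache:
            cache[key] = _cv_fitness(arr, y, to_params(genome), fold_indices, scale)
        return cache[key]

    # Initial population: warm-start default + uniform log-space samples.
    default = SVMParams.default_for(arr.shape[1])
    pop = [clip(np.log10([default.C, default.delta]))]
    while len(pop) < ga.pop_size:
        pop.append(rng.uniform(lo, hi))
    fits = [fitness(g) for g in pop]

    history = [max(fits)]
    for _ in range(ga.generations):
        order = np.argsort(fits)[::-1]
        elites = [pop[i].copy() for i in order[: ga.elitism]]
        children = list(elites)
        while len(children) < ga.pop_size:
            pa = _tournament(pop, fits, ga.tournament_k, rng)
            pb = _tournament(pop, fits, ga.tournament_k, rng)
            if rng.random() < ga.crossover_rate:
                alpha = rng.uniform(-0.5, 1.5, size=2)  # blend (BLX)
                child = alpha * pa + (1.0 - alpha) * pb
            else:
                child = pa.copy()
            mutate = rng.random(2) < ga.mutation_rate
            child = child + mutate * rng.normal(0.0, ga.mutation_sigma, size=2)
            children.append(clip(child))
        pop = children
        fits = [fitness(g) for g in pop]
        history.append(max(max(fits), history[-1]))

    best = pop[int(np.argmax(fits))]
    # The elite carried the all-time best forward, so the final argmax is
    # the global best evaluated.
    return to_params(best), history


def _tournament(
    pop: list[np.ndarray],
    fits: list[float],
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    idx = rng.integers(0, len(pop), size=min(k, len(pop)))
    winner = max(idx, key=lambda i: fits[i])
    return pop[winner]
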