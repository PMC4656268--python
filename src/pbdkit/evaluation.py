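"""Repeated stratified cross-validation and binary-classification metrics.

The evaluation protocol mirrors common practice for small medical-imaging
datasets: K-fold cross-validation with per-fold class proportions matched
to the whole set (stratification), repeated R times with reshuffled folds,
and metrics computed with the pathological class as positive.  Confusion
counts are pooled across the K folds within a run, percentages are then
averaged across runs.

Everything fitted from data — fuzzy memberships, optional feature scaling,
a nested choice of the error penalty C — is fitted on the training folds
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import features as _features
from . import fsvm as _fsvm
from .exceptions import ValidationError


# --------------------------------------------------------------------------
# metrics

@dataclass
class Metrics:
    """Confusion counts and derived percentages (pathological = positive).

    A metric whose denominator is zero is undefined and reported as
    ``None``, never as 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "precision": self.precision,
        }

    def __add__(self, other: "Metrics") -> "Metrics":
        return Metrics(self.tp + other.tp, self.tn + other.tn,
                       self.fp + other.fp, self.fn + other.fn)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Confusion counts for ±1 labels, +1 (pathological) positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors differ in length")
    return Metrics(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == -1) & (y_pred == -1)).sum()),
        fp=int(((y_true == -1) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == -1)).sum()),
    )


# --------------------------------------------------------------------------
# fold assignment

def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Within each class the sample indices are shuffled with ``seed`` and
    dealt to folds round-robin, so per-class counts across folds differ by
    at most one (and are exactly equal when the class size divides K).
    Returns an integer fold id per sample.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValidationError(f"need at least 2 folds, got {k}")
    if n < k:
        raise ValidationError(f"{n} samples cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            warnings.warn(
                f"class {cls} has only {len(idx)} samples for {k} folds; "
                "some folds will miss it"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class ModelConfig:
    """Classifier settings for one CV experiment."""

    C: float = 10.0
    kernel: _fsvm.KernelSpec = field(default_factory=_fsvm.KernelSpec)
    fuzzy: bool = True
    delta: float | None = None          # None -> relative default
    rel_delta: float = 1e-3
    scale_features: bool = False
    C_grid: tuple[float, ...] | None = None  # nested C selection when set


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation design: K folds, R runs, base seed."""

    k: int = 5
    runs: int = 10
    seed: int = 0


@dataclass
class CVReport:
    """Per-run pooled metrics plus per-fold detail."""

    run_metrics: list[Metrics]
    fold_metrics: list[list[Metrics]]
    degenerate_folds: int = 0
    chosen_C: list[float] = field(default_factory=list)

    def _mean(self, attr: str) -> float | None:
        vals = [getattr(m, attr) for m in self.run_metrics]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_accuracy(self) -> float | None:
        return self._mean("accuracy")

    @property
    def mean_sensitivity(self) -> float | None:
        return self._mean("sensitivity")

    @property
    def mean_specificity(self) -> float | None:
        return self._mean("specificity")

    @property
    def mean_precision(self) -> float | None:
        return self._mean("precision")

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(run=i, **m.as_dict()) for i, m in enumerate(self.run_metrics)]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "runs": len(self.run_metrics),
            "mean_accuracy": self.mean_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "mean_precision": self.mean_precision,
        }


# --------------------------------------------------------------------------
# training helpers

class _Scaler:
    """Z-scoring fitted on the training fold only."""

    def fit(self, X: np.ndarray) -> "_Scaler":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


def _fit_fold(X_tr, y_tr, config: ModelConfig, C: float) -> tuple:
    scaler = None
    if config.scale_features:
        scaler = _Scaler().fit(X_tr)
        X_tr = scaler.transform(X_tr)
    s = None
    if config.fuzzy:
        mm = _fsvm.fit_membership(X_tr, y_tr, delta=config.delta,
                                  rel_delta=config.rel_delta)
        s = _fsvm.membership(mm, X_tr, y_tr)
    model = _fsvm.train_fsvm(X_tr, y_tr, s=s, C=C, kernel=config.kernel)
    return model, scaler


def _select_C(X_tr, y_tr, config: ModelConfig, k: int, seed: int) -> float:
    """Inner stratified CV on the training partition; ties -> smallest C."""
    grid = sorted(config.C_grid)  # type: ignore[arg-type]
    if len(grid) == 1:
        return grid[0]
    k_inner = min(k, int(min(np.bincount((np.asarray(y_tr) == 1).astype(int)))))
    k_inner = max(2, k_inner)
    folds = stratified_kfold(y_tr, k_inner, seed)
    best_C, best_acc = grid[0], -1.0
    for C in grid:
        pooled = Metrics(0, 0, 0, 0)
        for f in range(k_inner):
            tr, te = folds != f, folds == f
            if len(np.unique(y_tr[tr])) < 2 or te.sum() == 0:
                continue
            model, scaler = _fit_fold(X_tr[tr], y_tr[tr], config, C)
            X_te = scaler.transform(X_tr[te]) if scaler else X_tr[te]
            pred, _ = _fsvm.predict(model, X_te)
            pooled = pooled + confusion(y_tr[te], pred)
        acc = pooled.accuracy if pooled.accuracy is not None else -1.0
        if acc > best_acc:
            best_acc, best_C = acc, C
    return best_C


# --------------------------------------------------------------------------
# cross-validation

def run_cv(X: np.ndarray, y: np.ndarray, model_config: ModelConfig = ModelConfig(),
           cv_config: CVConfig = CVConfig()) -> CVReport:
    """Repeated stratified K-fold cross-validation of the (F)SVM.

    For every run the folds are reshuffled with ``seed + run``; memberships,
    scaling and (when a ``C_grid`` is set) the error penalty are fitted or
    chosen on the K-1 training folds only.  Within a run the confusion
    counts of the K test folds are pooled; the report averages the pooled
    percentages across runs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y):
        raise ValidationError("features and labels differ in length")
    run_metrics: list[Metrics] = []
    fold_metrics: list[list[Metrics]] = []
    degenerate = 0
    chosen_C: list[float] = []
    for r in range(cv_config.runs):
        seed = cv_config.seed + r
        folds = stratified_kfold(y, cv_config.k, seed)
        pooled = Metrics(0, 0, 0, 0)
        per_fold: list[Metrics] = []
        for f in range(cv_config.k):
            tr, te = folds != f, folds == f
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                degenerate += 1
            if len(np.unique(y[tr])) < 2 or te.sum() == 0:
                continue
            C = model_config.C
            if model_config.C_grid is not None:
                C = _select_C(X[tr], y[tr], model_config, cv_config.k, seed)
                chosen_C.append(C)
            model, scaler = _fit_fold(X[tr], y[tr], model_config, C)
            X_te = scaler.transform(X[te]) if scaler else X[te]
            pred, _ = _fsvm.predict(model, X_te)
            m = confusion(y[te], pred)
            per_fold.append(m)
            pooled = pooled + m
        run_metrics.append(pooled)
        fold_metrics.append(per_fold)
    return CVReport(run_metrics=run_metrics, fold_metrics=fold_metrics,
                    degenerate_folds=degenerate, chosen_C=chosen_C)


# --------------------------------------------------------------------------
# grid searches

def grid_search_q(
    images: list[np.ndarray],
    labels: np.ndarray,
    q_grid=tuple(np.round(np.arange(0.1, 1.01, 0.1), 1)),
    model_config: ModelConfig = ModelConfig(),
    cv_config: CVConfig = CVConfig(),
    feature_config: _features.FeatureConfig = _features.FeatureConfig(),
) -> tuple[pd.DataFrame, float]:
    """Mean CV accuracy per entropic index q; returns (table, q*).

    Features are re-extracted for every q (one decomposition per image is
    shared across the grid, since only the entropy step depends on q).
    Ties in mean accuracy resolve to the smaller q.
    """
    if len(q_grid) == 0:
        raise ValidationError("q_grid must be non-empty")
    labels = np.asarray(labels, dtype=float)
    dists = [_features.subband_distributions(img, feature_config) for img in images]
    rows = []
    best_q, best_acc = None, -np.inf
    for q in sorted(float(q) for q in q_grid):
        X = np.array([_features.entropies_from_distributions(d, q) for d in dists])
        report = run_cv(X, labels, model_config, cv_config)
        acc = report.mean_accuracy
        rows.append({"q": q, "mean_accuracy": acc})
        if acc is not None and acc > best_acc:
            best_acc, best_q = acc, q
    return pd.DataFrame(rows), best_q


def grid_search_C(
    X: np.ndarray,
    y: np.ndarray,
    C_grid,
    model_config: ModelConfig = ModelConfig(),
    cv_config: CVConfig = CVConfig(),
    mode: str = "nested",
) -> tuple[pd.DataFrame, float]:
    """Select the error penalty C; returns (table, C*).

    ``mode="nested"`` (default) selects C inside each training partition by
    inner CV, so the reported accuracy is unbiased; C* is then the most
    frequently chosen candidate (ties -> smallest).  ``mode="outer"`` runs
    the full CV once per candidate and takes the argmax of mean accuracy
    (ties -> smallest), the simpler but optimistic convention.
    """
    if len(C_grid) == 0:
        raise ValidationError("C_grid must be non-empty")
    grid = sorted(float(C) for C in C_grid)
    if mode == "nested":
        cfg = replace(model_config, C_grid=tuple(grid))
        report = run_cv(X, y, cfg, cv_config)
        counts = pd.Series(report.chosen_C).value_counts()
        best = min(c for c in counts.index if counts[c] == counts.max())
        table = pd.DataFrame({"C": counts.index, "times_chosen": counts.values})
        return table.sort_values("C").reset_index(drop=True), float(best)
    if mode == "outer":
        rows = []
        best_C, best_acc = None, -np.inf
        for C in grid:
            report = run_cv(X, y, replace(model_config, C=C, C_grid=None), cv_config)
            acc = report.mean_accuracy
            rows.append({"C": C, "mean_accuracy": acc})
            if acc is not None and acc > best_acc:
                best_acc, best_C = acc, C
        return pd.DataFrame(rows), best_C
    raise ValidationError(f"mode must be 'nested' or 'outer', got {mode!r}")
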