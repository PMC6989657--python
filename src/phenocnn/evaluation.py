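"""Cross-validated evaluation and learning curves for binary phenotyping.

Each phenotype is evaluated one-vs-rest: its label column against all other
notes.  Results come from stratified k-fold cross-validation (k = 10 by
default); per-metric summaries report the fold mean and the standard error
SE = sd / sqrt(k).  Learning curves rerun the same folds while randomly
subsampling each fold's *training* split to a fraction of its size — test
splits are identical across fractions, so curve points are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import precision_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "MetricSet",
    "CVSummary",
    "LearningCurve",
    "compute_metrics",
    "cross_validate",
    "learning_curve",
]

METRICS = ("precision", "recall", "f1", "auroc")


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float
    auroc: float  # nan when labels are single-class
    auroc_defined: bool = True

    def as_percent(self) -> dict:
        return {m: 100.0 * getattr(self, m) for m in METRICS}


@dataclass
class CVSummary:
    folds: list[MetricSet] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.folds)

    def values(self, metric: str) -> np.ndarray:
        return np.array([getattr(f, metric) for f in self.folds], dtype=float)

    def mean(self, metric: str) -> float:
        return float(np.nanmean(self.values(metric)))

    def se(self, metric: str) -> float:
        v = self.values(metric)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            return float("nan")
        return float(np.std(v, ddof=1) / np.sqrt(len(v)))

    def summary(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            m: {"mean": scale * self.mean(m), "se": scale * self.se(m)}
            for m in METRICS
        }


@dataclass
class LearningCurve:
    fractions: list[float]
    summaries: list[CVSummary]

    def mean(self, metric: str) -> list[float]:
        return [s.mean(metric) for s in self.summaries]


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricSet:
    """Thresholded precision/recall/F1 plus rank-based AUROC.

    AUROC uses the standard rank statistic with tie correction
    (:func:`sklearn.metrics.roc_auc_score`); with single-class labels it is
    undefined and flagged rather than raised.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    p = precision_score(labels, pred, zero_division=0)
    r = recall_score(labels, pred, zero_division=0)
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    if len(np.unique(labels)) < 2:
        return MetricSet(p, r, f1, float("nan"), auroc_defined=False)
    return MetricSet(p, r, f1, float(roc_auc_score(labels, scores)))


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 9973 + fold) % (2**31 - 1)


def _subsample(train_idx: np.ndarray, fraction: float, rng) -> np.ndarray:
    n_keep = max(1, int(round(fraction * len(train_idx))))
    chosen = rng.choice(train_idx, size=n_keep, replace=False)
    return np.sort(chosen)


def _run(estimator, X, y, fractions, k, seed):
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"need at least k={k} samples of each class for stratified folds "
            f"(have {counts.tolist()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    summaries = [CVSummary() for _ in fractions]
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fs = _fold_seed(seed, fold)
        for fi, fraction in enumerate(fractions):
            rng = np.random.default_rng(_fold_seed(fs, fi))
            sub = _subsample(np.sort(train_idx), fraction, rng)
            y_sub = y[sub]
            if len(np.unique(y_sub)) < 2:
                warnings.warn(
                    f"fraction {fraction} left a single-class training split "
                    f"in fold {fold}; fold skipped",
                    stacklevel=3,
                )
                continue
            est = clone(estimator)
            if "random_state" in est.get_params():
                est.set_params(random_state=fs)
            est.fit(X[sub], y_sub)
            scores = est.predict_proba(X[test_idx])[:, 1]
            summaries[fi].folds.append(compute_metrics(scores, y[test_idx]))
    return summaries


def cross_validate(estimator, X, y, k: int = 10, seed: int = 0) -> CVSummary:
    """Stratified k-fold CV of a cloneable estimator; mean +/- SE per metric."""
    return _run(estimator, X, y, [1.0], k, seed)[0]


def learning_curve(
    estimator, X, y, fractions, k: int = 10, seed: int = 0
) -> LearningCurve:
    """CV at each training fraction with test folds fixed across fractions.

    ``fractions`` must be sorted ascending and lie in (0, 1]; fraction 1.0
    reproduces :func:`cross_validate` exactly for the same seed.
    """
    fractions = list(fractions)
    if fractions != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    summaries = _run(estimator, X, y, fractions, k, seed)
    return LearningCurve(fractions=fractions, summaries=summaries)
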