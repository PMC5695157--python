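"""Target prediction and cross-validated evaluation.

The beamformer-output feature vector already carries one calibrated score
per target, so the simplest decoder picks the maximum.  Classifier backends
(1-nearest-neighbor, LDA, linear SVM) can instead be trained on the feature
vectors of the training trials to exploit interactions between scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .containers import TrialSet
from .paradigms import ParadigmSpec, fit_paradigm, trialset_features

__all__ = [
    "RULES",
    "BONFERRONI_ALPHA",
    "predict_max",
    "fit_classifier",
    "predict_classifier",
    "EvaluationResult",
    "cross_validate",
    "compare_rules",
]

RULES = ("max", "nn", "lda", "svm")

#: two-tailed Wilcoxon significance threshold after Bonferroni correction
#: for the six pairwise rule comparisons (0.05 / 6).
BONFERRONI_ALPHA = 0.05 / 6


def predict_max(fv: np.ndarray) -> int:
    """Index of the highest beamformer output; ties go to the lowest index."""
    fv = np.asarray(fv, dtype=float)
    if fv.size == 0:
        raise ValueError("empty feature vector")
    if np.isnan(fv).any():
        raise ValueError("NaN in feature vector")
    return int(np.argmax(fv))


def fit_classifier(rule: str, features: np.ndarray, labels: np.ndarray,
                   seed: int = 0, n_neighbors: int = 1, C: float = 1.0):
    """Train a classifier backend on beamformer-output feature vectors.

    ``nn`` is k-nearest-neighbor (Euclidean, default k = 1), ``lda`` a
    linear discriminant with its default pooled-covariance solver, ``svm``
    a linear-kernel SVC (one-vs-one multiclass, C = 1 by default).  All are
    deterministic given the seed.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes in training data")
    if rule == "nn":
        clf = KNeighborsClassifier(n_neighbors=n_neighbors)
    elif rule == "lda":
        clf = LinearDiscriminantAnalysis()
    elif rule == "svm":
        clf = SVC(kernel="linear", C=C, decision_function_shape="ovo",
                  random_state=seed)
    else:
        raise ValueError(f"unknown classifier rule {rule!r}")
    clf.fit(features, labels)
    return clf


def predict_classifier(clf, fv: np.ndarray) -> int:
    """Predict the target index for one feature vector."""
    return int(clf.predict(np.asarray(fv, dtype=float).reshape(1, -1))[0])


@dataclass
class EvaluationResult:
    """Cross-validation accuracies, one row per (rule, length, fold)."""

    table: pd.DataFrame
    fold_of_trial: np.ndarray
    seed: int
    paradigm: str = ""

    def accuracy(self, rule: str, length) -> float:
        """Pooled accuracy over folds for one rule and stimulation length."""
        sub = self.table[(self.table.rule == rule) & (self.table.length == length)]
        if sub.empty:
            raise KeyError(f"no results for rule={rule!r}, length={length!r}")
        return float(sub.n_correct.sum() / sub.n_test.sum())

    def accuracies(self, rule: str) -> pd.Series:
        """Pooled accuracy per length for one rule, indexed by length."""
        sub = self.table[self.table.rule == rule]
        g = sub.groupby("length", sort=True)
        return g.n_correct.sum() / g.n_test.sum()


def cross_validate(ts: TrialSet, spec: ParadigmSpec,
                   rules: tuple[str, ...] = ("max",),
                   lengths: tuple | None = None,
                   n_folds: int | None = None,
                   seed: int = 0, ridge: float = 0.0,
                   truncate_training: bool = False) -> EvaluationResult:
    """Stratified k-fold evaluation over increasing stimulation lengths.

    Per fold, patterns, covariances and beamformers are fitted on the
    full-length training trials only; test trials are truncated to each
    evaluated length before feature extraction (classifier backends are
    trained on training-trial features extracted at the same length).
    ``truncate_training=True`` additionally truncates the training trials
    before pattern/covariance estimation, at the cost of a much smaller
    pooled-covariance sample in the short-length regime.  Accuracy is
    pooled over folds.

    ``lengths`` defaults to all highlight repetitions (P300: 1..15), whole
    seconds (SSVEP: 1..5) or code repetitions (cVEP: 1..10).  ``n_folds``
    defaults to 4 for the serial-highlight paradigm and 5 otherwise.
    """
    if n_folds is None:
        n_folds = 4 if spec.kind == "p300" else 5
    if lengths is None:
        if spec.kind == "p300":
            lengths = tuple(range(1, spec.highlights_per_target + 1))
        elif spec.kind == "ssvep":
            lengths = tuple(float(s) for s in range(1, int(spec.trial_seconds) + 1))
        else:
            lengths = tuple(range(1, spec.repetitions + 1))
    for rule in rules:
        if rule not in RULES:
            raise ValueError(f"unknown rule {rule!r}")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of_trial = np.empty(ts.n_trials, dtype=int)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(
            skf.split(np.zeros(ts.n_trials), ts.cues)):
        fold_of_trial[test_idx] = fold
        train, test = ts.subset(train_idx), ts.subset(test_idx)
        if np.unique(train.cues).size < spec.n_targets:
            raise ValueError(f"fold {fold}: training part lacks a cued target")
        fitted_full = None if truncate_training else fit_paradigm(
            train, spec, ridge=ridge)
        for length in lengths:
            fitted = (fit_paradigm(train, spec, ridge=ridge, length=length)
                      if truncate_training else fitted_full)
            test_feats = trialset_features(test, fitted, length=length)
            train_feats = None
            if any(r != "max" for r in rules):
                train_feats = trialset_features(train, fitted, length=length)
            for rule in rules:
                if rule == "max":
                    pred = np.array([predict_max(f) for f in test_feats])
                else:
                    clf = fit_classifier(rule, train_feats, train.cues, seed=seed)
                    pred = clf.predict(test_feats).astype(int)
                n_correct = int((pred == test.cues).sum())
                rows.append(dict(rule=rule, length=length, fold=fold,
                                 n_test=len(test_idx), n_correct=n_correct,
                                 accuracy=n_correct / len(test_idx)))
    table = pd.DataFrame(rows)
    return EvaluationResult(table=table, fold_of_trial=fold_of_trial,
                            seed=seed, paradigm=spec.kind)


def compare_rules(acc_a: np.ndarray, acc_b: np.ndarray,
                  alpha: float = BONFERRONI_ALPHA) -> dict:
    """Two-tailed Wilcoxon signed-rank comparison of paired accuracies.

    Returns statistic, p-value and a significance flag at the
    Bonferroni-corrected threshold (0.05/6 = 0.0083 for six pairwise rule
    comparisons).  With all paired differences zero there are no signed
    ranks; the comparison is reported as "no difference" (p = 1, flag
    False).
    """
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if acc_a.shape != acc_b.shape:
        raise ValueError("paired accuracy vectors must have equal length")
    if np.allclose(acc_a, acc_b):
        return dict(statistic=np.nan, p_value=1.0, significant=False,
                    note="no difference: all paired differences are zero")
    stat, p = stats.wilcoxon(acc_a, acc_b, alternative="two-sided")
    return dict(statistic=float(stat), p_value=float(p),
                significant=bool(p < alpha), note="")
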