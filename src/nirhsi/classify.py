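"""Vote-fraction random-forest polymer classification.

A random forest is trained on the binary peak/trough feature vectors of a
labelled reference library. For a new particle the fraction of trees voting
for each class, P_rf, is a prediction-certainty score. Per class, sweeping a
cutoff over P_rf traces a one-vs-rest ROC curve; the operating cutoff is the
one maximising the true positive rate subject to an estimated false positive
rate not above a target (5% by default), with the estimate coming from
stratified k-fold cross-validation. Particles whose polymer scores all fall
below their cutoffs are reported as "other" (natural material or an
unlibraried polymer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CLASS_ORDER",
    "OTHER_LABEL",
    "NEVER_ASSIGN",
    "ForestModel",
    "ThresholdPolicy",
    "RocCurve",
    "DegenerateTrainingError",
    "UndefinedRateError",
    "train_forest",
    "score",
    "score_many",
    "assign_class",
    "cross_validate",
    "roc_curve",
    "select_threshold",
    "evaluate_library",
]

#: Fixed polymer precedence used for tie-breaks and reporting.
CLASS_ORDER = ("PE", "PP", "PS")
OTHER_LABEL = "other"
#: Sentinel cutoff meaning "never assign this class" (no score exceeds it).
NEVER_ASSIGN = 1.0 + 1e-9


class DegenerateTrainingError(ValueError):
    """Training data contains fewer than two classes."""


class UndefinedRateError(ValueError):
    """ROC rates are undefined (no positives or no negatives)."""


@dataclass
class ForestModel:
    """A fitted forest plus the metadata needed for deterministic scoring."""

    estimator: RandomForestClassifier
    classes: tuple[str, ...]
    n_features: int
    seed: int

    @property
    def n_trees(self) -> int:
        return self.estimator.n_estimators


def train_forest(
    X: np.ndarray,
    y: Sequence[str],
    n_trees: int = 100,
    seed: int = 0,
) -> ForestModel:
    """Bootstrap-aggregate ``n_trees`` Gini decision trees on binary features.

    Unlimited depth keeps leaves pure, so the forest's class probabilities
    are exactly tree-vote fractions. Deterministic given ``seed``.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    if np.unique(y).size < 2:
        raise DegenerateTrainingError("need at least two classes to train")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        bootstrap=True,
        max_depth=None,
        random_state=seed,
    )
    est.fit(X, y)
    return ForestModel(
        estimator=est,
        classes=tuple(est.classes_),
        n_features=X.shape[1],
        seed=seed,
    )


def score(model: ForestModel, vector: np.ndarray) -> dict[str, float]:
    """Vote fraction P_rf per class for one feature vector; sums to 1."""
    return score_many(model, np.asarray(vector).reshape(1, -1))[0]


def score_many(model: ForestModel, X: np.ndarray) -> list[dict[str, float]]:
    """P_rf per class for each row of ``X``."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature vectors must have {model.n_features} entries, got {X.shape}"
        )
    proba = model.estimator.predict_proba(X)
    return [dict(zip(model.classes, row.astype(float))) for row in proba]


@dataclass
class ThresholdPolicy:
    """Per-class P_rf cutoffs with the FPR target they were selected for."""

    cutoffs: Mapping[str, float]
    target_fpr: float = 0.05

    def __post_init__(self) -> None:
        for cls, c in self.cutoffs.items():
            if not (0.0 <= c <= NEVER_ASSIGN):
                raise ValueError(f"cutoff for {cls!r} outside [0, 1]: {c}")

    @classmethod
    def argmax(cls, classes: Sequence[str] = CLASS_ORDER) -> "ThresholdPolicy":
        """Cutoff-0 policy: the highest-scoring polymer always wins
        (the no-threshold, max-P_rf decision rule)."""
        return cls({c: 0.0 for c in classes}, target_fpr=1.0)


def assign_class(scores: Mapping[str, float], policy: ThresholdPolicy) -> str:
    """Highest-P_rf polymer class whose score exceeds its cutoff, else "other".

    Ties break by the fixed class order PE, PP, PS.
    """
    candidates = []
    for cls in CLASS_ORDER:
        if cls not in scores or cls not in policy.cutoffs:
            continue
        if scores[cls] > policy.cutoffs[cls]:
            candidates.append(cls)
    if not candidates:
        return OTHER_LABEL
    best = max(candidates, key=lambda c: (scores[c], -CLASS_ORDER.index(c)))
    return best


def cross_validate(
    X: np.ndarray,
    y: Sequence[str],
    k: int = 10,
    n_trees: int = 100,
    seed: int = 0,
):
    """Stratified k-fold out-of-fold P_rf scores for every sample.

    Returns a DataFrame with one row per sample: ``fold``, ``true_label``,
    and one P_rf column per class. If the smallest class has fewer than
    ``k`` members, k is reduced to that count with a warning.
    """
    import pandas as pd

    X = np.asarray(X)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DegenerateTrainingError("need at least two classes to cross-validate")
    k_eff = min(k, int(counts.min()))
    if k_eff < k:
        warnings.warn(
            f"smallest class has {counts.min()} samples; reducing folds {k} -> {k_eff}",
            RuntimeWarning,
            stacklevel=2,
        )
    if k_eff < 2:
        raise ValueError("smallest class too small for cross-validation")

    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    all_classes = tuple(classes)
    records = [None] * len(y)
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = train_forest(X[train_idx], y[train_idx], n_trees=n_trees, seed=seed + fold)
        for i, s in zip(test_idx, score_many(model, X[test_idx])):
            row = {"fold": fold, "true_label": y[i]}
            for cls in all_classes:
                row[cls] = s.get(cls, 0.0)
            records[i] = row
    return pd.DataFrame(records)


@dataclass
class RocCurve:
    """One-vs-rest ROC: (threshold, TPR, FPR) points plus trapezoidal AUC.

    Points are ordered by decreasing threshold, so TPR and FPR are
    non-decreasing along the curve; the endpoints (0,0) and (1,1) are always
    present. The final point uses cutoff 0 with "assign everything"
    (max-P_rf) semantics.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    positive: str = ""

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds.tolist(), self.tpr.tolist(), self.fpr.tolist()))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )


def roc_curve(scores: np.ndarray, labels: Sequence[str], positive: str) -> RocCurve:
    """Sweep "P_rf > t" over the observed score values (plus 0 and 1).

    ``scores`` are the positive-class P_rf values; ``labels`` the true
    classes. AUC is the trapezoid-rule area over (FPR, TPR).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRateError(
            f"class {positive!r}: need at least one positive and one negative"
        )

    interior = [t for t in np.unique(scores)[::-1] if t < 1.0]
    thresholds, tprs, fprs = [], [], []
    for t in [1.0, *interior]:
        pred = scores > t
        thresholds.append(t)
        tprs.append((pred & y).sum() / n_pos)
        fprs.append((pred & ~y).sum() / n_neg)
    # Cutoff 0 with assign-all semantics closes the curve at (1, 1).
    thresholds.append(0.0)
    tprs.append(1.0)
    fprs.append(1.0)

    tpr = np.asarray(tprs)
    fpr = np.asarray(fprs)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(np.asarray(thresholds), tpr, fpr, auc, positive=positive)


def select_threshold(roc: RocCurve, target_fpr: float = 0.05) -> float:
    """Cutoff maximising TPR subject to estimated FPR <= ``target_fpr``.

    Ties on TPR resolve to the lowest achievable FPR, then to the smallest
    cutoff. If no point qualifies, :data:`NEVER_ASSIGN` is returned.
    """
    ok = roc.fpr <= target_fpr
    if not ok.any():
        return NEVER_ASSIGN
    best_tpr = roc.tpr[ok].max()
    at_best = ok & (roc.tpr == best_tpr)
    best_fpr = roc.fpr[at_best].min()
    candidates = at_best & (roc.fpr == best_fpr)
    return float(roc.thresholds[candidates].min())


def evaluate_library(
    X: np.ndarray,
    y: Sequence[str],
    k: int = 10,
    n_trees: int = 100,
    seed: int = 0,
    target_fpr: float = 0.05,
):
    """Cross-validated per-class ROC, AUC, and FPR-constrained cutoffs.

    Returns ``(oof_frame, report)`` where ``report`` maps each class to a
    dict with ``auc``, ``threshold``, and the TPR/FPR estimated at that
    threshold — the layout of a detection-probability summary table.
    """
    oof = cross_validate(X, y, k=k, n_trees=n_trees, seed=seed)
    y = np.asarray(y)
    report: dict[str, dict] = {}
    for cls in np.unique(y):
        roc = roc_curve(oof[cls].to_numpy(), y, cls)
        cutoff = select_threshold(roc, target_fpr)
        if cutoff >= NEVER_ASSIGN:
            tpr_at = 0.0
            fpr_at = 0.0
        else:
            idx = int(np.argmin(np.abs(roc.thresholds - cutoff)))
            tpr_at = float(roc.tpr[idx])
            fpr_at = float(roc.fpr[idx])
        report[str(cls)] = {
            "auc": roc.auc,
            "threshold": cutoff,
            "tpr_at_threshold": tpr_at,
            "fpr_at_threshold": fpr_at,
            "roc": roc,
        }
    return oof, report
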