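"""Soft-voting ensemble of random forest, SVM and k-nearest neighbours.

Each member classifier exposes class probabilities; the ensemble
probability for a test sample is the weighted mean of the member
probabilities (so rows remain a distribution), and the predicted class
is the argmax, with ties broken to the lowest class index (and logged).
Evaluation uses stratified 5-fold cross-validation in which every
sample is tested exactly once; when augmented copies of source images
are present, all variants of one source are confined to the same fold
and only original images ever appear in a test set, so augmentation can
never leak across the train/test boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .metrics import ConfusionMatrix, MetricReport, confusion, evaluate_confusion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleConfig:
    """Member settings of the soft-voting ensemble (all configurable;
    probabilities for the SVM come from pairwise-coupling calibration)."""

    rf_trees: int = 200
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    knn_k: int = 5
    knn_weights: str = "distance"
    member_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.member_weights):
            raise ValueError("member weights must be positive")
        if len(self.member_weights) < 2:
            raise ValueError("need at least 2 members")


@dataclass
class FoldSplit:
    """k disjoint, exhaustive test folds of sample indices."""

    folds: list[np.ndarray]
    stratified: bool
    seed: int


def _validate_features(features: np.ndarray, labels: np.ndarray) -> None:
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")


def fit_members(
    features: np.ndarray, labels: np.ndarray, cfg: EnsembleConfig | None = None
) -> list:
    """Fit the RF, SVM and KNN members; all expose predict_proba and are
    deterministic under the config seed."""
    from sklearn.calibration import CalibratedClassifierCV

    cfg = cfg or EnsembleConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    _validate_features(features, labels)
    # Platt-style sigmoid calibration gives the SVM its class
    # probabilities (pairwise coupling happens inside the one-vs-one SVC)
    min_count = int(np.bincount(np.unique(labels, return_inverse=True)[1]).min())
    svm = CalibratedClassifierCV(
        SVC(kernel=cfg.svm_kernel, C=cfg.svm_c, random_state=cfg.seed),
        method="sigmoid", ensemble=False, cv=min(5, max(2, min_count)),
    )
    members = [
        RandomForestClassifier(n_estimators=cfg.rf_trees, random_state=cfg.seed),
        svm,
        KNeighborsClassifier(n_neighbors=cfg.knn_k, weights=cfg.knn_weights),
    ]
    for member in members:
        member.fit(features, labels)
    return members


def soft_vote(
    member_probabilities: list[np.ndarray],
    weights: tuple[float, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-mean fusion of member probability matrices.

    Returns the ensemble probability matrix (rows re-sum to 1) and the
    argmax class indices.  Exact ties go to the lowest class index and
    are logged.
    """
    mats = [np.asarray(m, dtype=float) for m in member_probabilities]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("member probability matrices must be congruent")
    if weights is None:
        weights = (1.0,) * len(mats)
    if len(weights) != len(mats):
        raise ValueError("one weight per member required")
    w = np.asarray(weights, dtype=float)
    fused = np.tensordot(w, np.stack(mats), axes=1) / w.sum()
    fused = fused / fused.sum(axis=1, keepdims=True)
    predictions = fused.argmax(axis=1)  # np.argmax returns the first maximum
    n_ties = int((np.sum(fused == fused.max(axis=1, keepdims=True), axis=1) > 1).sum())
    if n_ties:
        logger.info("soft_vote: %d tied sample(s); ties broken to lowest "
                    "class index", n_ties)
    return fused, predictions


def predict_proba(members: list, features: np.ndarray,
                  cfg: EnsembleConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble probabilities and predictions for a feature matrix."""
    cfg = cfg or EnsembleConfig()
    probs = [m.predict_proba(np.asarray(features, dtype=float)) for m in members]
    return soft_vote(probs, cfg.member_weights)


def make_folds(
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> FoldSplit:
    """Stratified k folds; with ``groups``, all members of a group stay
    in one fold.  Falls back to unstratified (with a warning) when some
    class has fewer than k samples."""
    from sklearn.model_selection import KFold, StratifiedGroupKFold, StratifiedKFold

    labels = np.asarray(labels)
    counts = np.bincount(np.unique(labels, return_inverse=True)[1])
    stratified = counts.min() >= k
    if not stratified:
        warnings.warn(
            f"make_folds: smallest class has {counts.min()} < k={k} samples; "
            "falling back to unstratified folds",
            stacklevel=2,
        )
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [test for _, test in splitter.split(labels[:, None], labels, groups)]
    elif stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [test for _, test in splitter.split(labels[:, None], labels)]
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [test for _, test in splitter.split(labels[:, None])]
    return FoldSplit(folds=folds, stratified=stratified, seed=seed)


@dataclass
class CVResult:
    """Per-fold confusion matrices and metric reports plus their mean."""

    fold_confusions: list[ConfusionMatrix]
    fold_reports: list[MetricReport]
    mean_metrics: dict = field(default_factory=dict)

    @property
    def mean_macro_accuracy(self) -> float:
        return self.mean_metrics["macro"]["accuracy"]


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    cfg: EnsembleConfig | None = None,
    seed: int | None = None,
    class_order: list[str] | tuple[str, ...] | None = None,
    groups: np.ndarray | None = None,
    is_original: np.ndarray | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the soft-voting ensemble.

    ``groups`` ties augmented variants to their source image so they
    share a fold; ``is_original`` marks the samples allowed in test
    sets (augmented copies still train, but are never tested).
    Every original sample is tested exactly once.
    """
    cfg = cfg or EnsembleConfig()
    seed = cfg.seed if seed is None else seed
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(labels) < k:
        raise ValueError(f"need at least k={k} samples")
    class_order = tuple(class_order) if class_order else tuple(
        sorted(np.unique(labels))
    )

    split = make_folds(labels, k=k, seed=seed, groups=groups)
    all_idx = np.arange(len(labels))
    fold_cms: list[ConfusionMatrix] = []
    fold_reports: list[MetricReport] = []
    for test_idx in split.folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        if is_original is not None:
            test_idx = test_idx[is_original[test_idx]]
        members = fit_members(features[train_idx], labels[train_idx], cfg)
        classes = members[0].classes_
        probs = [m.predict_proba(features[test_idx]) for m in members]
        # align member class orders (sklearn orders classes_ identically
        # for all members fitted on the same labels, but be explicit)
        _, predictions = soft_vote(probs, cfg.member_weights)
        predicted_labels = classes[predictions]
        cm = confusion(labels[test_idx], predicted_labels, class_order)
        fold_cms.append(cm)
        fold_reports.append(evaluate_confusion(cm))

    mean_metrics = _mean_reports(fold_reports)
    return CVResult(fold_confusions=fold_cms, fold_reports=fold_reports,
                    mean_metrics=mean_metrics)


def _mean_reports(reports: list[MetricReport]) -> dict:
    """Average per-class and macro metrics across folds."""
    keys = ("accuracy", "sensitivity", "specificity", "precision", "f1")
    out: dict = {"macro": {}, "per_class": {}, "fold_accuracy": float(
        np.mean([r.fold_accuracy for r in reports])
    )}
    for key in keys:
        out["macro"][key] = float(np.mean([r.macro[key] for r in reports]))
    for name in reports[0].per_class:
        out["per_class"][name] = {
            key: float(np.mean([r.per_class[name][key] for r in reports]))
            for key in keys
        }
    return out
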