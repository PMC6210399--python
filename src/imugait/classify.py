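"""Classifier-comparison experiments over gait feature matrices.

One experiment: ANOVA-F selection of the top 20% of features (fitted on the
training partition only), a random stratified 6:4 train/test split at trial
level, 5-fold cross-validation of each algorithm on the training partition,
then a single fit on the full training partition evaluated on the held-out
test partition.  Five algorithms are compared: random forest (1000 trees),
AdaBoost (at most 150 estimators), a decision tree, Gaussian naive Bayes and
a multilayer perceptron (one hidden layer of 2000 units, Adam solver,
adaptive learning-rate schedule).

Reported per algorithm: cross-validation mean/sd accuracy (%), test accuracy
(%), macro-averaged precision and recall, and the confusion matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.metrics import confusion_matrix, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "ModelResult",
    "ExperimentReport",
    "anova_f_scores",
    "select_top_fraction",
    "TopFractionSelector",
    "split_train_test",
    "build_estimator",
    "default_models",
    "run_experiment",
    "summarize_reports",
]

ALGORITHMS: tuple[str, ...] = (
    "random_forest",
    "adaboost",
    "decision_tree",
    "gaussian_nb",
    "mlp",
)

_DISPLAY_NAMES = {
    "random_forest": "Random Forest",
    "adaboost": "Adaboost",
    "decision_tree": "Decision Tree",
    "gaussian_nb": "Naive Bayes",
    "mlp": "Multilayer Perceptron",
}


@dataclass(frozen=True)
class ModelSpec:
    """One algorithm plus its pinned hyperparameters."""

    algorithm: str
    seed: int = 0
    params: dict = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )


def build_estimator(spec: ModelSpec) -> BaseEstimator:
    """Instantiate the sklearn estimator for one model spec."""
    p = dict(spec.params)
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.pop("n_estimators", 1000), random_state=spec.seed, **p
        )
    if spec.algorithm == "adaboost":
        return AdaBoostClassifier(
            n_estimators=p.pop("n_estimators", 150), random_state=spec.seed, **p
        )
    if spec.algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **p)
    if spec.algorithm == "gaussian_nb":
        return GaussianNB(**p)
    if spec.algorithm == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=p.pop("hidden_layer_sizes", (2000,)),
            solver=p.pop("solver", "adam"),
            learning_rate=p.pop("learning_rate", "adaptive"),
            max_iter=p.pop("max_iter", 300),
            random_state=spec.seed,
            **p,
        )
    raise AssertionError(spec.algorithm)


def default_models(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(a, seed=seed) for a in ALGORITHMS]


def anova_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F score of each feature against the class labels.

    A feature with zero within-group variance but distinct group means gets
    an infinite score (ranked first); a feature constant everywhere scores 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scores, _ = f_classif(X, y)
    scores = np.asarray(scores, dtype=float)
    # zero within-group variance: infinite separation unless also constant
    # between groups, in which case the feature carries no signal at all
    within = np.zeros(X.shape[1])
    between = np.zeros(X.shape[1])
    grand = X.mean(axis=0)
    for c, n_c in zip(classes, counts):
        Xc = X[y == c]
        within += Xc.var(axis=0) * n_c
        between += n_c * (Xc.mean(axis=0) - grand) ** 2
    bad = ~np.isfinite(scores)
    scores[bad & (within == 0) & (between > 0)] = np.inf
    scores[bad & ~((within == 0) & (between > 0))] = 0.0
    return scores


def select_top_fraction(scores: np.ndarray, fraction: float = 0.20) -> np.ndarray:
    """Boolean mask keeping the ``max(1, floor(fraction*d))`` best-scoring
    features; score ties are broken by ascending feature index."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = max(1, int(np.floor(fraction * scores.size)))
    order = np.lexsort((np.arange(scores.size), -scores))
    mask = np.zeros(scores.size, dtype=bool)
    mask[order[:k]] = True
    return mask


class TopFractionSelector(SelectorMixin, BaseEstimator):
    """ANOVA-F feature selector keeping the top ``fraction`` of features."""

    def __init__(self, fraction: float = 0.20):
        self.fraction = fraction

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.scores_ = anova_f_scores(X, y)
        self.support_mask_ = select_top_fraction(self.scores_, self.fraction)
        return self

    def _get_support_mask(self):
        return self.support_mask_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


def split_train_test(
    X: np.ndarray,
    y: np.ndarray,
    test_size: float = 0.4,
    seed: int = 0,
    groups: np.ndarray | None = None,
):
    """Random stratified 6:4 split at trial level (reproducible from seed).

    When ``groups`` (subject ids) is given, whole subjects are assigned to
    one partition to rule out subject leakage; stratification is then
    approximate.
    """
    idx = np.arange(len(y))
    if groups is None:
        tr, te = train_test_split(
            idx, test_size=test_size, stratify=y, random_state=seed, shuffle=True
        )
        return np.sort(tr), np.sort(te)
    from sklearn.model_selection import GroupShuffleSplit

    gss = GroupShuffleSplit(n_splits=1, test_size=test_size, random_state=seed)
    tr, te = next(gss.split(idx, y, groups=groups))
    return np.sort(tr), np.sort(te)


@dataclass
class ModelResult:
    algorithm: str
    cv_mean_pct: float
    cv_sd_pct: float
    test_accuracy_pct: float
    avg_precision: float
    avg_recall: float
    confusion: list[list[int]]

    def to_dict(self) -> dict:
        return {
            "model": _DISPLAY_NAMES[self.algorithm],
            "cv_mean_accuracy_pct": self.cv_mean_pct,
            "cv_sd_pct": self.cv_sd_pct,
            "test_accuracy_pct": self.test_accuracy_pct,
            "avg_precision": self.avg_precision,
            "avg_recall": self.avg_recall,
            "confusion_matrix": self.confusion,
        }


@dataclass
class ExperimentReport:
    """Results of one experiment configuration across all algorithms."""

    mode: str
    classes: list[str]
    n_train: int
    n_test: int
    selected_features: list[str]
    results: dict[str, ModelResult]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view mirroring the per-configuration report schema."""
        rows = []
        for r in self.results.values():
            d = r.to_dict()
            d.pop("confusion_matrix")
            rows.append(d)
        return pd.DataFrame(rows).set_index("model")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "classes": self.classes,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "selected_features": self.selected_features,
            "results": {a: r.to_dict() for a, r in self.results.items()},
        }

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path


def run_experiment(
    features: FeatureMatrix,
    models: list[ModelSpec] | None = None,
    classes: list[str] | None = None,
    select_fraction: float = 0.20,
    test_size: float = 0.4,
    n_folds: int = 5,
    seed: int = 0,
    subject_grouped: bool = False,
) -> ExperimentReport:
    """Run one experiment configuration end to end.

    ``classes`` restricts the label task (default: the binary stroke vs
    other-neurological problem when both are present, else all labels).
    Feature selection is fitted on the training partition only and applied
    unchanged to the test partition.
    """
    if classes is None:
        present = sorted(set(features.labels))
        if {"stroke", "other_neuro"} <= set(present):
            classes = ["stroke", "other_neuro"]
        else:
            classes = present
    fm = features.subset(classes)
    X, y = fm.X, fm.y
    labels_sorted = sorted(classes)
    if len(set(y)) < 2:
        raise ValueError("need at least 2 classes with samples")
    groups = (
        fm.frame.index.get_level_values("subject_id").to_numpy()
        if subject_grouped
        else None
    )
    tr, te = split_train_test(X, y, test_size=test_size, seed=seed, groups=groups)
    _, tr_counts = np.unique(y[tr], return_counts=True)
    if tr_counts.min() < n_folds:
        raise ValueError(
            f"cohort too small for stratified {n_folds}-fold CV: "
            f"smallest training class has {tr_counts.min()} samples"
        )
    models = models if models is not None else default_models(seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    results: dict[str, ModelResult] = {}
    selected: list[str] | None = None
    for spec in models:
        pipe = Pipeline(
            [
                ("select", TopFractionSelector(select_fraction)),
                ("clf", build_estimator(spec)),
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            fold_scores = cross_val_score(pipe, X[tr], y[tr], cv=cv, scoring="accuracy")
            pipe.fit(X[tr], y[tr])
        y_pred = pipe.predict(X[te])
        if selected is None:
            mask = pipe.named_steps["select"].get_support()
            selected = [n for n, keep in zip(fm.feature_names, mask) if keep]
        cm = confusion_matrix(y[te], y_pred, labels=labels_sorted)
        results[spec.algorithm] = ModelResult(
            algorithm=spec.algorithm,
            cv_mean_pct=float(100 * fold_scores.mean()),
            cv_sd_pct=float(100 * fold_scores.std()),
            test_accuracy_pct=float(100 * np.mean(y_pred == y[te])),
            avg_precision=float(
                precision_score(y[te], y_pred, average="macro", zero_division=0)
            ),
            avg_recall=float(
                recall_score(y[te], y_pred, average="macro", zero_division=0)
            ),
            confusion=cm.tolist(),
        )
    return ExperimentReport(
        mode=fm.mode,
        classes=labels_sorted,
        n_train=len(tr),
        n_test=len(te),
        selected_features=selected or [],
        results=results,
    )


def summarize_reports(reports: list[ExperimentReport]) -> pd.DataFrame:
    """Best algorithm per configuration, by test accuracy (ties: first)."""
    rows = []
    for rep in reports:
        best = max(rep.results.values(), key=lambda r: r.test_accuracy_pct)
        rows.append(
            {
                "configuration": rep.mode,
                "best_model": _DISPLAY_NAMES[best.algorithm],
                "test_accuracy_pct": best.test_accuracy_pct,
                "avg_precision": best.avg_precision,
                "avg_recall": best.avg_recall,
            }
        )
    return pd.DataFrame(rows).set_index("configuration")
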