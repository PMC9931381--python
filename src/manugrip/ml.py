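"""Machine-learning classification of single-record grip sincerity.

Unlike the threshold method, the ML route scores one hand's record at a
time (no bimanual comparison): each trial becomes a feature vector of
demographics, total grip force, per-area percent loads, the variance of
the seven area loads and the log of the total contact load.  Records are
split 80/20 with class stratification (optionally grouped by subject so no
subject spans both partitions), four classifier families are tuned by
five-fold cross-validated grid search on AUC, and the held-out partition
is scored with the metrics module.

The feature list deliberately excludes the thumb's percent load by
default; it can be enabled via :class:`FeatureConfig` (see the methods
note on the ambiguity of the published feature count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import (
    GridSearchCV,
    GroupShuffleSplit,
    StratifiedKFold,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import metrics as _metrics
from .loadmap import AREAS, HandArea, TrialRecord

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "SplitSpec",
    "TrainSpec",
    "FittedModel",
    "build_features",
    "features_frame",
    "split_data",
    "train_model",
    "evaluate_model",
    "ALGORITHMS",
    "POSITIVE_LABEL",
]

#: The positive class everywhere: a submaximal (insincere) record.
POSITIVE_LABEL = "submaximal"

#: Categorical encodings written into every report header.
SEX_CODES = {"female": 0, "male": 1}
HANDEDNESS_CODES = {"right": 0, "left": 1}

ALGORITHMS = ("random_forest", "linear_svm", "gradient_boosting", "extreme_gradient_boosting")

#: Short display labels used in the comparison table.
ALGORITHM_LABELS = {
    "random_forest": "Random Forest",
    "linear_svm": "svmlinear",
    "gradient_boosting": "gbm",
    "extreme_gradient_boosting": "XGBoost",
}


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-construction options.

    ``include_thumb`` adds the thumb's percent load to the vector (off by
    default); ``log_base`` is the base of the total-load logarithm
    (natural log by default).
    """

    include_thumb: bool = False
    log_base: float = math.e


@dataclass(frozen=True)
class FeatureVector:
    """One record's features; ``names``/``values`` give the model input order."""

    age: float
    sex: int
    handedness: int
    total_force: float
    pct: Mapping[HandArea, float]
    load_variance: float
    log_load_sum: float
    include_thumb: bool = False

    @property
    def names(self) -> tuple[str, ...]:
        base = ["age", "sex", "handedness", "total_force"]
        areas = [HandArea.II, HandArea.III, HandArea.IV, HandArea.V, HandArea.HY, HandArea.TH]
        if self.include_thumb:
            areas = [HandArea.I] + areas
        base += [f"pct_{a.value}" for a in areas]
        base += ["load_variance", "log_load_sum"]
        return tuple(base)

    @property
    def values(self) -> np.ndarray:
        areas = [HandArea.II, HandArea.III, HandArea.IV, HandArea.V, HandArea.HY, HandArea.TH]
        if self.include_thumb:
            areas = [HandArea.I] + areas
        vals = [self.age, float(self.sex), float(self.handedness), self.total_force]
        vals += [self.pct[a] for a in areas]
        vals += [self.load_variance, self.log_load_sum]
        return np.array(vals, dtype=float)


def build_features(record: TrialRecord, config: FeatureConfig | None = None) -> FeatureVector:
    """Construct the feature vector of one trial record.

    ``load_variance`` is the sample variance (ddof=1) of the seven percent
    loads; ``log_load_sum`` is the logarithm of the total contact load
    (the sum of all area forces, i.e. the total grip force).  The effort
    label is never consulted.
    """
    if config is None:
        config = FeatureConfig()
    if not (record.loads.total_force > 0):
        raise ValueError("build_features requires a positive total force")
    pcts = record.loads.as_array()
    return FeatureVector(
        age=record.age,
        sex=SEX_CODES[record.sex],
        handedness=HANDEDNESS_CODES[record.handedness],
        total_force=record.loads.total_force,
        pct=dict(record.loads.percent),
        load_variance=float(np.var(pcts, ddof=1)),
        log_load_sum=float(math.log(record.loads.total_force, config.log_base)),
        include_thumb=config.include_thumb,
    )


def features_frame(
    records: Sequence[TrialRecord], config: FeatureConfig | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix and binary label vector (1 = submaximal) for ``records``."""
    fvs = [build_features(r, config) for r in records]
    X = pd.DataFrame([fv.values for fv in fvs], columns=list(fvs[0].names))
    y = np.array([1 if r.effort == POSITIVE_LABEL else 0 for r in records], dtype=int)
    return X, y


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation partitioning options."""

    train_fraction: float = 0.8
    stratify_by_label: bool = True
    group_by_subject: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


def split_data(
    records: Sequence[TrialRecord], spec: SplitSpec
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Partition records into train and validation sets.

    With the default record-level stratified split the class proportions
    in both parts match the stratified ideal to within one record; with
    ``group_by_subject`` the split is by whole subjects instead (no
    subject appears in both parts), which forgoes exact stratification.
    Deterministic given ``spec.seed``.
    """
    records = list(records)
    y = np.array([1 if r.effort == POSITIVE_LABEL else 0 for r in records])
    if len(np.unique(y)) < 2:
        raise ValueError("split_data requires records of both classes")
    idx = np.arange(len(records))
    if spec.group_by_subject:
        groups = np.array([r.subject_id for r in records])
        gss = GroupShuffleSplit(n_splits=1, train_size=spec.train_fraction, random_state=spec.seed)
        train_idx, val_idx = next(gss.split(idx, y, groups))
    else:
        stratify = y if spec.stratify_by_label else None
        train_idx, val_idx = train_test_split(
            idx,
            train_size=spec.train_fraction,
            stratify=stratify,
            random_state=spec.seed,
            shuffle=True,
        )
    train = [records[i] for i in sorted(train_idx)]
    val = [records[i] for i in sorted(val_idx)]
    return train, val


#: Small, seed-stable default hyperparameter grids per algorithm.
DEFAULT_GRIDS: dict[str, dict] = {
    "random_forest": {"n_estimators": [200], "max_depth": [None, 6], "min_samples_leaf": [1, 4]},
    "linear_svm": {"svc__C": [0.1, 1.0, 10.0]},
    "gradient_boosting": {"n_estimators": [150], "learning_rate": [0.1], "max_depth": [2, 3]},
    "extreme_gradient_boosting": {"n_estimators": [200], "max_depth": [2, 4], "learning_rate": [0.1, 0.3]},
}


@dataclass(frozen=True)
class TrainSpec:
    """Algorithm choice, cross-validation folds, and hyperparameter grid."""

    algorithm: str = "extreme_gradient_boosting"
    cv_folds: int = 5
    grid: Mapping[str, Sequence] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.grid is not None and not self.grid:
            raise ValueError("grid must be non-empty")


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "linear_svm":
        # linear SVM needs standardised features; decision_function is the score
        return Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="linear", random_state=seed))])
    if algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if algorithm == "extreme_gradient_boosting":
        return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss", tree_method="exact")
    raise ValueError(algorithm)


@dataclass
class FittedModel:
    """A tuned classifier plus everything needed to score new records.

    ``scores`` returns a continuous score (larger = more likely
    submaximal): a class-1 probability where the algorithm provides one,
    otherwise the signed decision value (linear SVM).  ``predict`` applies
    the algorithm's native hard-label rule (probability 0.5 / decision
    value 0).
    """

    algorithm: str
    estimator: object
    best_params: dict
    cv_auc: float
    feature_config: FeatureConfig
    label: str = ""

    def scores(self, records: Sequence[TrialRecord]) -> np.ndarray:
        X, _ = features_frame(records, self.feature_config)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return np.asarray(est.predict_proba(X)[:, 1], dtype=float)
        return np.asarray(est.decision_function(X), dtype=float)

    def predict(self, records: Sequence[TrialRecord]) -> np.ndarray:
        X, _ = features_frame(records, self.feature_config)
        return np.asarray(self.estimator.predict(X), dtype=int)


def train_model(
    train: Sequence[TrialRecord],
    spec: TrainSpec,
    feature_config: FeatureConfig | None = None,
) -> FittedModel:
    """Grid-search a classifier by cross-validated AUC and refit on all training data.

    The best hyperparameters maximise the mean AUC over ``cv_folds``
    stratified folds; the winning configuration is refit on the full
    training set.  Deterministic given ``spec.seed``.
    """
    if feature_config is None:
        feature_config = FeatureConfig()
    X, y = features_frame(train, feature_config)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if X.nunique().sum() == len(X.columns):
        raise ValueError("degenerate training data: all features constant")
    grid = dict(spec.grid) if spec.grid is not None else DEFAULT_GRIDS[spec.algorithm]
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        _make_estimator(spec.algorithm, spec.seed),
        param_grid=grid,
        scoring="roc_auc",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    return FittedModel(
        algorithm=spec.algorithm,
        estimator=search.best_estimator_,
        best_params=dict(search.best_params_),
        cv_auc=float(search.best_score_),
        feature_config=feature_config,
        label=ALGORITHM_LABELS[spec.algorithm],
    )


def evaluate_model(model: FittedModel, validation: Sequence[TrialRecord]) -> _metrics.MetricsReport:
    """Score the validation records and assemble the diagnostic report."""
    if not validation:
        raise ValueError("validation set is empty")
    y = np.array([1 if r.effort == POSITIVE_LABEL else 0 for r in validation])
    if len(np.unique(y)) < 2:
        raise ValueError("validation set must contain both classes (AUC undefined otherwise)")
    scores = model.scores(validation)
    predicted = model.predict(validation)
    cm = _metrics.confusion(y, predicted, positive_label=1)
    return _metrics.report_from(cm, scores, y, method_label=model.label or model.algorithm)
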