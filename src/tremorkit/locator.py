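"""Relative sensor-location identification on the upper-limb chain.

Three classifiers assign each sensor its ordinal position on the chain
(1 = hand, counting proximally):

* **ranking** — training-free: sort sensors by one feature's value in
  descending order; because motion and kinetic tremor are amplified distally,
  the sorted order *is* the chain order.  The sensor chain can be shortened,
  extended or slid without retraining.
* **random forest** — bagged decision trees (100 trees, minimum leaf size 4)
  on the per-sensor rank features, scored by out-of-bag error.
* **decision tree** — a single CART tree, pruned along the cost-complexity
  path with 10-fold cross-validation and the one-standard-deviation window
  (smallest tree whose CV error is within 1 SD of the minimum); both
  resubstitution and cross-validation errors are reported.

Classifier instances are (trial x sensor) rows with that sensor's 18
within-trial rank values as predictors and the chain ordinal as label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateModelError, ValidationError
from .features import (
    FEATURE_IDS,
    FeatureVector,
    compute_features,
    rank_transform,
)
from .io_formats import SensorConfiguration, TrialRecording

__all__ = [
    "LocationMethod",
    "LocationPrediction",
    "rank_classify",
    "evaluate_feature_accuracies",
    "build_rank_feature_table",
    "train_random_forest",
    "train_decision_tree",
    "classify",
]


class LocationMethod(str, Enum):
    RANKING = "ranking"
    RANDOM_FOREST = "random_forest"
    DECISION_TREE = "decision_tree"


@dataclass
class LocationPrediction:
    """Predicted chain order for one trial's sensors.

    ``predicted_order`` runs distal to proximal (index 0 = predicted hand).
    ``accuracy`` is the fraction of sensors placed at their true ordinal and
    is only populated when the trial carries ground truth.
    """

    predicted_order: list[str]
    method: LocationMethod
    feature_used: int | str
    per_sensor_correct: dict[str, bool] | None = None
    accuracy: float | None = None
    tie: bool = False
    conflicts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.per_sensor_correct is not None:
            expected = float(np.mean(list(self.per_sensor_correct.values())))
            if self.accuracy is None:
                self.accuracy = expected
            elif abs(self.accuracy - expected) > 1e-12:
                raise ValidationError("accuracy inconsistent with per_sensor_correct")


def _score_against_truth(
    predicted_order: Sequence[str], reference_order: Sequence[str]
) -> dict[str, bool]:
    truth = {sid: i for i, sid in enumerate(reference_order)}
    return {sid: truth[sid] == i for i, sid in enumerate(predicted_order)}


def rank_classify(
    trial: TrialRecording,
    feature_id: int,
    features: dict[str, FeatureVector] | None = None,
) -> LocationPrediction:
    """Training-free location identification by sorting one feature.

    Sensors are sorted by descending feature value; position ``i`` of the
    sorted list is predicted chain ordinal ``i + 1`` (1 = hand).  The
    operation is stateless — no model, no fitted parameters.
    """
    if feature_id not in FEATURE_IDS:
        raise ValidationError(f"unknown feature id {feature_id}; expected 1..18")
    if features is None:
        features = compute_features(trial)
    ranks = rank_transform(features)
    predicted = ranks.order(feature_id)
    correct = _score_against_truth(predicted, trial.reference_order)
    return LocationPrediction(
        predicted_order=predicted,
        method=LocationMethod.RANKING,
        feature_used=feature_id,
        per_sensor_correct=correct,
        tie=feature_id in ranks.tied_features,
    )


def evaluate_feature_accuracies(
    trials: Iterable[TrialRecording],
    configuration: SensorConfiguration | None = None,
) -> dict[int, float]:
    """Pooled per-feature ranking accuracy over a labelled trial collection.

    For every feature, the fraction of sensor placements correct across all
    trials (each sensor of each trial counts once).
    """
    trials = list(trials)
    if not trials:
        raise ValidationError("no trials supplied")
    if configuration is not None:
        configuration = SensorConfiguration(configuration)
        mismatched = [t.trial_id for t in trials if t.configuration is not configuration]
        if mismatched:
            raise ValidationError(
                f"trials {mismatched} do not match configuration {configuration.value}"
            )
    correct = dict.fromkeys(FEATURE_IDS, 0)
    total = 0
    for trial in trials:
        features = compute_features(trial)
        total += len(trial.sensors)
        for fid in FEATURE_IDS:
            pred = rank_classify(trial, fid, features=features)
            correct[fid] += sum(pred.per_sensor_correct.values())
    return {fid: correct[fid] / total for fid in FEATURE_IDS}


# ---------------------------------------------------------------------------
# trained classifiers
# ---------------------------------------------------------------------------

_RANK_COLUMNS = [f"rank_f{fid}" for fid in FEATURE_IDS]


def build_rank_feature_table(
    trials: Iterable[TrialRecording],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack (trial x sensor) rank-feature rows with chain-ordinal labels."""
    rows: list[dict[str, float]] = []
    labels: list[int] = []
    index: list[str] = []
    for trial in trials:
        features = compute_features(trial)
        ranks = rank_transform(features)
        ordinal = {sid: i + 1 for i, sid in enumerate(trial.reference_order)}
        for sid in trial.sensor_ids:
            rows.append(
                {f"rank_f{fid}": ranks.rank_of(fid, sid) for fid in FEATURE_IDS}
            )
            labels.append(ordinal[sid])
            index.append(f"{trial.trial_id}/{sid}")
    if not rows:
        raise ValidationError("no trials supplied")
    return pd.DataFrame(rows, index=index, columns=_RANK_COLUMNS), np.asarray(labels)


def _check_training_table(X: pd.DataFrame, y: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValidationError("feature table and labels must have equal length")
    if len(X) < 8:
        raise ValidationError("need at least 8 training instances")
    if np.unique(y).size < 2:
        raise DegenerateModelError("training labels contain a single class")
    return X, y


def train_random_forest(
    X: pd.DataFrame,
    y: np.ndarray,
    n_trees: int = 100,
    min_leaf: int = 4,
    seed: int = 0,
) -> tuple[RandomForestClassifier, float]:
    """Bagged tree ensemble on rank features; returns (model, out-of-bag error).

    Each tree sees a bootstrap resample and sqrt(n_features) candidate
    predictors per split; the out-of-bag error scores every instance with the
    trees whose bootstrap omitted it.
    """
    X, y = _check_training_table(X, y)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        min_samples_leaf=min_leaf,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
    )
    model.fit(X, y)
    return model, float(1.0 - model.oob_score_)


def train_decision_tree(
    X: pd.DataFrame,
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[DecisionTreeClassifier, float, float]:
    """CART tree pruned by cost-complexity with the 1-SD window.

    The pruning strength is chosen as the largest complexity penalty (smallest
    subtree) whose stratified ``n_folds``-fold cross-validation error does not
    exceed the minimum CV error plus one standard deviation of that estimate.
    Returns (model, resubstitution_error, cv_error_at_selection).
    """
    X, y = _check_training_table(X, y)
    if n_folds > len(X):
        raise ValidationError(f"n_folds ({n_folds}) exceeds the instance count ({len(X)})")
    path = DecisionTreeClassifier(random_state=seed).cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_errors = np.empty((alphas.size, n_folds))
    for f, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        for a, alpha in enumerate(alphas):
            tree = DecisionTreeClassifier(ccp_alpha=alpha, random_state=seed)
            tree.fit(X.iloc[train_idx], y[train_idx])
            fold_errors[a, f] = 1.0 - tree.score(X.iloc[test_idx], y[test_idx])
    cv_mean = fold_errors.mean(axis=1)
    cv_se = fold_errors.std(axis=1, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))
    window = cv_mean[i_min] + cv_se[i_min]
    admissible = np.flatnonzero(cv_mean <= window)
    i_sel = int(admissible.max())  # largest alpha within the window: simplest tree
    model = DecisionTreeClassifier(ccp_alpha=alphas[i_sel], random_state=seed)
    model.fit(X, y)
    resub_error = float(1.0 - model.score(X, y))
    return model, resub_error, float(cv_mean[i_sel])


def classify(
    model: RandomForestClassifier | DecisionTreeClassifier,
    rank_features: pd.DataFrame,
    reference_order: Sequence[str] | None = None,
) -> LocationPrediction:
    """Assign chain ordinals to one trial's sensors with a trained model.

    Rows of ``rank_features`` are sensors (index = sensor id, columns =
    ``rank_f1..rank_f18``).  If two sensors vote for the same ordinal, the
    higher-confidence sensor keeps it and the other takes its best remaining
    label; such conflicts are flagged.
    """
    if list(rank_features.columns) != _RANK_COLUMNS:
        raise ValidationError(
            "rank_features must have columns rank_f1..rank_f18 in order"
        )
    sensor_ids = list(rank_features.index)
    proba = model.predict_proba(rank_features)
    classes = list(model.classes_)
    assigned: dict[str, int] = {}
    conflicts: list[str] = []
    taken: set[int] = set()
    # greedy: most confident sensor first, next-best label on collision
    confidence = proba.max(axis=1)
    for row in np.argsort(-confidence, kind="stable"):
        sid = sensor_ids[row]
        prefs = np.argsort(-proba[row], kind="stable")
        choice = None
        for j, p in enumerate(prefs):
            if classes[p] not in taken:
                choice = classes[p]
                if j > 0:
                    conflicts.append(sid)
                break
        if choice is None:  # more sensors than classes: fall back to raw argmax
            choice = classes[prefs[0]]
            conflicts.append(sid)
        assigned[sid] = int(choice)
        taken.add(int(choice))
    predicted_order = [sid for sid, _ in sorted(assigned.items(), key=lambda kv: kv[1])]
    method = (
        LocationMethod.RANDOM_FOREST
        if isinstance(model, RandomForestClassifier)
        else LocationMethod.DECISION_TREE
    )
    correct = (
        _score_against_truth(predicted_order, reference_order)
        if reference_order is not None
        else None
    )
    return LocationPrediction(
        predicted_order=predicted_order,
        method=method,
        feature_used="model",
        per_sensor_correct=correct,
        conflicts=conflicts,
    )
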