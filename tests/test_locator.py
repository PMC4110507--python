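"""Ranking, random-forest and decision-tree location identification."""

import numpy as np
import pandas as pd
import pytest

from tremorkit.errors import DegenerateModelError, ValidationError
from tremorkit.features import FEATURE_IDS, FeatureVector
from tremorkit.io_formats import TrialRecording
from tremorkit.locator import (
    build_rank_feature_table,
    classify,
    evaluate_feature_accuracies,
    rank_classify,
    train_decision_tree,
    train_random_forest,
)


def _fv(value):
    return FeatureVector(values={fid: float(value) for fid in FEATURE_IDS})


class TestRankClassify:
    def test_consistent_ordering_is_perfect(self, clean_sim):
        trial = clean_sim.recording
        feats = dict(zip(trial.reference_order, [_fv(5.0), _fv(3.0), _fv(1.0)]))
        pred = rank_classify(trial, 1, features=feats)
        assert pred.accuracy == 1.0
        assert pred.predicted_order == trial.reference_order

    def test_reversed_ordering_places_only_middle_sensor(self, clean_sim):
        trial = clean_sim.recording
        feats = dict(zip(trial.reference_order, [_fv(1.0), _fv(3.0), _fv(5.0)]))
        pred = rank_classify(trial, 1, features=feats)
        assert pred.accuracy == pytest.approx(1 / 3)
        mid = trial.reference_order[1]
        assert pred.per_sensor_correct[mid]
        assert not any(
            pred.per_sensor_correct[s] for s in trial.reference_order if s != mid
        )

    def test_ties_flagged_and_broken_by_input_order(self, clean_sim):
        trial = clean_sim.recording
        feats = dict(zip(trial.reference_order, [_fv(2.0), _fv(2.0), _fv(1.0)]))
        pred = rank_classify(trial, 1, features=feats)
        assert pred.tie
        assert pred.predicted_order[:2] == trial.reference_order[:2]

    def test_unknown_feature_rejected(self, clean_sim):
        with pytest.raises(ValidationError):
            rank_classify(clean_sim.recording, 99)

    def test_invariant_to_sensor_file_order(self, clean_sim):
        """The prediction does not depend on block order in the file."""
        trial = clean_sim.recording
        shuffled = TrialRecording(
            trial_id=trial.trial_id,
            configuration=trial.configuration,
            sensors={sid: trial.sensors[sid] for sid in reversed(trial.sensor_ids)},
            reference_order=trial.reference_order,
            sample_rate=trial.sample_rate,
            true_locations=trial.true_locations,
        )
        assert (
            rank_classify(shuffled, 1).predicted_order
            == rank_classify(trial, 1).predicted_order
        )


class TestFeatureAccuracies:
    def test_highlighted_features_reach_perfect_accuracy(self, suite3):
        acc = evaluate_feature_accuracies([s.recording for s in suite3])
        from tremorkit.features import HIGHLIGHTED_FEATURES

        for fid in sorted(HIGHLIGHTED_FEATURES):
            assert acc[fid] == 1.0, f"feature {fid}: {acc[fid]}"

    def test_path_length_and_rms_features_are_redundant(self, suite3):
        """Features 1 and 2 are both magnitude-monotone on the same signals."""
        acc = evaluate_feature_accuracies([s.recording for s in suite3])
        assert acc[1] == acc[2]

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_feature_accuracies([])

    def test_mixed_configuration_rejected_when_pinned(self, suite3):
        from tremorkit.io_formats import SensorConfiguration

        with pytest.raises(ValidationError):
            evaluate_feature_accuracies(
                [s.recording for s in suite3], SensorConfiguration.FOUR_MIMU
            )


@pytest.fixture(scope="module")
def separable_table(suite3):
    """(trial x sensor) rank rows: 36 instances, deterministic per class."""
    return build_rank_feature_table([s.recording for s in suite3])


class TestRandomForest:
    def test_separable_table_low_oob_error(self, separable_table):
        X, y = separable_table
        assert len(X) >= 36
        _, oob = train_random_forest(X, y, seed=0)
        assert oob <= 0.05

    def test_permuted_labels_give_chance_accuracy(self, separable_table):
        X, y = separable_table
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            _, oob = train_random_forest(X, rng.permutation(y), seed=seed)
            accs.append(1.0 - oob)
        assert abs(np.mean(accs) - 1.0 / len(np.unique(y))) < 0.15

    def test_duplicating_instances_is_stable(self, separable_table):
        X, y = separable_table
        _, oob = train_random_forest(X, y, seed=0)
        X2 = pd.concat([X, X], ignore_index=True)
        _, oob2 = train_random_forest(X2, np.concatenate([y, y]), seed=0)
        assert abs(oob2 - oob) <= 0.05

    def test_single_class_rejected(self, separable_table):
        X, y = separable_table
        with pytest.raises(DegenerateModelError):
            train_random_forest(X, np.ones_like(y))


class TestDecisionTree:
    def test_separable_table_zero_resubstitution_error(self, separable_table):
        X, y = separable_table
        _, resub, _ = train_decision_tree(X, y, seed=0)
        assert resub == 0.0

    def test_resubstitution_never_exceeds_cv_error(self):
        """Training optimism: resubstitution error <= cross-validation error
        on noisy but structured rank tables."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([1, 2, 3], 15)
            # class-dependent rank pattern with 15% corrupted rows
            X = np.tile(np.arange(1, 19), (45, 1))
            for i, label in enumerate(y):
                X[i] = np.roll(X[i], label)
            corrupt = rng.random(45) < 0.15
            X[corrupt] = rng.integers(1, 4, size=(corrupt.sum(), 18))
            Xdf = pd.DataFrame(X, columns=[f"rank_f{fid}" for fid in FEATURE_IDS])
            _, resub, cv = train_decision_tree(Xdf, y, n_folds=5, seed=seed)
            assert resub <= cv + 1e-12, f"seed {seed}"

    def test_constant_features_prune_to_single_leaf(self):
        X = pd.DataFrame(
            np.ones((12, 18), dtype=int), columns=[f"rank_f{fid}" for fid in FEATURE_IDS]
        )
        y = np.array([1] * 6 + [2] * 4 + [3] * 2)
        model, resub, _ = train_decision_tree(X, y, n_folds=2, seed=0)
        assert model.get_n_leaves() == 1
        assert model.predict(X.iloc[:1])[0] == 1  # modal class
        assert resub == pytest.approx(0.5)

    def test_too_many_folds_rejected(self, separable_table):
        X, y = separable_table
        with pytest.raises(ValidationError):
            train_decision_tree(X, y, n_folds=len(X) + 1)


class TestClassify:
    def test_training_instance_gets_its_own_label(self, separable_table, suite3):
        X, y = separable_table
        model, _ = train_random_forest(X, y, seed=0)
        trial = suite3[0].recording
        rows = X.loc[[f"{trial.trial_id}/{sid}" for sid in trial.sensor_ids]]
        rows.index = trial.sensor_ids
        pred = classify(model, rows, reference_order=trial.reference_order)
        assert pred.accuracy == 1.0
        assert not pred.conflicts

    def test_conflicting_votes_resolved_and_flagged(self, separable_table):
        X, y = separable_table
        model, _ = train_random_forest(X, y, seed=0)
        row = X.iloc[[0]].copy()
        dup = pd.concat([row, row])
        dup.index = ["s1", "s2"]
        pred = classify(model, dup)
        assert len(set(pred.predicted_order)) == 2  # both sensors placed
        assert pred.conflicts  # identical rows must collide

    def test_held_out_accuracy_near_oob_estimate(self, separable_table):
        from conftest import THREE_SENSOR_CONFIGS
        from tremorkit.synth import make_fixture_suite

        X, y = separable_table
        model, oob = train_random_forest(X, y, seed=0)
        held_out = make_fixture_suite(4, seed=99, configurations=THREE_SENSOR_CONFIGS)
        correct = total = 0
        for sim in held_out:
            trial = sim.recording
            Xh, yh = build_rank_feature_table([trial])
            Xh.index = trial.sensor_ids
            pred = classify(model, Xh, reference_order=trial.reference_order)
            correct += sum(pred.per_sensor_correct.values())
            total += len(trial.sensor_ids)
        assert correct / total >= (1.0 - oob) - 0.1

    def test_schema_mismatch_rejected(self, separable_table):
        X, y = separable_table
        model, _ = train_random_forest(X, y, seed=0)
        with pytest.raises(ValidationError):
            classify(model, X.iloc[:3, :5])
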