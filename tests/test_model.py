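import numpy as np
import pytest

from sotyper.features import FeatureTable
from sotyper.io import resolve_montage
from sotyper.model import (CLASS_ORDER, SchemaMismatchError, SOTypeClassifier,
                           TrainedEnsemble, TrainingSettings, evaluate,
                           make_split_plan, run_montage_battery,
                           train_ensemble)
from conftest import synthetic_feature_table

FAST = TrainingSettings(n_estimators=60, max_depth=3, learning_rate=0.3)


def test_split_plan_sizes_and_disjointness():
    ids = [f"s{i}" for i in range(10)]
    plan = make_split_plan(ids, n_splits=5, train_fraction=0.7, seed=0)
    assert plan.n_splits == 5
    for train, test in plan.splits:
        assert len(train) == 7 and len(test) == 3
        assert train & test == set()
        assert train | test == set(ids)


def test_split_plan_reproducible():
    ids = [f"s{i}" for i in range(9)]
    p1 = make_split_plan(ids, seed=42)
    p2 = make_split_plan(ids, seed=42)
    assert p1.splits == p2.splits


def test_split_plan_bad_fraction():
    with pytest.raises(ValueError):
        make_split_plan(["a", "b"], train_fraction=1.5)


def test_events_of_subject_on_one_side_only():
    table = synthetic_feature_table(n_subjects=8, rows_per_subject=10, seed=1)
    plan = make_split_plan(table.meta["subject_id"], seed=3)
    for train, test in plan.splits:
        sides = table.meta["subject_id"].map(
            lambda s: "train" if s in train else "test")
        for sid, grp in sides.groupby(table.meta["subject_id"]):
            assert grp.nunique() == 1


def test_separable_features_high_heldout_accuracy():
    table = synthetic_feature_table(n_subjects=12, rows_per_subject=25,
                                    montage="FC", separation=3.0, seed=2)
    clf = SOTypeClassifier(table, settings=FAST)
    res = clf.fit(seed=0)
    assert res.heldout_accuracy >= 0.95


def test_label_shuffled_accuracy_near_chance():
    table = synthetic_feature_table(n_subjects=12, rows_per_subject=25,
                                    montage="FC", separation=3.0, seed=4,
                                    shuffle_labels=True)
    clf = SOTypeClassifier(table, settings=FAST)
    res = clf.fit(seed=0)
    assert abs(res.heldout_accuracy - res.chance_accuracy) <= 0.1


def test_training_deterministic_given_seeds():
    table = synthetic_feature_table(n_subjects=8, rows_per_subject=10,
                                    montage="F", seed=5)
    r1 = SOTypeClassifier(table, settings=FAST).fit(seed=7)
    r2 = SOTypeClassifier(table, settings=FAST).fit(seed=7)
    p1 = r1.predict_proba(r1.model.table)
    p2 = r2.predict_proba(r2.model.table)
    np.testing.assert_array_equal(p1, p2)


def test_missing_class_in_training_side_raises():
    table = synthetic_feature_table(n_subjects=4, rows_per_subject=6,
                                    montage="F", seed=6)
    # give one subject all the Local rows, then force it into test
    meta = table.meta.copy()
    meta.loc[meta["so_type"] == "Local", "subject_id"] = "subj00"
    meta.loc[meta["subject_id"] == "subj00", "so_type"] = "Local"
    bad = FeatureTable(table.data, meta, table.montage)
    plan = make_split_plan(meta["subject_id"].unique(), seed=0)
    plan.splits = [(set(meta["subject_id"]) - {"subj00"}, {"subj00"})]
    with pytest.raises(ValueError, match="Local"):
        train_ensemble(bad, plan, FAST)


def test_probability_rows_sum_to_one():
    table = synthetic_feature_table(n_subjects=8, rows_per_subject=10,
                                    montage="F", seed=8)
    res = SOTypeClassifier(table, settings=FAST).fit(seed=0)
    proba = res.predict_proba(res.model.table)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)


def test_ensemble_average_is_arithmetic_mean():
    table = synthetic_feature_table(n_subjects=8, rows_per_subject=10,
                                    montage="F", seed=9)
    res = SOTypeClassifier(table, settings=FAST).fit(seed=0)
    import xgboost as xgb
    dmat = xgb.DMatrix(res.model.table.data.values,
                       feature_names=res.ensemble.feature_columns)
    per_model = np.array([b.predict(dmat) for b in res.ensemble.boosters])
    np.testing.assert_allclose(res.predict_proba(res.model.table),
                               per_model.mean(axis=0), rtol=1e-6)


def test_schema_mismatch_raises():
    table = synthetic_feature_table(n_subjects=6, rows_per_subject=8,
                                    montage="F", seed=10)
    res = SOTypeClassifier(table, settings=FAST).fit(seed=0)
    other = synthetic_feature_table(n_subjects=2, rows_per_subject=4,
                                    montage="FC", seed=10)
    with pytest.raises(SchemaMismatchError):
        res.predict_proba(other)


def test_evaluate_perfect_predictions():
    labels = ["Global", "Frontal", "Local", "Global"]
    proba = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]], float)
    rep = evaluate(proba, labels)
    assert rep.accuracy == 1.0
    assert rep.log_loss < 1e-10
    assert rep.confusion.sum() == 4
    assert np.trace(rep.confusion) == 4


def test_evaluate_chance_baseline_closed_form():
    # proportions (0.376, 0.295, 0.330) -> sum of squares ~ 0.338
    rng = np.random.default_rng(0)
    n = 10000
    labels = (["Global"] * 3760 + ["Frontal"] * 2950 + ["Local"] * 3290)
    proba = np.tile([1 / 3, 1 / 3, 1 / 3], (len(labels), 1))
    rep = evaluate(proba, labels)
    expected = 0.376 ** 2 + 0.295 ** 2 + 0.329 ** 2
    assert rep.chance_accuracy == pytest.approx(expected, abs=0.002)


def test_evaluate_confusion_counting():
    labels = ["Global", "Global", "Global"]
    proba = np.array([[0.9, 0.05, 0.05], [0.8, 0.1, 0.1], [0.2, 0.7, 0.1]])
    rep = evaluate(proba, labels)
    assert rep.confusion[0].tolist() == [2, 1, 0]


def test_evaluate_errors():
    with pytest.raises(ValueError):
        evaluate(np.ones((2, 3)) / 3, ["Global"])
    with pytest.raises(ValueError):
        evaluate(np.ones((1, 3)) / 3, ["Sideways"])


def test_predict_proba_mean_of_synthetic_boosters():
    # five models outputting one-hot on different classes (3,1,1) -> .6/.2/.2
    onehots = [np.array([1.0, 0, 0])] * 3 + [np.array([0, 1.0, 0]),
                                             np.array([0, 0, 1.0])]
    mean = np.mean(onehots, axis=0)
    np.testing.assert_allclose(mean, [0.6, 0.2, 0.2])


def test_montage_battery_predictor_counts():
    table = synthetic_feature_table(n_subjects=6, rows_per_subject=8,
                                    seed=11)
    out = run_montage_battery(table, montage_names=("FCPO", "F"),
                              feature_modes=("full", "base"), seed=0,
                              settings=FAST)
    assert len(out[("FCPO", "full")].ensemble.feature_columns) == 280
    assert len(out[("F", "base")].ensemble.feature_columns) == 12
    assert len(out) == 4


def test_stage_filter_restricts_rows():
    table = synthetic_feature_table(n_subjects=6, rows_per_subject=8,
                                    montage="F", seed=12)
    table.meta.loc[:20, "stage"] = "N2"
    clf = SOTypeClassifier(table, feature_mode="full", stage="N2",
                           settings=FAST)
    assert (clf.table.meta["stage"] == "N2").all()
    assert len(clf.table) == 21


def test_ensemble_save_load_roundtrip(tmp_path):
    table = synthetic_feature_table(n_subjects=6, rows_per_subject=8,
                                    montage="F", seed=13)
    res = SOTypeClassifier(table, settings=FAST).fit(seed=0)
    res.ensemble.save(tmp_path / "model")
    back = TrainedEnsemble.load(tmp_path / "model")
    np.testing.assert_allclose(back.predict_proba(res.model.table),
                               res.predict_proba(res.model.table),
                               rtol=1e-6)


def test_summary_mentions_key_quantities():
    table = synthetic_feature_table(n_subjects=6, rows_per_subject=8,
                                    montage="F", seed=14)
    res = SOTypeClassifier(table, settings=FAST).fit(seed=0)
    s = res.summary()
    assert "held-out accuracy" in s
    assert "chance baseline" in s
    assert "Global" in s
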