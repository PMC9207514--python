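"""Screening metrics, AUC, cross-validation, ranking, ratio sweep."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import fntscreen as fs
import fntscreen.evaluation as ev
import fntscreen.hybrid_trainer as ht
from fntscreen.errors import InputError, MetricError


def test_hand_computed_confusion_example():
    # tp=9 fn=1 fp=2 tn=8
    y = np.array([1] * 10 + [0] * 10)
    scores = np.concatenate([
        np.full(9, 0.9), [0.1],          # positives: 9 above, 1 below
        np.full(2, 0.9), np.full(8, 0.1)  # negatives: 2 above, 8 below
    ])
    rep = ev.compute_metrics(y, scores)
    assert (rep.tp, rep.fn, rep.fp, rep.tn) == (9, 1, 2, 8)
    assert rep.tpr == pytest.approx(0.9, abs=1e-12)
    assert rep.fpr == pytest.approx(0.2, abs=1e-12)
    assert rep.precision == pytest.approx(9 / 11, abs=1e-12)
    assert rep.specificity == pytest.approx(0.8, abs=1e-12)
    assert rep.f1 == pytest.approx(2 * (9 / 11) * 0.9 / (9 / 11 + 0.9), abs=1e-12)


def test_perfect_and_degenerate_threshold_cases():
    y = np.array([1, 1, 0, 0])
    rep = ev.compute_metrics(y, np.array([0.9, 0.8, 0.2, 0.1]))
    assert (rep.tpr, rep.fpr, rep.f1) == (1.0, 0.0, 1.0)
    rep = ev.compute_metrics(y, np.full(4, 0.3))
    assert rep.tpr == 0.0 and rep.specificity == 1.0
    assert "precision" in rep.undefined  # tp+fp = 0 -> flagged zero


def test_specificity_complements_fpr():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 50)
    scores = rng.random(50)
    rep = ev.compute_metrics(y, scores)
    assert rep.specificity == pytest.approx(1.0 - rep.fpr, abs=1e-12)


def test_auc_pair_enumeration_and_extremes():
    y = np.array([1, 1, 0, 0])
    s = np.array([0.9, 0.4, 0.6, 0.1])
    # brute force over all positive-negative pairs: 3 wins + 1 loss of 4
    wins = sum(
        1.0 if sp > sn else 0.5 if sp == sn else 0.0
        for sp in s[y == 1] for sn in s[y == 0]
    )
    assert ev.auc(y, s) == pytest.approx(wins / 4) == pytest.approx(0.75)
    assert ev.auc(y, np.array([0.9, 0.8, 0.2, 0.1])) == 1.0
    assert ev.auc(y, np.full(4, 0.5)) == 0.5


def test_auc_agrees_with_sklearn_reference():
    rng = np.random.default_rng(1)
    for _ in range(20):
        y = rng.integers(0, 2, 40)
        if len(np.unique(y)) < 2:
            continue
        scores = np.round(rng.random(40), 2)  # rounding induces ties
        assert ev.auc(y, scores) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def test_auc_single_class_rejected():
    with pytest.raises(MetricError):
        ev.auc(np.ones(5), np.random.default_rng(0).random(5))


def test_empty_metrics_input_rejected():
    with pytest.raises(InputError):
        ev.compute_metrics(np.empty(0), np.empty(0))


@pytest.fixture(scope="module")
def cv_result(blobs):
    X, y = blobs
    cfg = ht.TrainConfig(
        population_size=8, gp_generations=3, ssa_iterations_screen=8,
        ssa_population_screen=4, ssa_iterations_final=20, seed=19,
    )
    return ev.cross_validate(X, y, cfg, k=5), X, y, cfg


def test_cv_folds_partition_and_stratify(cv_result):
    cv, X, y, _ = cv_result
    assert set(cv.fold_assignment) == set(range(5))
    # disjoint + exhaustive by construction of the assignment vector
    assert np.all(cv.fold_assignment >= 0)
    for fold in range(5):
        mask = cv.fold_assignment == fold
        n_pos = int(y[mask].sum())
        assert abs(n_pos - y.sum() / 5) <= 1


def test_cv_deterministic(cv_result, blobs):
    cv, X, y, cfg = cv_result
    again = ev.cross_validate(X, y, cfg, k=5)
    assert np.array_equal(cv.fold_assignment, again.fold_assignment)
    assert cv.mean == again.mean


def test_cv_class_smaller_than_k_rejected(blobs):
    X, y = blobs
    idx = np.r_[0:6, 60:66]  # 6 positives + 6 negatives
    with pytest.raises(InputError, match="smaller k"):
        ev.cross_validate(X[idx], y[idx], ht.TrainConfig(), k=10)


def test_cv_frame_schema(cv_result):
    cv, *_ = cv_result
    df = cv.as_frame()
    assert list(df.columns)[:5] == ["fold", "tp", "fp", "tn", "fn"]
    assert 0.0 <= cv.mean["auc"] <= 1.0


def test_rank_methods_best_everywhere_and_midrank():
    table = pd.DataFrame(
        {"d1": [0.9, 0.8, 0.7], "d2": [0.95, 0.85, 0.75]},
        index=["m1", "m2", "m3"],
    )
    ranks = ev.rank_methods(table)
    assert ranks["m1"] == 1.0 and ranks["m3"] == 3.0
    # tie for best in one of two datasets -> ranks 1.5 there
    tied = pd.DataFrame({"d1": [0.9, 0.9], "d2": [0.8, 0.7]}, index=["a", "b"])
    r = ev.rank_methods(tied)
    assert r["a"] == pytest.approx((1.5 + 1) / 2)
    assert r["b"] == pytest.approx((1.5 + 2) / 2)


def test_rank_methods_column_permutation_invariant():
    rng = np.random.default_rng(2)
    table = pd.DataFrame(rng.random((4, 3)), columns=list("xyz"))
    assert ev.rank_methods(table).equals(ev.rank_methods(table[["z", "x", "y"]]))


def test_rank_methods_missing_entries_rejected():
    table = pd.DataFrame({"d1": [0.9, np.nan]})
    with pytest.raises(InputError):
        ev.rank_methods(table)


def test_ratio_experiment_counts_and_errors():
    spec = fs.FingerprintSpec(n_pos=12, n_neg=0, n_bits=64, block_size=16, seed=8)
    positives, _ = fs.make_fingerprint_classes(spec)
    pool = fs.make_decoy_pool(positives, 40, dissimilarity=0.1, rng=9)
    cfg = ht.TrainConfig(
        population_size=4, gp_generations=1, ssa_iterations_screen=3,
        ssa_population_screen=3, ssa_iterations_final=3, seed=5,
    )
    table, errors = ev.ratio_experiment(positives, pool, [1, 2, 10], cfg, k=3)
    assert list(table["ratio"]) == [1, 2]
    assert list(table["n_neg"]) == [12, 24]
    assert 10 in errors  # pool of 40 cannot supply 120 decoys
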