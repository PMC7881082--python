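"""Confusion counts, derived metrics, K-fold CV, and abnormal-row filtering."""

import math

import numpy as np
import pandas as pd
import pytest

from seizurekit import (
    ConfusionCounts,
    compute_metrics,
    confusion,
    cross_validate,
    filter_abnormal,
    kfold_assign,
    simulate_feature_table,
)
from conftest import make_separable_table
from reference_values import CONTINUOUS_COUNTS, RANDOM_COUNTS


def test_confusion_perfect_and_trivial_predictions():
    y = ["s"] * 5 + ["n"] * 5
    assert confusion(y, y) == ConfusionCounts(tp=5, tn=5, fp=0, fn=0)
    assert confusion(y, ["n"] * 10) == ConfusionCounts(tp=0, tn=5, fp=0, fn=5)


def test_confusion_matches_brute_force_count():
    rng = np.random.default_rng(0)
    for _ in range(20):
        y_true = rng.choice(["s", "n"], size=50)
        y_pred = rng.choice(["s", "n"], size=50)
        c = confusion(y_true, y_pred)
        pairs = list(zip(y_true, y_pred))
        assert c.tp == pairs.count(("s", "s"))
        assert c.tn == pairs.count(("n", "n"))
        assert c.fp == pairs.count(("n", "s"))
        assert c.fn == pairs.count(("s", "n"))
        assert c.total == 50


def test_confusion_rejects_length_mismatch_and_nonbinary():
    with pytest.raises(ValueError, match="mismatch"):
        confusion(["s"], ["s", "n"])
    with pytest.raises(ValueError, match="binary"):
        confusion(["s", "n", "x"], ["s", "n", "n"])


def test_headline_metric_cells():
    knn = compute_metrics(ConfusionCounts(tp=37, tn=31, fp=6, fn=6))
    assert knn.accuracy == pytest.approx(85.0)
    assert knn.sensitivity == pytest.approx(86.04651, abs=5e-6)
    assert knn.specificity == pytest.approx(83.78378, abs=5e-6)
    assert knn.miss_rate == pytest.approx(13.95349, abs=5e-6)
    ens = compute_metrics(ConfusionCounts(tp=42, tn=31, fp=9, fn=0))
    assert ens.accuracy == pytest.approx(89.02439, abs=5e-6)
    assert ens.sensitivity == 100.0
    assert ens.positive_predictivity == pytest.approx(82.35294, abs=5e-6)
    assert ens.f1 == pytest.approx(90.32258, abs=5e-6)


def test_forced_metrics_on_minimal_counts():
    r = compute_metrics(ConfusionCounts(tp=1, tn=1, fp=0, fn=0))
    assert (r.accuracy, r.sensitivity, r.specificity, r.f1) == (100, 100, 100, 100)
    assert (r.fall_out, r.miss_rate) == (0, 0)


def test_zero_denominator_reported_as_undefined(caplog):
    r = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
    assert math.isnan(r.sensitivity) and math.isnan(r.miss_rate)
    assert math.isnan(r.positive_predictivity) and math.isnan(r.f1)
    assert r.specificity == 100.0
    assert any("undefined" in rec.message for rec in caplog.records)


@pytest.mark.parametrize(
    "counts", list(RANDOM_COUNTS.values()) + list(CONTINUOUS_COUNTS.values())
)
def test_complement_identities(counts):
    r = compute_metrics(ConfusionCounts(*counts))
    assert r.sensitivity + r.miss_rate == pytest.approx(100.0)
    assert r.specificity + r.fall_out == pytest.approx(100.0)
    assert r.recall == r.sensitivity and r.precision == r.positive_predictivity
    assert min(r.precision, r.recall) - 1e-9 <= r.f1 <= max(r.precision, r.recall)


def test_kfold_is_a_stratified_partition():
    table = simulate_feature_table(125, effect=1.0, seed=0)  # 250 rows
    assignment = kfold_assign(table, K=5, seed=3)
    sizes = np.bincount(assignment.fold_index, minlength=5)
    assert sizes.tolist() == [50] * 5
    y = table["State"].to_numpy()
    for fold in range(5):
        per_class = [np.sum((assignment.fold_index == fold) & (y == c))
                     for c in ("s", "n")]
        assert max(per_class) - min(per_class) <= 1
    # partition: every row in exactly one fold (brute-force set check)
    union = set()
    for fold in range(5):
        members = set(np.flatnonzero(assignment.fold_index == fold))
        assert union.isdisjoint(members)
        union |= members
    assert union == set(range(250))


def test_kfold_equal_to_n_rows_is_leave_one_out(separable_table):
    assignment = kfold_assign(separable_table, K=len(separable_table), seed=0)
    assert sorted(assignment.fold_index) == list(range(len(separable_table)))


def test_kfold_class_smaller_than_k_rejected():
    table = make_separable_table(3)
    with pytest.raises(ValueError, match="at least K"):
        kfold_assign(table, K=5, seed=0)


def test_kfold_reproducible_for_fixed_seed(separable_table):
    a = kfold_assign(separable_table, K=5, seed=9).fold_index
    b = kfold_assign(separable_table, K=5, seed=9).fold_index
    assert (a == b).all()


def test_cross_validate_separable_table_is_perfect(separable_table):
    result = cross_validate("lda", separable_table, K=5, seed=0)
    assert result.pooled.accuracy == 100.0


def test_cross_validate_fold_counts_sum_to_pooled(separable_table):
    result = cross_validate("knn", separable_table, K=5, seed=1)
    total = sum(result.fold_counts[1:], result.fold_counts[0])
    assert total == result.pooled_counts
    assert result.pooled_counts.total == len(separable_table)


def _contaminated_table(seed, n_bad=4):
    """Separated table plus normal-labeled rows planted far ictal-side."""
    table = simulate_feature_table(50, effect=4.0, seed=seed)
    seizure_median = table[table["State"] == "s"].median(numeric_only=True)
    bad_rows = []
    for i in range(n_bad):
        row = seizure_median.copy()
        for col in ("STD", "Max", "Var", "MOM", "POW", "ENT"):
            row[col] *= 50.0  # many robust SDs beyond even the ictal cluster
        row["Min"] *= 50.0
        row["State"] = "n"
        row["record_id"] = "planted"
        bad_rows.append(row)
    return pd.concat([table, pd.DataFrame(bad_rows)], ignore_index=True)


def test_filter_removes_planted_outlier_rows():
    table = _contaminated_table(seed=0)
    filtered, removed = filter_abnormal(table, z_threshold=3.0)
    assert set(removed["record_id"]) == {"planted"}
    assert len(removed) == 4
    assert len(filtered) + len(removed) == len(table)


def test_filter_leaves_clean_tables_alone():
    clean_runs = 0
    for seed in range(20):
        table = simulate_feature_table(40, effect=3.0, seed=seed)
        _, removed = filter_abnormal(table, z_threshold=3.0)
        clean_runs += len(removed) == 0
    assert clean_runs >= 19  # zero removals in >= 95% of seeded runs


def test_filtering_contaminated_training_does_not_hurt_cv_accuracy():
    deltas = []
    for seed in range(5):
        table = _contaminated_table(seed)
        unfiltered = cross_validate("knn", table, K=5, seed=seed).pooled.accuracy
        filtered_table, _ = filter_abnormal(table, z_threshold=3.0)
        filtered = cross_validate("knn", filtered_table, K=5, seed=seed).pooled.accuracy
        deltas.append(filtered - unfiltered)
    assert np.mean(deltas) >= 0.0
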