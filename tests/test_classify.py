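"""LOOCV machinery, metric formulas, majority vote, grid search, leakage."""
import numpy as np
import pandas as pd
import pytest

from glioradiomics import (
    ClassifierSpec,
    grid_search,
    loocv,
    majority_vote,
    make_estimator,
    metrics_from_confusion,
    roc_auc,
)
from glioradiomics.classify import fit_fold

from oracles import naive_auc


def gaussian_table(rng, n_per_class=10, n_features=5, shift=10.0, classes=("necrosis", "solid")):
    rows = []
    for k, cls in enumerate(classes):
        X = rng.normal(k * shift, 1.0, size=(n_per_class, n_features))
        for i, x in enumerate(X):
            rows.append({"subject_id": f"s{k}{i}", "region_label": cls,
                         **{f"f{j}": v for j, v in enumerate(x)}})
    return pd.DataFrame(rows)


def test_separated_classes_are_perfectly_classified(rng):
    table = gaussian_table(rng)
    res = loocv(table, ClassifierSpec(family="knn", params={"n_neighbors": 1}))
    assert res.metrics.overall_accuracy == 1.0
    assert len(res.predicted_labels) == len(table)
    assert np.allclose(res.probabilities.sum(axis=1), 1.0)


def test_permuted_labels_score_at_chance(rng):
    classes = ("necrosis", "solid", "peritumoral", "edema")
    table = gaussian_table(rng, n_per_class=12, classes=classes)
    permuted = table.copy()
    permuted["region_label"] = rng.permutation(table["region_label"].to_numpy())
    res = loocv(permuted, ClassifierSpec(family="knn", params={"n_neighbors": 5}))
    n = len(table)
    half_width = 1.96 * np.sqrt(0.25 * 0.75 / n)
    assert abs(res.metrics.overall_accuracy - 0.25) <= half_width


def test_loocv_is_deterministic(rng):
    table = gaussian_table(rng, shift=1.0)
    spec = ClassifierSpec(family="random_forest", params={"n_estimators": 50}, seed=3)
    a = loocv(table, spec)
    b = loocv(table, spec)
    assert a.predicted_labels == b.predicted_labels
    assert np.array_equal(a.probabilities, b.probabilities)
    assert a.to_json() == b.to_json()


def test_fold_with_missing_class_is_logged_and_scored(rng, caplog):
    table = gaussian_table(rng, n_per_class=6)
    lone = table.iloc[:1].copy()
    lone["region_label"] = "edema"
    table = pd.concat([table, lone], ignore_index=True)
    with caplog.at_level("WARNING"):
        res = loocv(table, ClassifierSpec(family="knn", params={"n_neighbors": 1}))
    assert any("lost class" in rec.message for rec in caplog.records)
    assert len(res.predicted_labels) == len(table)


def test_metrics_reproduce_one_vs_rest_formulas():
    # class A: TP=9, FN=1, FP=1, TN=89
    counts = np.array([[9, 1], [1, 89]])
    rep = metrics_from_confusion(counts, ["A", "B"])
    assert rep.recall["A"] == pytest.approx(0.90)
    assert rep.precision["A"] == pytest.approx(0.90)
    assert rep.f1["A"] == pytest.approx(0.90)
    assert rep.accuracy["A"] == pytest.approx(0.98)

    perfect = np.diag([5, 5, 5, 5])
    rep = metrics_from_confusion(perfect, list("ABCD"))
    assert rep.overall_accuracy == 1.0
    assert all(v == 1.0 for v in rep.recall.values())
    assert all(v == 1.0 for v in rep.f1.values())

    # degenerate predictor: everything called class A on balanced 4-class data
    all_a = np.zeros((4, 4), dtype=int)
    all_a[:, 0] = 10
    rep = metrics_from_confusion(all_a, list("ABCD"))
    assert rep.recall["A"] == 1.0
    assert rep.precision["A"] == pytest.approx(0.25)
    assert rep.recall["B"] == rep.recall["C"] == rep.recall["D"] == 0.0
    assert any(flag.startswith("precision/") for flag in rep.zero_denominator_flags)


def test_macro_accuracy_equals_trace_over_total(rng):
    counts = rng.integers(0, 20, size=(4, 4))
    rep = metrics_from_confusion(counts, list("ABCD"))
    assert rep.overall_accuracy == pytest.approx(
        np.trace(counts) / counts.sum()
    )


@pytest.mark.parametrize(
    "votes, probs, expected",
    [
        (["A", "A", "B"], None, "A"),
        (["B", "B", "B"], None, "B"),
        (["A", "B"], np.array([[0.6, 0.4], [0.45, 0.55]]), "A"),
    ],
)
def test_majority_vote(votes, probs, expected):
    assert majority_vote(votes, probs) == expected


def test_majority_vote_rejects_empty():
    with pytest.raises(ValueError):
        majority_vote([])


def test_auc_examples_and_pair_counting_oracle(rng):
    labels = np.array(["pos", "pos", "neg", "neg"])
    perfect = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
    auc = roc_auc(perfect, labels, ["pos", "neg"])
    assert auc["pos"] == 1.0 and auc["neg"] == 1.0

    constant = np.full((4, 2), 0.5)
    auc = roc_auc(constant, labels, ["pos", "neg"])
    assert auc["pos"] == 0.5

    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.4, 0.7])
    y = np.array([0, 0, 1, 1, 1, 0])
    probs = np.column_stack([1 - scores, scores])
    auc = roc_auc(probs, np.where(y == 1, "pos", "neg"), ["neg", "pos"])
    assert auc["pos"] == pytest.approx(naive_auc(scores, y))

    degenerate = roc_auc(constant, np.array(["pos"] * 4), ["pos", "neg"])
    assert degenerate["pos"] is None


def test_grid_search_single_point_and_cap(rng):
    table = gaussian_table(rng)
    spec = ClassifierSpec(family="knn", grid={"n_neighbors": [3]})
    chosen = grid_search(table, spec)
    assert chosen.resolved_params()["n_neighbors"] == 3

    rf = ClassifierSpec(family="random_forest", params={"max_features": 2000})
    model = make_estimator(rf, n_features=10)
    assert model.named_steps["clf"].get_params()["max_features"] == 10


def test_grid_search_recovers_k_one():
    """Twin points per class: the nearest neighbor is always the twin, the
    next two neighbors always belong to other classes, so only k=1 is clean."""
    base = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    rows = []
    for i, x in enumerate(base):
        cls = "A" if i % 2 == 0 else "B"
        for twin in (x, x + 0.01):
            rows.append({"subject_id": f"s{i}", "region_label": cls, "f0": twin})
    table = pd.DataFrame(rows)
    spec = ClassifierSpec(
        family="knn", grid={"n_neighbors": [1, 3, 5], "metric": ["euclidean"]}
    )
    chosen = grid_search(table, spec)
    assert chosen.resolved_params()["n_neighbors"] == 1


def test_no_leakage_from_held_out_row(rng):
    table = gaussian_table(rng, n_per_class=8)
    spec = ClassifierSpec(family="knn", params={"n_neighbors": 3})
    corrupted = table.copy()
    cols = [c for c in table.columns if c.startswith("f")]
    corrupted.loc[4, cols] = 1e6

    model_a = fit_fold(table, spec, held_out=4)
    model_b = fit_fold(corrupted, spec, held_out=4)
    assert np.allclose(model_a.named_steps["scale"].mean_,
                       model_b.named_steps["scale"].mean_)
    probe = rng.normal(5.0, 3.0, size=(20, len(cols)))
    assert np.array_equal(model_a.predict(probe), model_b.predict(probe))
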