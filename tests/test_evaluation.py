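import numpy as np
import pandas as pd
import pytest

import afrecur as af
import afrecur.evaluate as ev
from afrecur.evaluate import ALL_METHODS, ConfusionMatrix
from naive_oracles import naive_auc


def _labels_74():
    return np.array([1] * 42 + [0] * 32), np.array(
        [f"P{i:03d}" for i in range(74)], dtype=object)


def test_split_protocol_matches_stated_arithmetic():
    y, ids = _labels_74()
    plan = af.make_split(ids, y, af.AnalysisConfig(n_repetitions=10), seed=0)
    lab = dict(zip(ids, y))
    test_labels = [lab[p] for p in plan.test_ids]
    assert len(plan.test_ids) == 16
    assert sum(test_labels) == 8 and len(test_labels) - sum(test_labels) == 8
    for train, val in plan.repetitions:
        assert len(train) == 39 and len(val) == 19          # 58 remaining
        assert sum(lab[p] for p in val) == 11               # round(34/3)
        assert sum(lab[p] for p in train) == 23
        assert not (set(train) | set(val)) & set(plan.test_ids)
        assert not set(train) & set(val)


def test_split_plan_is_deterministic_and_covers_validation():
    y, ids = _labels_74()
    cfg = af.AnalysisConfig(n_repetitions=100)
    a = af.make_split(ids, y, cfg, seed=5)
    b = af.make_split(ids, y, cfg, seed=5)
    assert a == b
    seen_in_validation = set()
    for _, val in a.repetitions:
        seen_in_validation |= set(val)
    non_test = set(ids) - set(a.test_ids)
    assert seen_in_validation == non_test


def test_split_rejects_too_small_classes():
    y = np.array([0] * 9 + [1] * 30)
    ids = np.array([f"P{i}" for i in range(39)], dtype=object)
    with pytest.raises(ValueError, match="class 0"):
        af.make_split(ids, y, af.AnalysisConfig())


def test_metrics_match_printed_formulas():
    m = af.compute_metrics(ConfusionMatrix(tp=3, tn=4, fp=1, fn=2))
    assert m["accuracy"] == pytest.approx(0.7)
    assert m["sensitivity"] == pytest.approx(0.6)
    assert m["specificity"] == pytest.approx(0.8)
    assert m["f1"] == pytest.approx(6 / 9)
    perfect = af.compute_metrics(ConfusionMatrix(tp=5, tn=5, fp=0, fn=0))
    assert all(perfect[k] == 1.0 for k in
               ("accuracy", "sensitivity", "specificity", "f1"))
    degenerate = af.compute_metrics(ConfusionMatrix(tp=0, tn=7, fp=1, fn=0))
    assert np.isnan(degenerate["sensitivity"])


def test_roc_auc_perfect_null_and_concordance_oracle():
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 2, 60)
    _, auc = af.roc_auc(labels * 2.0 - 1.0, labels)
    assert auc == 1.0

    null_labels = rng.integers(0, 2, 1000)
    _, auc_null = af.roc_auc(rng.standard_normal(1000), null_labels)
    assert abs(auc_null - 0.5) < 0.05

    scores = rng.standard_normal(80)
    labels = rng.integers(0, 2, 80)
    _, auc = af.roc_auc(scores, labels)
    assert auc == pytest.approx(naive_auc(scores, labels), abs=1e-12)

    with pytest.raises(ValueError, match="both classes"):
        af.roc_auc(scores, np.ones(80, dtype=int))


def test_compare_groups_routes_tests_by_distribution_shape():
    rng = np.random.default_rng(1)
    n = 120
    y = np.repeat([0, 1], n // 2)
    frame = pd.DataFrame({
        "gaussian": rng.standard_normal(n) + 0.1 * y,
        "heavy_tailed": np.exp(3.0 * rng.standard_normal(n)),
        "label_copy": y.astype(float),
        "constant": np.ones(n),
    })
    table = af.compare_groups(frame, y).set_index("feature")
    assert table.loc["gaussian", "test"] == "t-test"
    assert "+/-" in table.loc["gaussian", "summary0"]
    assert table.loc["heavy_tailed", "test"] == "mann-whitney"
    assert table.loc["label_copy", "test"] == "chi-square"
    assert table.loc["label_copy", "p_value"] < 1e-10
    assert table.loc["constant", "test"] == "skipped"


def test_compare_groups_needs_both_classes(small_features):
    with pytest.raises(ValueError, match="both classes"):
        af.compare_groups(small_features.drop(columns=["recurrence"]),
                          np.ones(len(small_features), dtype=int))


@pytest.fixture(scope="module")
def quick_report(small_features, quick_config):
    return af.run_experiment(features=small_features, config=quick_config)


def test_experiment_bookkeeping(quick_report, quick_config):
    rep = quick_report
    n_reps = quick_config.n_repetitions
    assert sorted(rep.per_repetition["method"].unique()) == sorted(ALL_METHODS)
    assert len(rep.per_repetition) == n_reps * len(ALL_METHODS)
    metrics = rep.per_repetition[["accuracy", "sensitivity", "specificity"]]
    assert ((metrics >= 0) & (metrics <= 1) | metrics.isna()).all().all()
    # averaged confusion matrix preserves the test-set size
    test_size = sum(quick_config.test_per_class)
    sums = rep.averaged_confusion.sum(axis=1)
    assert np.allclose(sums, test_size)
    # group usage rows are percentages over each method's chosen subset
    assert np.allclose(rep.group_usage.sum(axis=1), 100.0)
    # weights recorded per ensemble repetition
    assert set(rep.weights["method"]) == {"mv", "awv", "owv"}
    assert len(rep.weights) == n_reps * 3 * 5


def test_report_export_round_trip(quick_report, tmp_path):
    quick_report.to_dir(tmp_path / "report")
    per_rep = pd.read_csv(tmp_path / "report" / "per_repetition.csv")
    assert len(per_rep) == len(quick_report.per_repetition)
    assert (tmp_path / "report" / "summary.txt").read_text().startswith(
        "Test-set performance")
    figures = af.plot_report(quick_report, tmp_path / "figs")
    assert all((tmp_path / "figs").joinpath(p.split("/")[-1]).exists()
               for p in figures)


def test_mean_voting_equals_owv_when_grid_is_barycenter(
        small_features, quick_config, monkeypatch):
    def barycenter_only(votes, labels, step=0.1):
        w = af.mean_voting_weights()
        pred, _ = af.ensemble_classify(w, votes)
        return w, float(np.mean(pred == np.asarray(labels, dtype=int)))

    monkeypatch.setattr(ev, "grid_search_weights", barycenter_only)
    rep = af.run_experiment(features=small_features, config=quick_config)
    per = rep.per_repetition.set_index(["method", "repetition"])
    for r in range(quick_config.n_repetitions):
        mv = per.loc[("mv", r)]
        owv = per.loc[("owv", r)]
        assert mv["accuracy"] == owv["accuracy"]
        assert mv["tp"] == owv["tp"] and mv["tn"] == owv["tn"]


def test_test_rows_never_influence_selection_or_weights(
        small_features, quick_config, quick_report):
    """Structural no-leakage check: perturbing the held-out test rows'
    features must leave SFFS traces, validation accuracies and fitted
    ensemble weights unchanged."""
    mutated = small_features.copy()
    hrv_cols = [c for c in mutated.columns if c != "recurrence"]
    mutated.loc[list(quick_report.test_ids), hrv_cols] *= 13.7
    rep2 = af.run_experiment(features=mutated, config=quick_config)
    assert rep2.test_ids == quick_report.test_ids
    for method in ALL_METHODS:
        assert rep2.traces[method].chosen_subset == \
            quick_report.traces[method].chosen_subset
        assert rep2.traces[method].accuracies == \
            quick_report.traces[method].accuracies
    pd.testing.assert_frame_equal(rep2.weights, quick_report.weights)
    pd.testing.assert_series_equal(
        rep2.per_repetition["validation_accuracy"],
        quick_report.per_repetition["validation_accuracy"])


def test_run_experiment_input_validation(small_features):
    with pytest.raises(ValueError, match="cohort or a feature matrix"):
        af.run_experiment()
    with pytest.raises(ValueError, match="canonical"):
        af.run_experiment(features=small_features.iloc[:, :10])
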