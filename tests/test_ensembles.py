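import itertools

import numpy as np
import pytest

import afrecur as af
from afrecur.ensembles import grid_search_weights
from naive_oracles import naive_best_grid_accuracy, naive_vote_rule

ALL_PATTERNS = np.array(list(itertools.product([0, 1], repeat=5)))


def test_mean_voting_weights_are_exactly_one_fifth():
    w = af.mean_voting_weights()
    assert np.array_equal(w, np.full(5, 0.2))
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_mean_voting_equals_three_of_five_majority_on_all_patterns():
    labels, _ = af.ensemble_classify(af.mean_voting_weights(), ALL_PATTERNS)
    majority = (ALL_PATTERNS.sum(axis=1) >= 3).astype(int)
    assert np.array_equal(labels, majority)


def test_ensemble_rule_matches_truth_table_oracle():
    rng = np.random.default_rng(12)
    grid = af.enumerate_weight_grid(0.1, 5)
    weight_sets = grid[rng.choice(len(grid), size=25, replace=False)]
    for w in weight_sets:
        labels, scores = af.ensemble_classify(w, ALL_PATTERNS)
        for row, lab, sc in zip(ALL_PATTERNS, labels, scores):
            exp_lab, exp_sc = naive_vote_rule(w, row)
            assert lab == exp_lab
            assert sc == pytest.approx(exp_sc, abs=1e-12)


def test_boundary_score_of_exactly_half_maps_to_class_zero():
    w = np.array([0.3, 0.2, 0.1, 0.2, 0.2])
    votes = np.array([[1, 1, 0, 0, 0]])  # score 0.5 exactly
    labels, scores = af.ensemble_classify(w, votes)
    assert scores[0] == pytest.approx(0.5, abs=1e-12)
    assert labels[0] == 0
    labels_up, _ = af.ensemble_classify(w, np.array([[1, 1, 1, 0, 0]]))
    assert labels_up[0] == 1


def test_awv_weights_normalize_validation_accuracies():
    assert np.allclose(af.awv_weights([0.6, 0.4, 0.5, 0.5, 0.5]),
                       [0.24, 0.16, 0.20, 0.20, 0.20])
    assert np.allclose(af.awv_weights([0.5] * 5), [0.2] * 5)
    assert np.allclose(af.awv_weights([1, 0, 0, 0, 0]), [1, 0, 0, 0, 0])
    with pytest.raises(ValueError, match="all-zero"):
        af.awv_weights([0.0] * 5)
    with pytest.raises(ValueError):
        af.awv_weights([0.5, 0.5, 0.5, 0.5, 1.5])


def test_weight_grid_enumeration():
    grid = af.enumerate_weight_grid(0.1, 5)
    assert grid.shape == (1001, 5)  # compositions of 10 into 5 parts: C(14,4)
    assert np.allclose(grid.sum(axis=1), 1.0)
    assert len({tuple(w) for w in np.round(grid, 9)}) == 1001
    assert any(np.allclose(w, [1, 0, 0, 0, 0]) for w in grid)
    assert any(np.allclose(w, [0.2] * 5) for w in grid)

    tiny = af.enumerate_weight_grid(0.5, 2)
    assert sorted(map(tuple, tiny)) == [(0.0, 1.0), (0.5, 0.5), (1.0, 0.0)]

    with pytest.raises(ValueError, match="evenly divide"):
        af.enumerate_weight_grid(0.3, 5)


@pytest.mark.parametrize("seed", range(5))
def test_owv_equals_brute_force_grid_maximization(seed):
    rng = np.random.default_rng(seed)
    votes = rng.integers(0, 2, size=(19, 5))
    labels = rng.integers(0, 2, size=19)
    w, acc = grid_search_weights(votes, labels)
    grid = af.enumerate_weight_grid(0.1, 5)
    _, brute_acc = naive_best_grid_accuracy(votes.tolist(), labels.tolist(),
                                            grid.tolist())
    assert acc == pytest.approx(brute_acc, abs=1e-12)
    preds, _ = af.ensemble_classify(w, votes)
    assert np.mean(preds == labels) == pytest.approx(acc, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_owv_dominates_single_votes_and_mean_voting(seed):
    rng = np.random.default_rng(100 + seed)
    labels = rng.integers(0, 2, size=21)
    votes = np.column_stack([
        np.where(rng.random(21) < p, labels, 1 - labels)
        for p in (0.9, 0.7, 0.6, 0.55, 0.5)
    ])
    _, owv_acc = grid_search_weights(votes, labels)
    single_accs = (votes == labels[:, None]).mean(axis=0)
    mv_pred, _ = af.ensemble_classify(af.mean_voting_weights(), votes)
    mv_acc = np.mean(mv_pred == labels)
    assert owv_acc >= single_accs.max() - 1e-12
    assert owv_acc >= mv_acc - 1e-12


def test_perfect_single_classifier_gets_full_validation_accuracy():
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 2, size=30)
    votes = np.column_stack([labels] + [rng.integers(0, 2, 30)
                                        for _ in range(4)])
    w, acc = grid_search_weights(votes, labels)
    assert acc == 1.0
    preds, _ = af.ensemble_classify(w, votes)
    assert np.array_equal(preds, labels)


def test_label_flip_symmetry():
    rng = np.random.default_rng(9)
    votes = rng.integers(0, 2, size=(25, 5))
    labels = rng.integers(0, 2, size=25)
    grid = af.enumerate_weight_grid(0.1, 5)
    for w in grid[rng.choice(len(grid), 10, replace=False)]:
        pred, _ = af.ensemble_classify(w, votes)
        acc = np.mean(pred == labels)
        # complementing all votes and labels mirrors the rule: with the
        # strict-> boundary, a complemented score 1 - s compares to 0.5 the
        # same way unless s == 0.5 exactly (excluded by this fixture)
        scores = votes @ w
        if np.any(np.isclose(scores, 0.5)):
            continue
        pred_c, _ = af.ensemble_classify(w, 1 - votes)
        acc_c = np.mean(pred_c == (1 - labels))
        assert acc_c == pytest.approx(acc, abs=1e-12)


def test_weight_vote_arity_mismatch_rejected():
    with pytest.raises(ValueError):
        af.ensemble_classify([0.5, 0.5], np.array([[1, 0, 1, 0, 1]]))
    with pytest.raises(ValueError, match="sum to 1"):
        af.ensemble_classify([0.5, 0.2, 0.2, 0.2, 0.2],
                             np.array([[1, 0, 1, 0, 1]]))
    with pytest.raises(ValueError, match="binary"):
        af.ensemble_classify(af.mean_voting_weights(),
                             np.array([[1, 0, 2, 0, 1]]))


def test_voting_ensemble_classifier_end_to_end():
    rng = np.random.default_rng(2)
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 4)) + y[:, None] * 4.0
    for method in ("mv", "awv", "owv"):
        clf = af.VotingEnsembleClassifier(method=method, seed=0).fit(X, y)
        assert clf.weights_.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.mean(clf.predict(X) == y) > 0.9
    with pytest.raises(ValueError, match="method"):
        af.VotingEnsembleClassifier(method="stacking").fit(X, y)
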