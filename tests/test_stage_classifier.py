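import numpy as np
import pandas as pd
import pytest
from itertools import product

from microstage.stage_classifier import (
    evaluate_cv,
    kappa_f1,
    ovr_roc,
    rank_features,
)


def _separable_cohort(rng, n_per_class=30, n_features=30, n_informative=5, shift=3.0):
    """Three classes separated along a handful of informative features."""
    xs, ys = [], []
    for c, label in enumerate(["NC", "NM", "M"]):
        x = rng.normal(0, 1, size=(n_per_class, n_features))
        x[:, :n_informative] += c * shift
        xs.append(x)
        ys.extend([label] * n_per_class)
    x = pd.DataFrame(np.vstack(xs), columns=[f"f{k}" for k in range(n_features)])
    return x, np.array(ys)


class TestRankFeatures:
    def test_perfect_feature_ranks_first_by_both_scores(self, rng):
        n = 60
        x = pd.DataFrame(rng.normal(size=(n, 20)),
                         columns=[f"f{k}" for k in range(20)])
        y = np.array(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        x["f7"] = np.repeat([0.0, 10.0, 20.0], 20) + rng.normal(0, 0.1, n)
        table = rank_features(x, y, n_trees=100, seed=0)
        assert table.loc["f7", "rank_gini"] == 1
        assert table.loc["f7", "rank_accuracy"] == 1

    def test_null_features_have_comparable_importances(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 10)))
        y = rng.permutation(["a", "b", "c"] * 20)
        table = rank_features(x, y, n_trees=100, seed=1)
        gini = table["mean_decrease_gini"]
        assert gini.max() < 3 * gini.mean()  # no feature stands out

    def test_seeded_determinism(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 6)))
        y = np.array(["a", "b", "c"] * 10)
        t1 = rank_features(x, y, n_trees=50, seed=5)
        t2 = rank_features(x, y, n_trees=50, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_ranks_are_permutations(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 8)))
        y = np.array(["a", "b", "c"] * 10)
        table = rank_features(x, y, n_trees=50, seed=2)
        assert sorted(table["rank_gini"]) == list(range(1, 9))
        assert sorted(table["rank_accuracy"]) == list(range(1, 9))


class TestOvrRoc:
    def test_one_hot_probabilities_perfect_auc(self):
        y = np.array(["a", "b", "c", "a", "b", "c"])
        p = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]] * 2, dtype=float)
        out = ovr_roc(p, y, classes=["a", "b", "c"])
        assert all(v == 1.0 for v in out["per_class_auc"].values())
        assert out["macro_auc"] == 1.0 and out["micro_auc"] == 1.0

    def test_matches_pairwise_concordance_oracle(self, rng):
        """AUC equals the count of concordant (positive, negative) pairs."""
        y = np.array(["a"] * 4 + ["b"] * 3 + ["c"] * 3)
        p = rng.dirichlet(np.ones(3), size=10)
        out = ovr_roc(p, y, classes=["a", "b", "c"])
        for k, cls in enumerate(["a", "b", "c"]):
            pos = p[y == cls, k]
            neg = p[y != cls, k]
            conc = np.mean([(1.0 if a > b else 0.5 if a == b else 0.0)
                            for a, b in product(pos, neg)])
            assert out["per_class_auc"][cls] == pytest.approx(conc, abs=1e-12)

    def test_label_independent_probabilities_near_half(self, rng):
        y = np.array(["a", "b", "c"] * 40)
        p = rng.dirichlet(np.ones(3), size=120)
        out = ovr_roc(p, y, classes=["a", "b", "c"])
        for v in out["per_class_auc"].values():
            assert abs(v - 0.5) < 0.15

    def test_absent_class_warns_and_macro_over_present(self, rng):
        y = np.array(["a", "b"] * 5)
        p = rng.dirichlet(np.ones(3), size=10)
        with pytest.warns(UserWarning, match="absent"):
            out = ovr_roc(p, y, classes=["a", "b", "c"])
        assert np.isnan(out["per_class_auc"]["c"])
        assert np.isfinite(out["macro_auc"])


class TestKappaF1:
    def test_diagonal_confusion_perfect(self):
        out = kappa_f1(np.diag([10, 12, 8]))
        assert out["kappa"] == pytest.approx(1.0)
        assert out["macro_f1"] == pytest.approx(1.0)

    def test_uniform_confusion_chance(self):
        out = kappa_f1(np.full((3, 3), 5))
        assert out["kappa"] == pytest.approx(0.0, abs=1e-12)

    def test_micro_f1_equals_accuracy(self, rng):
        c = rng.integers(0, 30, size=(3, 3))
        c[0, 0] += 1  # ensure positive total
        out = kappa_f1(c)
        assert out["micro_f1"] == pytest.approx(out["accuracy"], abs=1e-12)

    def test_degenerate_marginals_flagged(self):
        c = np.zeros((3, 3))
        c[0, 0] = 10  # every truth and prediction in one class
        out = kappa_f1(c)
        assert out["kappa"] == 0.0 and out["kappa_degenerate"]


class TestEvaluateCv:
    def test_separable_cohort_high_accuracy(self, rng):
        x, y = _separable_cohort(rng)
        rep = evaluate_cv(x, y, top_k=8, folds=5, n_trees=100, seed=0)
        assert rep.accuracy >= 0.95
        assert rep.kappa >= 0.9
        assert rep.macro_auc > 0.95

    def test_shuffled_labels_near_chance(self, rng):
        x, y = _separable_cohort(rng, n_per_class=30)
        y_null = rng.permutation(y)
        rep = evaluate_cv(x, y_null, top_k=8, folds=5, n_trees=100, seed=1)
        # binomial 99% bounds around 1/3 for n=90
        n = len(y_null)
        bound = 2.576 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(rep.accuracy - 1 / 3) < bound + 0.05
        assert abs(rep.kappa) < 0.2

    def test_confusion_row_sums_equal_class_counts(self, rng):
        x, y = _separable_cohort(rng, n_per_class=15)
        rep = evaluate_cv(x, y, top_k=5, folds=3, n_trees=50, seed=2)
        assert rep.confusion.sum(axis=1).tolist() == [15, 15, 15]

    def test_class_smaller_than_folds_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(8, 4)))
        y = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 2)
        with pytest.raises(ValueError, match="fewer folds"):
            evaluate_cv(x, y, folds=5, n_trees=10, seed=0)

    def test_in_fold_selection_controls_leakage_on_null_data(self, rng):
        """With many noise features and permuted labels, leakage-safe CV stays
        at chance; full-data selection is the optimistic comparator."""
        x = pd.DataFrame(rng.normal(size=(60, 200)))
        y = rng.permutation(["a", "b", "c"] * 20)
        safe = evaluate_cv(x, y, top_k=8, folds=5, n_trees=50, seed=3,
                           select_in_fold=True)
        bound = 2.576 * np.sqrt((1 / 3) * (2 / 3) / 60)
        assert abs(safe.accuracy - 1 / 3) < bound + 0.1
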