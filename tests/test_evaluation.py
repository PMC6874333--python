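import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import labeled_random_table
from nbbd import (OTUTable, evaluate, experiment_grid, kruskal_wallis,
                  report_from_confusion, summarize_top, train_rf)
from nbbd.evaluation import _rank_auc


class TestMetricArithmetic:
    def test_confusion_example(self):
        rep = report_from_confusion(tp=8, fp=1, tn=9, fn=2)
        assert rep.acc == pytest.approx(0.85)
        assert rep.sn == pytest.approx(0.8)
        assert rep.sp == pytest.approx(0.9)
        assert rep.mcc == pytest.approx(70 / np.sqrt(9 * 10 * 10 * 11), abs=1e-4)

    def test_degenerate_single_class_predictions_give_zero_mcc(self):
        rep = report_from_confusion(tp=10, fp=10, tn=0, fn=0)
        assert rep.mcc == 0.0

    def test_accuracy_rederivable_from_confusion(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 30, 4)
            if tp + fp + tn + fn == 0:
                continue
            rep = report_from_confusion(int(tp), int(fp), int(tn), int(fn))
            assert rep.acc == pytest.approx((tp + tn) / (tp + fp + tn + fn))


class TestAuc:
    def test_perfect_ranking(self):
        y = np.array(["n", "n", "p", "p"])
        assert _rank_auc(y, np.array([0.1, 0.2, 0.8, 0.9]), "p") == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        y = np.array(["p"] * 20 + ["n"] * 30)
        scores = rng.random(50)
        a1 = _rank_auc(y, scores, "p")
        a2 = _rank_auc(y, np.exp(5 * scores), "p")
        assert a1 == pytest.approx(a2)

    def test_ties_handled_by_midrank(self):
        y = np.array(["p", "n"])
        assert _rank_auc(y, np.array([0.5, 0.5]), "p") == pytest.approx(0.5)


class TestTrainEvaluate:
    def test_memorises_separable_training_data(self):
        t = labeled_random_table(n_samples=40, n_taxa=6, seed=5, separating="t01")
        model = train_rf(t, ["t01"], n_trees=50, seed=0)
        rep = evaluate(model, t, ["t01"])
        assert rep.acc == 1.0
        assert rep.auc == 1.0

    def test_deterministic_given_seed(self):
        t = labeled_random_table(seed=6)
        r1 = evaluate(train_rf(t, t.taxon_ids, 50, seed=1), t)
        r2 = evaluate(train_rf(t, t.taxon_ids, 50, seed=1), t)
        assert r1 == r2

    def test_missing_feature_named_in_error(self):
        t = labeled_random_table(seed=7)
        with pytest.raises(KeyError, match="ghost"):
            train_rf(t, ["ghost"], 10, seed=0)

    def test_empty_feature_list_rejected(self):
        t = labeled_random_table(seed=8)
        with pytest.raises(ValueError, match="empty feature list"):
            train_rf(t, [], 10, seed=0)

    def test_single_class_test_set_has_no_auc(self):
        t = labeled_random_table(n_samples=40, seed=9)
        model = train_rf(t, t.taxon_ids, 20, seed=0)
        one_class = t.restrict_samples(t.sample_ids[:20])
        rep = evaluate(model, one_class)
        assert rep.auc is None
        assert 0 <= rep.acc <= 1


@pytest.fixture(scope="module")
def grid_result():
    train = labeled_random_table(n_samples=60, n_taxa=8, seed=10, separating="t02")
    test = labeled_random_table(n_samples=30, n_taxa=8, seed=11, separating="t02")

    def first_k(fsds, k, seed):
        return fsds.taxon_ids[:k]

    def broken(fsds, k, seed):
        raise RuntimeError("selector exploded")

    methods = {"first_k": first_k, "broken": broken}
    return experiment_grid(train, test, [10, 20], methods,
                           k_grid=[2, 4], n_trees=20, seed=1)


class TestExperimentGrid:
    def test_cardinality(self, grid_result):
        # 2 fsds x (1 baseline + 2 methods x 2 k) = 10 rows
        assert len(grid_result) == 10

    def test_baseline_uses_all_features(self, grid_result):
        base = grid_result[grid_result["method"] == "none"]
        assert (base["n_features"] == 8).all()

    def test_failures_recorded_as_status_rows(self, grid_result):
        broken = grid_result[grid_result["method"] == "broken"]
        assert (broken["status"].str.startswith("error")).all()

    def test_deterministic(self):
        train = labeled_random_table(n_samples=40, n_taxa=6, seed=12)
        test = labeled_random_table(n_samples=20, n_taxa=6, seed=13)
        methods = {"first_k": lambda fsds, k, s: fsds.taxon_ids[:k]}
        g1 = experiment_grid(train, test, [10], methods, k_grid=[2], n_trees=20, seed=3)
        g2 = experiment_grid(train, test, [10], methods, k_grid=[2], n_trees=20, seed=3)
        pd.testing.assert_frame_equal(g1, g2)

    def test_summary_picks_highest_auc_then_fewest_features(self):
        grid = pd.DataFrame([
            {"fsds": "DS20", "method": "m", "k": 2, "n_features": 2,
             "auc": 0.9, "status": "ok"},
            {"fsds": "DS20", "method": "m", "k": 4, "n_features": 4,
             "auc": 0.9, "status": "ok"},
            {"fsds": "DS20", "method": "m", "k": 6, "n_features": 6,
             "auc": 0.8, "status": "ok"},
        ])
        top = summarize_top(grid)
        assert len(top) == 1
        assert top.iloc[0]["n_features"] == 2


class TestKruskalWallis:
    @pytest.fixture
    def separated(self):
        df = pd.DataFrame({"t": [1.0, 2, 3, 4, 5, 6]}, index=[f"s{i}" for i in range(6)])
        labels = pd.Series(["a", "a", "a", "b", "b", "b"], index=df.index)
        return OTUTable(df, labels=labels)

    def test_separated_groups_reach_maximal_h(self, separated):
        h, p = kruskal_wallis(separated, "t")
        # no rank overlap: H is the two-group maximum for n=6
        assert h == pytest.approx(stats.kruskal([1, 2, 3], [4, 5, 6])[0])
        assert p < 0.06

    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({"t": [2.0, 2, 2, 2]}, index=list("wxyz"))
        labels = pd.Series(["a", "a", "b", "b"], index=df.index)
        h, p = kruskal_wallis(OTUTable(df, labels=labels), "t")
        assert (h, p) == (0.0, 1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(20)
        df = pd.DataFrame({"t": rng.random(12)}, index=[f"s{i}" for i in range(12)])
        l1 = pd.Series(["a"] * 6 + ["b"] * 6, index=df.index)
        l2 = pd.Series(["b"] * 6 + ["a"] * 6, index=df.index)
        h1, _ = kruskal_wallis(OTUTable(df, labels=l1), "t")
        h2, _ = kruskal_wallis(OTUTable(df, labels=l2), "t")
        assert h1 == pytest.approx(h2)

    def test_monotone_relation_to_mann_whitney(self):
        """With two groups, larger deviation of U from its null midpoint must
        mean larger H."""
        rng = np.random.default_rng(21)
        records = []
        for i in range(12):
            x = rng.random(10)
            y = rng.random(10) + rng.uniform(0, 1)
            df = pd.DataFrame({"t": np.r_[x, y]}, index=[f"s{j}" for j in range(20)])
            labels = pd.Series(["a"] * 10 + ["b"] * 10, index=df.index)
            h, _ = kruskal_wallis(OTUTable(df, labels=labels), "t")
            u = stats.mannwhitneyu(x, y).statistic
            records.append((abs(u - 50), h))
        records.sort()
        hs = [h for _, h in records]
        assert all(b >= a - 1e-9 for a, b in zip(hs, hs[1:]))
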