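import numpy as np
import pandas as pd
import pytest
from scipy import stats

from duotomo import diagnosis as dx
from duotomo.errors import ModelError, StandardizationError


def make_table(X, y, feature_names=None, split="train", mass_prefix="m"):
    n, k = X.shape
    names = feature_names or [f"f{i}" for i in range(k)]
    df = pd.DataFrame(X, columns=names)
    df["label"] = np.where(np.asarray(y) > 0, "malignant", "benign")
    df["mass_id"] = [f"{mass_prefix}{i}" for i in range(n)]
    df["split"] = split
    return dx.FeatureTable(df=df, feature_names=names)


@pytest.fixture(scope="module")
def separable_table():
    rng = np.random.default_rng(0)
    X0 = rng.normal(0, 1, (40, 11))
    X1 = rng.normal(0, 1, (40, 11))
    X1[:, 2] += 3.0
    X1[:, 7] += 2.5
    X = np.vstack([X0, X1])
    y = np.array([0] * 40 + [1] * 40)
    return dx.standardize(make_table(X, y))


class TestStandardize:
    def test_closed_form_on_three_values(self):
        X = np.array([[1.0], [2.0], [3.0]])
        table = make_table(X, [0, 1, 0])
        out = dx.standardize(table)
        got = out.df["f0"].to_numpy()
        assert np.allclose(got, [-1.224744871, 0.0, 1.224744871])

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        X = (X - X.mean(0)) / X.std(0)
        out = dx.standardize(make_table(X, rng.integers(0, 2, 30)))
        assert np.allclose(out.df[out.feature_names].to_numpy(), X, atol=1e-9)

    def test_test_rows_use_training_scaler(self):
        X = np.array([[0.0], [2.0], [4.0], [2.0]])
        table = make_table(X, [0, 1, 0, 1])
        table.df.loc[3, "split"] = "test"
        out = dx.standardize(table)
        # training mean is 2 => the test row equal to it maps to zero
        assert out.df.loc[3, "f0"] == pytest.approx(0.0)
        assert out.rows("train")["f0"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out.rows("train")["f0"].std(ddof=0) == pytest.approx(1.0)

    def test_zero_variance_feature_named_in_error(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(StandardizationError, match="f0"):
            dx.standardize(make_table(X, [0, 1] * 5))


class TestSelectFeatures:
    def test_uninformative_feature_dropped_by_t_test(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.normal(size=200), rng.normal(size=200)])
        X[100:, 1] += 3.0
        y = np.array([0] * 100 + [1] * 100)
        sel = dx.select_features(dx.standardize(make_table(X, y)))
        assert "f0" not in sel.retained
        assert "f1" in sel.retained
        row = sel.diagnostics.set_index("feature").loc["f0"]
        assert row["dropped_at"] == "t_test"

    def test_duplicated_feature_deduplicated(self):
        rng = np.random.default_rng(3)
        base = np.concatenate([rng.normal(0, 1, 100), rng.normal(3, 1, 100)])
        X = np.column_stack([base, base.copy()])
        y = np.array([0] * 100 + [1] * 100)
        sel = dx.select_features(dx.standardize(make_table(X, y)))
        assert len(sel.retained) == 1

    def test_well_separated_feature_survives_overlap_step(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(3, 1, 100)])
        y = np.array([0] * 100 + [1] * 100)
        sel = dx.select_features(dx.standardize(make_table(x[:, None], y)))
        assert sel.retained == ["f0"]
        detail = sel.diagnostics.set_index("feature").loc["f0", "detail"]
        overlap = float(detail.split("=")[1])
        assert overlap < 0.25  # N(0,1) vs N(3,1) overlap is ~13%

    def test_column_permutation_does_not_change_retained_set(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 5))
        X[60:, 0] += 2.0
        X[60:, 3] += 1.5
        y = np.array([0] * 60 + [1] * 60)
        t1 = dx.standardize(make_table(X, y))
        perm = [3, 0, 4, 1, 2]
        t2 = dx.standardize(
            make_table(X[:, perm], y, feature_names=[f"f{i}" for i in perm])
        )
        s1 = dx.select_features(t1)
        s2 = dx.select_features(t2)
        assert set(s1.retained) == set(s2.retained)

    def test_empty_result_is_valid_not_exception(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        sel = dx.select_features(dx.standardize(make_table(X, y)))
        assert sel.retained == [] or isinstance(sel.retained, list)
        assert len(sel.diagnostics) == 3


class TestCNN:
    def test_separable_cohort_reaches_high_training_auc(self, separable_table):
        model = dx.train_cnn(separable_table, separable_table.feature_names,
                             seed=7)
        pom = dx.predict_pom(model, separable_table)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(separable_table.y(), pom) >= 0.99
        assert model.loss_history[-1] < model.loss_history[0]

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 11))
        y = rng.permutation([0] * 40 + [1] * 40)
        table = dx.standardize(make_table(X, y))
        model = dx.train_cnn(table, table.feature_names, seed=9)
        from sklearn.metrics import roc_auc_score

        # evaluate on an independent null draw
        X2 = rng.normal(size=(200, 11))
        y2 = rng.permutation([0] * 100 + [1] * 100)
        auc = roc_auc_score(y2, model.net.predict_proba(X2))
        assert abs(auc - 0.5) < 0.1

    def test_same_seed_identical_pom(self, separable_table):
        m1 = dx.train_cnn(separable_table, separable_table.feature_names, seed=3)
        m2 = dx.train_cnn(separable_table, separable_table.feature_names, seed=3)
        p1 = dx.predict_pom(m1, separable_table)
        p2 = dx.predict_pom(m2, separable_table)
        assert np.array_equal(p1, p2)

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 4))
        table = dx.standardize(make_table(X, np.zeros(20)))
        with pytest.raises(ModelError):
            dx.train_cnn(table, table.feature_names)

    def test_pom_bounded_and_duplicate_rows_equal(self, separable_table):
        model = dx.train_cnn(separable_table, separable_table.feature_names,
                             seed=11)
        rng = np.random.default_rng(12)
        X = rng.normal(0, 5, (1000, 11))
        pom = model.net.predict_proba(X)
        assert (pom >= 0).all() and (pom <= 1).all()
        dup = model.net.predict_proba(np.vstack([X[0], X[0]]))
        assert dup[0] == dup[1]

    def test_feature_mismatch_rejected(self, separable_table):
        model = dx.train_cnn(separable_table, ["f0", "f1"], seed=1)
        bad = make_table(np.zeros((4, 2)), [0, 1, 0, 1],
                         feature_names=["g0", "g1"])
        with pytest.raises(ModelError):
            dx.predict_pom(model, bad)

    def test_class_conditional_pom_ordering(self, separable_table):
        model = dx.train_cnn(separable_table, separable_table.feature_names,
                             seed=13)
        pom = dx.predict_pom(model, separable_table)
        y = separable_table.y()
        assert pom[y == 1].mean() > pom[y == 0].mean()


class TestROC:
    def test_perfect_separation_auc_one(self):
        pom = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 0.95])
        y = np.array([0, 0, 0, 1, 1, 1])
        roc = dx.roc_and_threshold(pom, y)
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_shuffled_pom_near_chance(self):
        rng = np.random.default_rng(14)
        y = np.array([0, 1] * 250)
        pom = rng.permutation(np.linspace(0, 1, 500))
        roc = dx.roc_and_threshold(pom, y)
        assert abs(roc.auc - 0.5) < 0.1

    def test_auc_equals_mann_whitney_u(self):
        rng = np.random.default_rng(15)
        pom = rng.random(120)
        y = rng.integers(0, 2, 120)
        y[:2] = [0, 1]
        roc = dx.roc_and_threshold(pom, y, min_sensitivity=0.9)
        u = stats.mannwhitneyu(pom[y == 1], pom[y == 0],
                               alternative="two-sided").statistic
        assert roc.auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_threshold_achieves_min_sensitivity(self):
        rng = np.random.default_rng(16)
        pom = rng.random(200)
        y = (pom + rng.normal(0, 0.3, 200) > 0.5).astype(int)
        y[:2] = [0, 1]
        roc = dx.roc_and_threshold(pom, y, min_sensitivity=0.95)
        assert roc.sensitivity >= 0.95
        # it is the largest such threshold: one step tighter breaks the floor
        tighter = np.unique(pom)[np.unique(pom) > roc.threshold]
        if tighter.size:
            sens = np.mean(pom[y == 1] >= tighter[0])
            assert sens < 0.95

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(17)
        pom = rng.random(100)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        a1 = dx.roc_and_threshold(pom, y).auc
        a2 = dx.roc_and_threshold(np.exp(3 * pom), y).auc
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            dx.roc_and_threshold(np.array([0.2, 0.8]), np.array([1, 1]))


class TestPermutationImportance:
    @pytest.fixture(scope="class")
    def two_feature_model(self):
        rng = np.random.default_rng(18)

        def cohort(n):
            informative = np.concatenate([rng.normal(0, 1, n // 2),
                                          rng.normal(2.5, 1, n // 2)])
            noise = rng.normal(size=n)
            X = np.column_stack([informative, noise])
            y = np.array([0] * (n // 2) + [1] * (n // 2))
            return X, y

        Xtr, ytr = cohort(120)
        Xte, yte = cohort(120)
        table = make_table(np.vstack([Xtr, Xte]), np.concatenate([ytr, yte]))
        table.df.loc[120:, "split"] = "test"
        table = dx.standardize(table)
        model = dx.train_cnn(table, table.feature_names, seed=19)
        return model, table

    def test_identity_permutation_zero_drop(self, two_feature_model):
        model, table = two_feature_model
        X = table.X("test", features=model.feature_names)
        y = table.y("test")
        from sklearn.metrics import roc_auc_score

        base = roc_auc_score(y, model.net.predict_proba(X))
        same = dx.permuted_auc(model, X, y, 0, np.arange(len(y)))
        assert same == base

    def test_informative_feature_dominates(self, two_feature_model):
        model, table = two_feature_model
        imp = dx.permutation_importance(model, table, split="test",
                                        n_repeats=10, seed=20)
        assert imp["f0"] > imp["f1"]
        assert abs(imp["f1"]) < 0.05  # pure-noise feature near zero


class TestClopperPearson:
    @staticmethod
    def bisect_lower(x, n, alpha):
        """Independent oracle: invert the upper binomial tail by bisection."""
        if x == 0:
            return 0.0
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            tail = 1.0 - stats.binom.cdf(x - 1, n, mid)
            if tail < alpha / 2:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    @staticmethod
    def bisect_upper(x, n, alpha):
        if x == n:
            return 1.0
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            tail = stats.binom.cdf(x, n, mid)
            if tail < alpha / 2:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    @pytest.mark.parametrize("x,n", [(43, 44), (30, 40), (9, 40), (28, 40),
                                     (0, 10), (10, 10), (1, 44)])
    def test_beta_quantile_matches_tail_bisection(self, x, n):
        cp = dx.clopper_pearson(x, n, level=0.99)
        assert cp.ci_lower == pytest.approx(self.bisect_lower(x, n, 0.01),
                                            abs=1e-10)
        assert cp.ci_upper == pytest.approx(self.bisect_upper(x, n, 0.01),
                                            abs=1e-10)

    def test_degenerate_tails(self):
        assert dx.clopper_pearson(0, 20).ci_lower == 0.0
        assert dx.clopper_pearson(20, 20).ci_upper == 1.0

    def test_printed_clinical_statistics(self):
        s = dx.confusion_interval_stats(dx.ConfusionCounts(tp=43, fn=1,
                                                           tn=30, fp=10))
        assert round(100 * s.sensitivity.estimate, 1) == 97.7
        assert round(100 * s.sensitivity.ci_lower, 1) == 84.3
        assert round(100 * s.sensitivity.ci_upper, 1) == 100.0
        assert round(100 * s.specificity.estimate, 1) == 75.0
        assert round(100 * s.specificity.ci_lower, 1) == 53.9
        assert round(100 * s.specificity.ci_upper, 1) == 90.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            dx.clopper_pearson(5, 0)
        with pytest.raises(ValueError):
            dx.clopper_pearson(11, 10)

    def test_mcnemar_exact_sanity(self):
        assert dx.mcnemar_exact(0, 0) == 1.0
        # 23 correct downgrades vs 2 incorrect upgrades is highly asymmetric
        assert dx.mcnemar_exact(23, 2) < 0.001
        assert dx.mcnemar_exact(10, 10) == pytest.approx(1.0)
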