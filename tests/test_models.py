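"""ROC/AUC, DeLong inference, cross-validation, feature selection, training."""

import itertools

import numpy as np
import pytest

from cfpromoter import (ClassifierBundle, ClassifierSpec, backward_select,
                        combine_clinical, delong_ci, delong_paired_test,
                        delong_variance, grid_search, kfold_cv_auc, lasso_select,
                        loocv, roc_auc, train, youden_threshold)


def pair_counting_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_concordant_pairs(self):
        assert roc_auc([.9, .8, .7, .1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([1.0] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_monotone_invariance(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        assert roc_auc(s, y) == pytest.approx(roc_auc(np.exp(2 * s), y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_matches_pair_counting_all_small_instances(self, rng):
        """Oracle equivalence up to n = 12, including tied scores."""
        for n in range(4, 13):
            for _ in range(20):
                y = rng.integers(0, 2, size=n)
                if len(np.unique(y)) < 2:
                    continue
                s = rng.choice(np.arange(5.0), size=n)  # force ties
                assert roc_auc(s, y) == pytest.approx(pair_counting_auc(s, y))


class TestDeLong:
    def test_perfect_separation_degenerate_ci(self):
        with pytest.warns(UserWarning, match="perfect separation"):
            auc, lo, hi = delong_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert (auc, lo, hi) == (1.0, 1.0, 1.0)

    def test_variance_positive_and_shrinks_with_n(self, rng):
        var_by_n = []
        for n in (50, 200, 800):
            s = rng.normal(size=n)
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            _, var = delong_variance(s, y)
            assert var > 0
            var_by_n.append(var)
        assert var_by_n[0] > var_by_n[1] > var_by_n[2]

    def test_variance_matches_bootstrap(self):
        """DeLong variance vs a 2000-replicate bootstrap on a fixed instance."""
        rng = np.random.default_rng(42)
        n = 80
        y = np.array([1] * 30 + [0] * 50)
        s = np.where(y == 1, rng.normal(0.8, 1, n), rng.normal(0, 1, n))
        _, var = delong_variance(s, y)
        boot = []
        pos_idx, neg_idx = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        for _ in range(2000):
            bi = np.concatenate([rng.choice(pos_idx, len(pos_idx)),
                                 rng.choice(neg_idx, len(neg_idx))])
            boot.append(roc_auc(s[bi], y[bi]))
        assert var == pytest.approx(np.var(boot, ddof=1), rel=0.15)

    def test_identical_scores_p_one(self, rng):
        s = rng.normal(size=20)
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        with pytest.warns(UserWarning, match="identical"):
            assert delong_paired_test(s, s, y) == 1.0

    def test_informative_vs_noise_power(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            a = y + rng.normal(0, 0.7, n)        # informative
            b = rng.permutation(a)               # same marginal, no signal
            if delong_paired_test(a, b, y) < 0.01:
                hits += 1
        assert hits >= 19

    def test_agrees_with_permutation_oracle(self):
        """Swap-permutation oracle for paired AUC comparison, fixed instance."""
        rng = np.random.default_rng(7)
        n = 60
        y = np.array([1] * 25 + [0] * 35)
        shared = rng.normal(size=n)
        a = shared + 0.9 * y + rng.normal(0, 1.2, n)
        b = shared + 0.55 * y + rng.normal(0, 1.2, n)
        p_delong = delong_paired_test(a, b, y)
        obs = abs(roc_auc(a, y) - roc_auc(b, y))
        B = 4000
        count = 0
        for _ in range(B):
            flip = rng.integers(0, 2, size=n).astype(bool)
            aa = np.where(flip, b, a)
            bb = np.where(flip, a, b)
            if abs(roc_auc(aa, y) - roc_auc(bb, y)) >= obs - 1e-12:
                count += 1
        p_perm = count / B
        mc_sd = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(p_delong - p_perm) < 4 * mc_sd + 0.02


class TestCV:
    def test_separable_data_pooled_auc_one(self):
        X = np.array([[0.0]] * 20 + [[10.0]] * 20)
        y = np.array([0] * 20 + [1] * 20)
        assert kfold_cv_auc(X, y, ClassifierSpec("svm_linear"), seed=0) == 1.0

    def test_null_auc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 5))
            y = rng.integers(0, 2, size=200)
            aucs.append(kfold_cv_auc(X, y, ClassifierSpec("logistic"), seed=seed))
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_seed_reproducibility(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, size=60)
        spec = ClassifierSpec("svm_linear")
        assert kfold_cv_auc(X, y, spec, seed=3) == kfold_cv_auc(X, y, spec, seed=3)

    def test_too_small_class_rejected(self):
        X = np.zeros((12, 2))
        y = np.array([1] * 3 + [0] * 9)
        with pytest.raises(ValueError, match="stratify"):
            kfold_cv_auc(X, y, ClassifierSpec("svm_linear"), k=10)


class TestBackwardSelect:
    def test_noise_feature_deleted_most_seeds(self):
        """The pure-noise feature is eliminated in most replicates; pooled-CV
        ties occasionally retain the pair, but the informative feature is
        never dropped alone."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 400
            y = rng.integers(0, 2, size=n)
            X = np.column_stack([y + rng.normal(0, 0.6, n), rng.normal(size=n)])
            sel, _ = backward_select(X, y, ClassifierSpec("svm_linear"), k=10,
                                     seed=seed, feature_ids=["A", "B"])
            assert "A" in sel
            if sel == ["A"]:
                hits += 1
        assert hits >= 15

    def test_trace_reproducible(self, rng):
        X = rng.normal(size=(80, 4))
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        spec = ClassifierSpec("svm_linear")
        assert backward_select(X, y, spec, k=5, seed=2) == \
            backward_select(X, y, spec, k=5, seed=2)

    def test_single_feature_rejected(self, rng):
        with pytest.raises(ValueError):
            backward_select(rng.normal(size=(20, 1)), rng.integers(0, 2, 20),
                            ClassifierSpec("svm_linear"))


class TestLassoSelect:
    def test_informative_kept_noise_dropped(self):
        rng = np.random.default_rng(0)
        n = 400
        y = rng.integers(0, 2, size=n)
        X = np.column_stack([y + rng.normal(0, 0.5, n),
                             rng.normal(size=(n, 50))])
        sel = lasso_select(X, y, seed=0)
        assert 0 in sel
        assert len([j for j in sel if j > 0]) <= 10  # >=80% of noise dropped

    def test_null_design_near_null_cv_auc(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 20))
        y = rng.integers(0, 2, size=200)
        sel = lasso_select(X, y, seed=1)
        assert set(sel) <= set(range(20))
        auc = kfold_cv_auc(X[:, sel] if sel else X[:, :1], y,
                           ClassifierSpec("logistic"), seed=1)
        assert 0.35 <= auc <= 0.65

    def test_seed_reproducibility(self, rng):
        X = rng.normal(size=(100, 10))
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        assert lasso_select(X, y, seed=4) == lasso_select(X, y, seed=4)


class TestTrainBundle:
    def _toy(self):
        X = np.array([[0, 0.0]] * 15 + [[3, 3.0]] * 15)
        y = np.array([0] * 15 + [1] * 15)
        return X, y

    @pytest.mark.parametrize("kind", ["svm_linear", "svm_rbf", "logistic",
                                      "random_forest", "xgboost"])
    def test_separable_training_auc_one(self, kind):
        X, y = self._toy()
        spec = ClassifierSpec(kind, {"grid": {"n_estimators": [20]}}
                              if kind in ("random_forest", "xgboost") else {}, seed=0)
        bundle = train(X, y, spec, k=3)
        assert bundle.training_auc == 1.0

    def test_save_reload_scores_identical(self, tmp_path, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        bundle = train(X, y, ClassifierSpec("svm_linear"))
        p = tmp_path / "bundle.pkl"
        bundle.save(p)
        reloaded = ClassifierBundle.load(p)
        assert np.array_equal(bundle.score(X), reloaded.score(X))

    def test_grid_search_returns_argmax_member(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        grid = {"max_depth": [2, 4], "n_estimators": [20, 50], "learning_rate": [0.1]}
        spec = ClassifierSpec("xgboost", seed=0)
        chosen = grid_search(X, y, spec, grid, k=3)
        assert chosen["max_depth"] in grid["max_depth"]
        # exhaustive replay: chosen member attains the max CV AUC
        replay = {}
        for combo in itertools.product(*grid.values()):
            params = dict(zip(grid.keys(), combo))
            replay[tuple(sorted(params.items()))] = kfold_cv_auc(
                X, y, ClassifierSpec("xgboost", params, 0), k=3, seed=0)
        assert replay[tuple(sorted(chosen.items()))] == pytest.approx(max(replay.values()))


class TestLoocv:
    def test_separable_auc_one_and_fit_counter(self):
        X = np.array([[0.0]] * 10 + [[5.0]] * 10)
        y = np.array([0] * 10 + [1] * 10)
        res = loocv(X, y, ClassifierSpec("svm_linear"))
        assert res.auc == 1.0
        assert res.n_fits == 20
        assert res.ci_low <= res.auc <= res.ci_high

    def test_null_mean_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 5))
            y = np.array([1] * 50 + [0] * 50)
            aucs.append(loocv(X, y, ClassifierSpec("logistic")).auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_youden_threshold_metrics_consistent(self, rng):
        s = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        t = youden_threshold(s, y)
        se = np.mean(s[y == 1] >= t)
        sp = np.mean(s[y == 0] < t)
        # no other threshold does better on J
        for tt in np.unique(s):
            se2 = np.mean(s[y == 1] >= tt)
            sp2 = np.mean(s[y == 0] < tt)
            assert se + sp >= se2 + sp2 - 1e-12


class TestCombineClinical:
    def test_null_clinical_does_not_significantly_help(self):
        rng = np.random.default_rng(0)
        n = 200
        y = rng.integers(0, 2, size=n)
        Xg = np.column_stack([(y + rng.normal(0, 0.8, n) > 0.5).astype(float)
                              for _ in range(5)])
        clin = rng.normal(size=(n, 2))  # label-independent BMI/FF stand-ins
        genomic = train(Xg, y, ClassifierSpec("svm_linear"))
        combined = combine_clinical(Xg, clin, y, kernel="linear")
        p = delong_paired_test(genomic.score(Xg), combined.score(np.hstack(
            [Xg, (clin - clin.mean(0)) / clin.std(0)])), y)
        assert p > 0.05

    def test_clinical_only_null_auc_near_half(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            y = rng.integers(0, 2, size=n)
            clin = rng.normal(size=(n, 2))
            bundle = train(clin, y, ClassifierSpec("svm_linear"))
            aucs.append(roc_auc(bundle.score(clin), y))
        assert 0.45 <= np.mean(aucs) <= 0.62  # in-sample fit inflates slightly

    def test_missing_values_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.integers(0, 2, size=20)
        clin = rng.normal(size=(20, 2))
        clin[3, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            combine_clinical(X, clin, y)

    def test_duplicated_column_tolerated(self, rng):
        X = rng.integers(0, 2, size=(30, 3)).astype(float)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        bundle = combine_clinical(X, X[:, 0], y, kernel="rbf")
        assert bundle.score(np.hstack([X, ((X[:, :1] - X[:, 0].mean()) /
                                           (X[:, 0].std() or 1))])).shape == (30,)
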