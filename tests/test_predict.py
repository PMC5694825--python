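"""Feature assembly, splitting, RFE, forest training and model comparison."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connectocast import predict as cp


def brute_binom_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Minlike two-sided binomial p by full pmf enumeration (oracle)."""
    pmf = [comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    ref = pmf[k] * (1 + 1e-9)
    return sum(q for q in pmf if q <= ref)


def covariate_frame(n, rng):
    return pd.DataFrame(
        {
            "subject_id": [f"P{i:03d}" for i in range(n)],
            "age": rng.uniform(34, 65, n),
            "education": rng.integers(10, 22, n),
            "stage": rng.integers(1, 4, n),
            "minority": rng.integers(0, 2, n),
            "menopause": rng.integers(0, 2, n),
            "cad": rng.normal(50, 10, n),
        }
    )


class TestAssembleFeatures:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.cov = covariate_frame(31, rng)
        ids = self.cov["subject_id"]
        regions = [f"R{i:03d}" for i in range(90)]
        self.clust = pd.DataFrame(rng.uniform(0, 1, (31, 90)), index=ids,
                                  columns=regions)
        self.outcome = pd.Series(rng.integers(0, 2, 31), index=ids)

    def test_model1_shape(self):
        fm = cp.assemble_features(self.clust, self.cov, self.outcome, 1)
        assert fm.features.shape == (31, 6)
        assert list(fm.features.columns) == list(cp.MODEL1_COVARIATES)

    def test_model3_shape(self):
        fm = cp.assemble_features(self.clust, self.cov, self.outcome, 3)
        assert fm.features.shape == (31, 96)

    def test_model2_missing_region_names_error(self):
        with pytest.raises(KeyError, match="right inferior parietal"):
            cp.assemble_features(self.clust, self.cov, self.outcome, 2)

    def test_model2_with_named_regions(self):
        clust = self.clust.rename(
            columns=dict(zip(self.clust.columns[:3], cp.MODEL2_REGIONS))
        )
        fm = cp.assemble_features(clust, self.cov, self.outcome, 2)
        assert fm.features.shape == (31, 9)


class TestStratifiedSplit:
    def outcome(self, n1, n0):
        y = [1] * n1 + [0] * n0
        return pd.Series(y, index=[f"P{i:03d}" for i in range(n1 + n0)])

    def test_study_sized_split_sizes(self):
        sizes = set()
        for seed in range(40):
            s = cp.stratified_split(self.outcome(17, 14), seed=seed)
            sizes.add(len(s.test_ids))
            assert len(s.train_ids) + len(s.test_ids) == 31
        assert sizes <= {7, 8} and 7 in sizes and 8 in sizes

    def test_integral_counts_are_exact(self):
        y = self.outcome(20, 20)
        s = cp.stratified_split(y, seed=1)
        assert len(s.train_ids) == 30 and len(s.test_ids) == 10
        assert y.loc[s.test_ids].sum() == 5

    def test_deterministic(self):
        y = self.outcome(17, 14)
        a = cp.stratified_split(y, seed=3)
        b = cp.stratified_split(y, seed=3)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            cp.stratified_split(self.outcome(10, 0), seed=0)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            cp.SplitScheme(train_ids=["a", "b"], test_ids=["b"], seed=0)


class TestExactBinomial:
    @pytest.mark.parametrize(
        "k, n, expected",
        [(5, 7, 0.453), (7, 8, 0.070), (8, 8, 0.008)],
    )
    def test_reported_model_pvalues(self, k, n, expected):
        assert cp.exact_binomial_test(k, n) == pytest.approx(expected, abs=5e-4)

    def test_eight_of_eight_closed_form(self):
        assert cp.exact_binomial_test(8, 8) == pytest.approx(2 * 0.5**8)

    def test_matches_enumeration_oracle(self):
        for n in range(1, 13):
            for k in range(n + 1):
                assert cp.exact_binomial_test(k, n) == pytest.approx(
                    brute_binom_two_sided(k, n), rel=1e-9
                )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cp.exact_binomial_test(1, 0)
        with pytest.raises(ValueError):
            cp.exact_binomial_test(5, 3)


def planted_frame(n, p_noise, n_informative=2, effect=2.0, seed=0):
    rng = np.random.default_rng(seed)
    y = pd.Series(rng.integers(0, 2, n), index=[f"P{i:03d}" for i in range(n)])
    cols = {}
    for j in range(n_informative):
        cols[f"sig{j}"] = rng.normal(0, 1, n) - effect * y.to_numpy()
    for j in range(p_noise):
        cols[f"noise{j}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols, index=y.index), y


class TestRFE:
    def test_informative_features_recovered(self):
        hits = 0
        for seed in range(10):
            X, y = planted_frame(100, 20, seed=seed)
            r = cp.rfe_select(X, y, n_partitions=15, seed=seed)
            hits += {"sig0", "sig1"} <= set(r.selected_features)
        assert hits >= 9

    def test_single_feature_degenerate(self):
        X, y = planted_frame(40, 0, n_informative=1, seed=2)
        r = cp.rfe_select(X, y, n_partitions=5, seed=0)
        assert r.selected_features == ["sig0"]
        assert r.sizes == [1]

    def test_all_noise_accuracy_near_chance(self):
        X, y = planted_frame(100, 12, n_informative=0, seed=5)
        r = cp.rfe_select(X, y, n_partitions=20, seed=1)
        best = len(r.selected_features)
        # single-partition binomial band around 0.5 for |B| = 25
        assert 0.30 <= r.mean_accuracy[best] <= 0.70

    def test_ladder_shapes(self):
        assert cp._size_ladder(5) == [5, 4, 3, 2, 1]
        assert cp._size_ladder(96)[0] == 96
        assert cp._size_ladder(96)[-1] == 1
        assert all(a > b for a, b in zip(cp._size_ladder(96), cp._size_ladder(96)[1:]))

    def test_invalid_partition_count(self):
        X, y = planted_frame(30, 2, seed=0)
        with pytest.raises(ValueError):
            cp.rfe_select(X, y, n_partitions=0, seed=0)


class TestTrainForest:
    def test_outcome_as_feature_is_learned(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.integers(0, 2, 200))
        X = pd.DataFrame({"leak": y.to_numpy().astype(float),
                          "noise": rng.normal(size=200)})
        _, oob, imp = cp.train_forest(X, y, n_trees=200, seed=0)
        assert oob <= 0.05
        assert imp["leak"] > imp["noise"]

    def test_pure_noise_oob_near_chance(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = pd.Series([0, 1] * 100)
            X = pd.DataFrame(rng.normal(size=(200, 8)))
            X.columns = [f"f{i}" for i in range(8)]
            _, oob, _ = cp.train_forest(X, y, n_trees=100, seed=seed)
            assert 0.35 <= oob <= 0.65

    def test_deterministic_given_seed(self):
        X, y = planted_frame(60, 5, seed=3)
        m1, oob1, imp1 = cp.train_forest(X, y, n_trees=100, seed=9)
        m2, oob2, imp2 = cp.train_forest(X, y, n_trees=100, seed=9)
        assert oob1 == oob2 and imp1 == imp2

    def test_constant_outcome_errors(self):
        X, _ = planted_frame(20, 3, seed=0)
        with pytest.raises(ValueError):
            cp.train_forest(X, pd.Series(np.ones(20, dtype=int), index=X.index))


class TestEvaluateHoldout:
    def fit_eval(self, n_test=8, flip=0):
        X, y = planted_frame(80, 2, effect=5.0, seed=4)
        model, oob, imp = cp.train_forest(X.iloc[:-n_test], y.iloc[:-n_test],
                                          n_trees=100, seed=0)
        y_test = y.iloc[-n_test:].copy()
        if flip:
            y_test.iloc[:flip] = 1 - y_test.iloc[:flip]
        return cp.evaluate_holdout(model, X.iloc[-n_test:], y_test,
                                   oob_error=oob, importances=imp)

    def test_perfect_holdout(self):
        ev = self.fit_eval()
        assert ev.accuracy == 1.0
        assert ev.binomial_p == pytest.approx(0.008, abs=5e-4)
        assert ev.auc == 1.0
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0

    def test_chance_level_binomial(self):
        ev = self.fit_eval(flip=4)
        assert ev.accuracy == pytest.approx(0.5)
        assert ev.binomial_p == pytest.approx(1.0)

    def test_separated_scores_auc_one(self):
        ev = self.fit_eval()
        pos = ev.scores[ev.labels == 1]
        neg = ev.scores[ev.labels == 0]
        assert pos.min() > neg.max()
        assert ev.auc == 1.0

    def test_single_class_test_set_warns(self):
        X, y = planted_frame(60, 2, effect=5.0, seed=4)
        model, _, _ = cp.train_forest(X.iloc[:50], y.iloc[:50], n_trees=50, seed=0)
        mask = y.iloc[50:] == 1
        with pytest.warns(UserWarning, match="AUC undefined"):
            ev = cp.evaluate_holdout(model, X.iloc[50:][mask.to_numpy()],
                                     y.iloc[50:][mask.to_numpy()])
        assert ev.auc is None


class TestCompareAUCs:
    def test_identical_scores(self):
        rng = np.random.default_rng(0)
        labels = np.array([0, 1] * 10)
        s = rng.normal(size=20)
        c = cp.compare_aucs(s, s, labels, n_bootstrap=200, seed=1)
        assert c.z == 0.0 and c.p == 1.0

    def test_extreme_separation_significant(self):
        labels = np.array([0, 1] * 25)
        perfect = labels.astype(float)
        anti = 1.0 - labels
        c = cp.compare_aucs(perfect, anti, labels, n_bootstrap=500, seed=2)
        assert c.auc1 == 1.0 and c.auc2 == 0.0
        assert c.p < 0.01

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        labels = np.array([0, 1] * 15)
        s1 = labels + rng.normal(0, 0.8, 30)
        s2 = labels + rng.normal(0, 2.0, 30)
        a = cp.compare_aucs(s1, s2, labels, n_bootstrap=400, seed=7)
        b = cp.compare_aucs(s2, s1, labels, n_bootstrap=400, seed=7)
        assert a.z == pytest.approx(-b.z, rel=0.2)
        assert np.sign(a.z) == np.sign(a.auc1 - a.auc2)

    def test_null_pvalues_uniform(self):
        """Two equally uninformative scorers: comparison p is ~Uniform(0,1)."""
        rng = np.random.default_rng(11)
        pvals = []
        labels = np.array([0, 1] * 20)
        for _ in range(100):
            s1 = rng.normal(size=40)
            s2 = rng.normal(size=40)
            pvals.append(
                cp.compare_aucs(s1, s2, labels, n_bootstrap=200,
                                seed=int(rng.integers(2**31))).p
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_subjects_errors(self):
        with pytest.raises(ValueError):
            cp.compare_aucs([1, 0, 1], [0, 1, 0], [1, 0, 1])


class TestRFRegress:
    def test_noiseless_signal_high_r2(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.uniform(-2, 2, 200)})
        y = pd.Series(3.0 * X["x"].to_numpy())
        ev = cp.rf_regress(X, y, n_trees=300, seed=1)
        assert ev.adjusted_r_squared >= 0.9
        assert ev.p_value < 1e-6

    def test_null_target_low_r2(self):
        adj = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
            y = pd.Series(rng.normal(size=200))
            ev = cp.rf_regress(X, y, n_trees=100, seed=seed)
            adj.append(ev.adjusted_r_squared)
        assert np.median(adj) <= 0.1

    def test_adjustment_identity_and_bound(self):
        # R^2 = 1 is a fixed point of the adjustment for any valid n, p
        for n, p in [(30, 5), (100, 10)]:
            assert 1 - (1 - 1.0) * (n - 1) / (n - p - 1) == 1.0
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("wxyz"))
        y = pd.Series(X["w"] + rng.normal(0, 0.5, 80))
        ev = cp.rf_regress(X, y, n_trees=200, seed=0)
        assert ev.adjusted_r_squared <= ev.r_squared

    def test_importance_identifies_signal(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(150, 4)), columns=list("wxyz"))
        y = pd.Series(2.0 * X["w"] + rng.normal(0, 0.3, 150))
        ev = cp.rf_regress(X, y, n_trees=200, seed=3)
        assert max(ev.importances, key=ev.importances.get) == "w"
        assert ev.importances["w"] > 0

    def test_degrees_of_freedom_guard(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(5, 5)), columns=list("abcde"))
        with pytest.raises(ValueError, match="n - p - 1"):
            cp.rf_regress(X, pd.Series(rng.normal(size=5)))

    def test_constant_target_errors(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=list("ab"))
        with pytest.raises(ValueError, match="constant"):
            cp.rf_regress(X, pd.Series(np.ones(30)))
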