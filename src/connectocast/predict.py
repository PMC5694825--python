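"""Nested RFE random-forest prediction of impairment, and model comparison.

The predictive scheme, end to end:

1. Assemble a feature matrix for one of three model specifications —
   Model 1: six patient/medical covariates (age, education, stage, minority
   status, menopausal status, CAD total); Model 2: the covariates plus the
   clustering coefficients of three a-priori regions; Model 3: the
   covariates plus clustering coefficients for all regions.
2. Split patients 75/25 with stratified class sampling; the 25% hold-out is
   untouched until final evaluation.
3. Recursive feature elimination on the training set: across 100 seeded
   random A/B partitions of the training set, rank features with a forest
   fit on A, score candidate subset sizes by predicting each held-out B
   member, and keep the size with the best mean accuracy (ties toward fewer
   features).
4. Re-train a 500-tree forest (sqrt-mtry) on the full training set with
   out-of-bag error estimation, evaluate on the hold-out: accuracy,
   sensitivity, specificity, ROC AUC from forest vote fractions, and a
   two-sided exact binomial test against chance 0.5.
5. Compare competing models' AUCs with a paired bootstrap over hold-out
   subjects (Hanley–McNeil style z on the bootstrap SD of the AUC
   difference), and supplement classification with regression forests
   predicting individual follow-up z-scores (OOB R-squared, adjusted,
   with percent-increase-in-MSE permutation importances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score

__all__ = [
    "MODEL1_COVARIATES",
    "MODEL2_REGIONS",
    "FeatureMatrix",
    "SplitScheme",
    "RFEResult",
    "ModelEvaluation",
    "AUCComparison",
    "RegressionEvaluation",
    "assemble_features",
    "stratified_split",
    "rfe_select",
    "train_forest",
    "evaluate_holdout",
    "exact_binomial_test",
    "compare_aucs",
    "rf_regress",
]

MODEL1_COVARIATES = ("age", "education", "stage", "minority", "menopause", "cad")

#: A-priori regions whose clustering enters Model 2 (previously reported to
#: show subtly altered clustering pre-treatment).
MODEL2_REGIONS = (
    "right middle orbitofrontal",
    "right inferior parietal",
    "right mesial superior frontal",
)

CLUSTERING_PREFIX = "clust_"


@dataclass(frozen=True)
class FeatureMatrix:
    features: pd.DataFrame  # rows = patients (indexed by subject_id)
    outcome: pd.Series  # binary, 1 = impaired

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.features.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)


@dataclass(frozen=True)
class SplitScheme:
    train_ids: list
    test_ids: list
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass(frozen=True)
class RFEResult:
    selected_features: list[str]
    sizes: list[int]
    mean_accuracy: dict[int, float]  # subset size -> mean accuracy over partitions
    per_partition_accuracy: dict[int, list[float]]


@dataclass(frozen=True)
class ModelEvaluation:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None
    binomial_p: float
    oob_error: float
    importances: dict[str, float]
    n_test: int
    scores: np.ndarray = field(repr=False)  # vote fraction per test subject
    labels: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class AUCComparison:
    auc1: float
    auc2: float
    z: float
    p: float
    n_bootstrap: int


@dataclass(frozen=True)
class RegressionEvaluation:
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    importances: dict[str, float]  # percent increase in OOB MSE
    n: int
    n_features: int


def assemble_features(
    clustering: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: pd.Series,
    model: int,
    model2_regions: tuple[str, ...] = MODEL2_REGIONS,
) -> FeatureMatrix:
    """Build the feature matrix for model 1, 2 or 3.

    ``clustering`` is wide — one row per patient (indexed by subject_id),
    one column per region label holding that region's baseline clustering
    coefficient. ``covariates`` carries the six patient/medical columns.
    Stage is kept ordinal; binary covariates are 0/1.
    """
    cov = covariates.set_index("subject_id")[list(MODEL1_COVARIATES)].astype(float)
    if model == 1:
        feats = cov
    elif model in (2, 3):
        wanted = list(model2_regions) if model == 2 else list(clustering.columns)
        missing = [r for r in wanted if r not in clustering.columns]
        if missing:
            raise KeyError(f"regions absent from metric table: {missing}")
        clust = clustering[wanted].astype(float)
        clust.columns = [CLUSTERING_PREFIX + c for c in clust.columns]
        feats = cov.join(clust, how="inner")
    else:
        raise ValueError(f"unknown model spec: {model}")
    feats = feats.loc[outcome.index]
    return FeatureMatrix(features=feats, outcome=outcome.astype(int))


def _round_half_random(x: float, rng: np.random.Generator) -> int:
    """Round to nearest; an exact .5 fraction is resolved by a fair coin."""
    lower = int(np.floor(x))
    frac = x - lower
    if abs(frac - 0.5) < 1e-12:
        return lower + int(rng.random() < 0.5)
    return lower + int(frac > 0.5)


def stratified_split(
    outcome: pd.Series, fraction: float = 0.75, seed: int = 0
) -> SplitScheme:
    """75/25 stratified class split with probabilistic rounding.

    Per class, the test count is ``(1 - fraction) * n_class`` rounded to the
    nearest integer, exact halves resolved by a seeded coin flip; the
    remainder trains.
    """
    rng = np.random.default_rng(seed)
    classes = outcome.unique()
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present to split")
    test_ids: list = []
    train_ids: list = []
    for cls in sorted(classes):
        ids = outcome.index[outcome == cls].to_numpy()
        n_test = _round_half_random((1.0 - fraction) * len(ids), rng)
        n_test = min(max(n_test, 0), len(ids))
        perm = rng.permutation(ids)
        test_ids.extend(perm[:n_test].tolist())
        train_ids.extend(perm[n_test:].tolist())
    return SplitScheme(train_ids=sorted(train_ids), test_ids=sorted(test_ids), seed=seed)


def _make_forest(n_trees: int, mtry, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry if mtry is not None else "sqrt",
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )


def _size_ladder(p: int) -> list[int]:
    """Candidate subset sizes: exhaustive countdown for small p, geometric
    halving for large p (tractability on ~100-feature models)."""
    if p <= 20:
        return list(range(p, 0, -1))
    sizes = []
    s = p
    while s > 1:
        sizes.append(s)
        s = (s + 1) // 2
    sizes.append(1)
    return sizes


def rfe_select(
    X: pd.DataFrame,
    y: pd.Series,
    n_partitions: int = 100,
    seed: int = 0,
    inner_fraction: float = 0.75,
    n_trees_inner: int = 15,
    n_trees_rank: int = 30,
    n_trees_final: int = 500,
) -> RFEResult:
    """Recursive feature elimination over random partitions of the training set.

    Each partition splits the training set into A (ranking/fitting) and B
    (scoring); a forest fit on A ranks features by Gini importance, and each
    candidate subset size is scored by predicting every B member from a
    forest fit on A restricted to the top-ranked features of that size. The
    size with the best mean accuracy across partitions wins (ties toward
    fewer features); the final feature set is the top of a ranking refit on
    the whole training set.
    """
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    p = X.shape[1]
    if p < 1:
        raise ValueError("need at least one feature")
    sizes = _size_ladder(p)
    ss = np.random.SeedSequence(seed)
    part_seeds = ss.generate_state(2 * n_partitions + 1) % (2**31)
    acc: dict[int, list[float]] = {s: [] for s in sizes}
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=int)

    for part in range(n_partitions):
        split = stratified_split(y, fraction=inner_fraction, seed=int(part_seeds[part]))
        a_idx = [X.index.get_loc(i) for i in split.train_ids]
        b_idx = [X.index.get_loc(i) for i in split.test_ids]
        if len(b_idx) == 0 or len(set(yv[a_idx])) < 2:
            continue
        forest_seed = int(part_seeds[n_partitions + part])
        ranker = _make_forest(n_trees_rank, None, forest_seed)
        ranker.fit(Xv[a_idx], yv[a_idx])
        order = np.argsort(-ranker.feature_importances_, kind="stable")
        for s in sizes:
            cols = order[:s]
            clf = _make_forest(n_trees_inner, None, forest_seed)
            clf.fit(Xv[np.ix_(a_idx, cols)], yv[a_idx])
            pred = clf.predict(Xv[np.ix_(b_idx, cols)])
            acc[s].append(float(np.mean(pred == yv[b_idx])))

    mean_acc = {s: (float(np.mean(v)) if v else float("nan")) for s, v in acc.items()}
    best = max(mean_acc, key=lambda s: (mean_acc[s], -s))
    final_ranker = _make_forest(n_trees_final, None, int(part_seeds[-1]))
    final_ranker.fit(Xv, yv)
    order = np.argsort(-final_ranker.feature_importances_, kind="stable")
    selected = [X.columns[i] for i in order[:best]]
    return RFEResult(
        selected_features=selected,
        sizes=sizes,
        mean_accuracy=mean_acc,
        per_partition_accuracy=acc,
    )


def train_forest(
    X: pd.DataFrame,
    y: pd.Series,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
):
    """Fit the 500-tree classification forest with OOB error estimation.

    Returns (fitted forest, oob_error, Gini importances by feature). mtry
    defaults to floor(sqrt(p)) features tried per split; each tree sees a
    bootstrap sample of the subjects.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; cannot train a classifier")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry if mtry is not None else "sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(X.to_numpy(dtype=float), y.to_numpy(dtype=int))
    oob_error = 1.0 - float(clf.oob_score_)
    importances = dict(zip(X.columns, clf.feature_importances_.astype(float)))
    return clf, oob_error, importances


def exact_binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p (minimum-likelihood convention)."""
    if n < 1:
        raise ValueError("need at least one trial")
    if not 0 <= k <= n:
        raise ValueError("successes must lie in [0, n]")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def evaluate_holdout(
    model: RandomForestClassifier,
    X_test: pd.DataFrame,
    y_test: pd.Series,
    oob_error: float = float("nan"),
    importances: dict[str, float] | None = None,
) -> ModelEvaluation:
    """Score the held-out patients: accuracy, sens/spec, AUC, binomial p.

    The ROC score for each subject is the forest's vote fraction for the
    impaired class; AUC uses the midrank tie convention. The binomial test
    compares the correct count with chance 0.5. A single-class test set
    leaves AUC undefined (None).
    """
    Xv = X_test.to_numpy(dtype=float)
    yv = y_test.to_numpy(dtype=int)
    pred = model.predict(Xv)
    scores = model.predict_proba(Xv)[:, list(model.classes_).index(1)]
    n = len(yv)
    correct = int(np.sum(pred == yv))
    accuracy = correct / n
    pos, neg = yv == 1, yv == 0
    sensitivity = float(np.mean(pred[pos] == 1)) if pos.any() else float("nan")
    specificity = float(np.mean(pred[neg] == 0)) if neg.any() else float("nan")
    if pos.any() and neg.any():
        auc = float(roc_auc_score(yv, scores))
    else:
        import warnings

        warnings.warn("single-class test set: AUC undefined", stacklevel=2)
        auc = None
    return ModelEvaluation(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        binomial_p=exact_binomial_test(correct, n, 0.5),
        oob_error=oob_error,
        importances=importances or {},
        n_test=n,
        scores=scores,
        labels=yv,
    )


def compare_aucs(
    scores1: np.ndarray,
    scores2: np.ndarray,
    labels: np.ndarray,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> AUCComparison:
    """Paired bootstrap comparison of two models' AUCs on shared subjects.

    Subjects are resampled with replacement within each class (keeping both
    classes represented and the pairing between models); z is the observed
    AUC difference over the bootstrap SD of the difference, with a two-sided
    normal p.
    """
    scores1 = np.asarray(scores1, float)
    scores2 = np.asarray(scores2, float)
    labels = np.asarray(labels, int)
    if not (len(scores1) == len(scores2) == len(labels)):
        raise ValueError("score vectors and labels must share subjects")
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 subjects per class")
    auc1 = float(roc_auc_score(labels, scores1))
    auc2 = float(roc_auc_score(labels, scores2))
    delta = auc1 - auc2
    rng = np.random.default_rng(seed)
    n1, n0 = len(pos), len(neg)
    # Vectorized replicates: midrank (Mann-Whitney) AUC per bootstrap row.
    pos_idx = rng.choice(pos, size=(n_bootstrap, n1))
    neg_idx = rng.choice(neg, size=(n_bootstrap, n0))
    idx = np.concatenate([pos_idx, neg_idx], axis=1)

    def auc_rows(scores: np.ndarray) -> np.ndarray:
        ranks = stats.rankdata(scores[idx], axis=1)
        rank_sum_pos = ranks[:, :n1].sum(axis=1)
        return (rank_sum_pos - n1 * (n1 + 1) / 2) / (n1 * n0)

    deltas = auc_rows(scores1) - auc_rows(scores2)
    sd = float(deltas.std(ddof=1))
    if sd == 0.0:
        z = 0.0 if delta == 0.0 else float(np.sign(delta)) * float("inf")
    else:
        z = delta / sd
    p = 1.0 if z == 0.0 else float(2.0 * stats.norm.sf(abs(z)))
    return AUCComparison(auc1=auc1, auc2=auc2, z=float(z), p=min(p, 1.0),
                         n_bootstrap=n_bootstrap)


def _oob_indices_per_tree(forest, n_samples: int):
    """Out-of-bag sample indices for every tree of a fitted forest."""
    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples)
    return [
        _generate_unsampled_indices(tree.random_state, n_samples, n_boot)
        for tree in forest.estimators_
    ]


def _percent_increase_mse(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
) -> np.ndarray:
    """%IncMSE: OOB permutation importance per feature.

    For each tree, the OOB MSE is recomputed after permuting one feature
    within the tree's OOB sample; the importance is the percent increase of
    the mean permuted MSE over the mean baseline MSE.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    try:
        oob_sets = _oob_indices_per_tree(forest, n)
    except Exception:  # private helper moved: fall back to whole-sample OOB proxy
        oob_sets = [np.arange(n)] * len(forest.estimators_)
    base = np.zeros(len(forest.estimators_))
    perm = np.zeros((len(forest.estimators_), p))
    for t, (tree, oob) in enumerate(zip(forest.estimators_, oob_sets)):
        if len(oob) == 0:
            continue
        Xo = X[oob]
        resid = tree.predict(Xo) - y[oob]
        base[t] = np.mean(resid**2)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm[t, j] = np.mean((tree.predict(Xp) - y[oob]) ** 2)
    mean_base = base.mean()
    if mean_base <= 0:
        return np.zeros(p)
    return 100.0 * (perm.mean(axis=0) - mean_base) / mean_base


def rf_regress(
    X: pd.DataFrame,
    y: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> RegressionEvaluation:
    """Regression forest for one cognitive test's follow-up z-scores.

    R-squared comes from out-of-bag predictions; the adjusted value is
    ``1 - (1 - R2)(n - 1)/(n - p - 1)``, with a p-value from the implied F
    statistic. Importances are percent increase in OOB MSE under
    per-feature permutation.
    """
    n, p = X.shape
    if n - p - 1 <= 0:
        raise ValueError("adjusted R-squared undefined: need n - p - 1 > 0")
    yv = y.to_numpy(dtype=float)
    if np.allclose(yv, yv[0]):
        raise ValueError("target is constant")
    # mtry = p/3 (regression-forest default of the cited implementation
    # lineage); classification uses sqrt(p).
    reg = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, p // 3) if p > 1 else 1.0,
        bootstrap=True,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    Xv = X.to_numpy(dtype=float)
    reg.fit(Xv, yv)
    r2 = float(reg.oob_score_)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    if r2 >= 1.0:
        p_value = 0.0
    elif r2 <= 0.0:
        p_value = 1.0
    else:
        f_stat = (r2 / p) / ((1.0 - r2) / (n - p - 1))
        p_value = float(stats.f.sf(f_stat, p, n - p - 1))
    inc = _percent_increase_mse(reg, Xv, yv, seed=seed)
    return RegressionEvaluation(
        r_squared=r2,
        adjusted_r_squared=float(adj),
        p_value=p_value,
        importances=dict(zip(X.columns, inc.astype(float))),
        n=n,
        n_features=p,
    )
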