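"""Interpretable risk modeling for grade >= 2 radiation pneumonitis.

Workflow: a random forest is trained per stratified cross-validation fold
and Gini-impurity-reduction importances are averaged over folds to rank
predictors; a decision tree restricted to the top-ranked features is grown
greedily by Gini gain and cost-complexity pruned, with the penalty chosen by
cross-validated accuracy under the one-standard-error rule; the pruned tree
is evaluated by pooled cross-validated predictions (default) or a held-out
split, reporting accuracy, F1 (positive class = the pneumonitis event),
AUROC from leaf event-probabilities, the confusion matrix at a 0.5
probability cut, and a one-sided exact binomial test of accuracy against the
no-information rate (NIR, the majority-class frequency).

Delta (post-minus-pre) biomarkers are accepted as predictors alongside
pre-treatment values; because they require the follow-up scan they describe
early post-treatment risk stratification, not purely pre-treatment
prediction -- a caveat the caller owns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier, export_text

from fractolung.errors import ConfigurationError, DegenerateLabelsError
from fractolung.stats import compare_pre_post

DEFAULT_FEATURES = (
    "age", "sex", "smoking", "lung_disease",
    "mld_cgy", "v5_pct", "v10_pct", "v20_pct",
    "boxfd_pre", "lacunarity_pre", "mstfd_pre",
    "d_boxfd", "d_lacunarity", "d_mstfd",
)


def _check_labels(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError(
            "outcome has a single class; ranking/evaluation undefined"
        )


def _validate_features(
    table: pd.DataFrame, feature_cols: tuple[str, ...]
) -> pd.DataFrame:
    missing = [c for c in feature_cols if c not in table.columns]
    if missing:
        raise ConfigurationError(f"missing feature columns: {missing}")
    X = table[list(feature_cols)]
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ConfigurationError(
            f"missing values in feature columns {bad}; imputation is not "
            "performed -- complete the table upstream"
        )
    return X


@dataclass
class ImportanceRanking:
    """Descending (feature, mean Gini importance) pairs with CV dispersion."""

    features: tuple[str, ...]
    mean_importance: np.ndarray
    std_importance: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(-self.mean_importance, kind="stable")
        self.features = tuple(self.features[i] for i in order)
        self.mean_importance = np.asarray(self.mean_importance)[order]
        self.std_importance = np.asarray(self.std_importance)[order]
        assert np.all(self.mean_importance >= 0)

    def top(self, k: int = 3) -> tuple[str, ...]:
        return self.features[:k]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.features,
            "mean_importance": self.mean_importance,
            "std_importance": self.std_importance,
        })


def rank_features(
    table: pd.DataFrame,
    feature_cols: tuple[str, ...] = DEFAULT_FEATURES,
    label_col: str = "label",
    seed: int = 0,
    n_folds: int = 5,
    n_trees: int = 500,
) -> ImportanceRanking:
    """Random-forest Gini-importance ranking averaged over CV folds.

    One forest is trained on each stratified training fold; per-feature
    importances are averaged (mean) and their fold-to-fold dispersion (std)
    retained.  Deterministic for a fixed seed.
    """
    if len(table) < 20:
        raise ConfigurationError(f"need >= 20 rows for ranking, have {len(table)}")
    X = _validate_features(table, tuple(feature_cols)).to_numpy(float)
    y = table[label_col].to_numpy()
    _check_labels(y)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(n_folds + 1)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(fold_seeds[0]) % (2**32))
    imps = []
    for i, (tr, _te) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt",
            random_state=int(fold_seeds[i + 1]) % (2**32),
        )
        rf.fit(X[tr], y[tr])
        imps.append(rf.feature_importances_)
    imps = np.vstack(imps)
    return ImportanceRanking(
        features=tuple(feature_cols),
        mean_importance=imps.mean(axis=0),
        std_importance=imps.std(axis=0),
    )


@dataclass
class FittedTree:
    """A Gini-grown, cost-complexity-pruned decision tree.

    ``removed_features`` lists features that split the unpruned tree but no
    longer appear after pruning (the pruning trace); ``thresholds`` maps each
    surviving split feature to its cut points.
    """

    estimator: DecisionTreeClassifier
    features: tuple[str, ...]
    ccp_alpha: float
    cv_table: pd.DataFrame  # alpha, mean CV accuracy, std
    removed_features: tuple[str, ...]

    @property
    def thresholds(self) -> dict[str, list[float]]:
        t = self.estimator.tree_
        out: dict[str, list[float]] = {}
        for node in range(t.node_count):
            f = t.feature[node]
            if f >= 0:  # internal node
                out.setdefault(self.features[f], []).append(float(t.threshold[node]))
        return out

    def predict_proba_event(self, table: pd.DataFrame) -> np.ndarray:
        X = _validate_features(table, self.features).to_numpy(float)
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        if True in classes:
            return proba[:, classes.index(True)]
        return np.zeros(len(X))  # single-leaf, all-negative tree

    def to_text(self) -> str:
        return export_text(self.estimator, feature_names=list(self.features))


def _split_features(est: DecisionTreeClassifier,
                    features: tuple[str, ...]) -> set[str]:
    t = est.tree_
    return {features[t.feature[n]] for n in range(t.node_count) if t.feature[n] >= 0}


def fit_pruned_tree(
    table: pd.DataFrame,
    selected_features: tuple[str, ...],
    label_col: str = "label",
    seed: int = 0,
    n_folds: int = 5,
) -> FittedTree:
    """Grow a Gini decision tree on the selected features and prune it.

    Cost-complexity pruning: the candidate alphas come from the full tree's
    pruning path; each candidate's accuracy is cross-validated and the
    LARGEST alpha whose mean accuracy is within one standard error of the
    best is chosen (one-SE rule), trading a little accuracy for a simpler,
    less overfit tree.  A dataset with no valid split yields a single-leaf
    majority-class tree.
    """
    if not selected_features:
        raise ConfigurationError("selected_features must be non-empty")
    X = _validate_features(table, tuple(selected_features)).to_numpy(float)
    y = table[label_col].to_numpy()
    base = DecisionTreeClassifier(criterion="gini", random_state=seed % (2**32))
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    single_class = len(np.unique(y)) < 2
    if single_class or len(alphas) == 1:
        est = clone(base).fit(X, y)
        return FittedTree(
            estimator=est, features=tuple(selected_features), ccp_alpha=0.0,
            cv_table=pd.DataFrame({"alpha": [0.0], "mean_acc": [np.nan],
                                   "std_acc": [np.nan]}),
            removed_features=(),
        )
    # every fold needs at least one member of each class
    n_splits = int(max(2, min(n_folds, np.bincount(pd.factorize(y)[0]).min())))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=seed % (2**32))
    folds = list(skf.split(X, y))
    means, stds = [], []
    for a in alphas:
        accs = []
        for tr, te in folds:
            est = DecisionTreeClassifier(criterion="gini", ccp_alpha=float(a),
                                         random_state=seed % (2**32))
            est.fit(X[tr], y[tr])
            accs.append(float((est.predict(X[te]) == y[te]).mean()))
        means.append(float(np.mean(accs)))
        stds.append(float(np.std(accs, ddof=1)))
    means_arr = np.asarray(means)
    best = int(np.argmax(means_arr))
    se = stds[best] / np.sqrt(len(folds))
    ok = means_arr >= means_arr[best] - se
    chosen_alpha = float(alphas[np.max(np.nonzero(ok))])
    unpruned = DecisionTreeClassifier(criterion="gini",
                                      random_state=seed % (2**32)).fit(X, y)
    pruned = DecisionTreeClassifier(criterion="gini", ccp_alpha=chosen_alpha,
                                    random_state=seed % (2**32)).fit(X, y)
    removed = tuple(sorted(
        _split_features(unpruned, tuple(selected_features))
        - _split_features(pruned, tuple(selected_features))
    ))
    return FittedTree(
        estimator=pruned, features=tuple(selected_features),
        ccp_alpha=chosen_alpha,
        cv_table=pd.DataFrame({"alpha": alphas, "mean_acc": means,
                               "std_acc": stds}),
        removed_features=removed,
    )


@dataclass
class ModelReport:
    """Evaluation metrics for a fitted tree."""

    scheme: str
    n: int
    accuracy: float
    f1: float
    auroc: float | None
    confusion: np.ndarray  # rows = actual (neg, pos), cols = predicted
    nir: float
    nir_p: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "scheme": self.scheme, "n": self.n,
            "accuracy": self.accuracy, "f1": self.f1, "auroc": self.auroc,
            "confusion": np.asarray(self.confusion).tolist(),
            "nir": self.nir, "nir_p": self.nir_p,
            "flags": list(self.flags),
        }


def nir_binomial_p(n_correct: int, n: int, nir: float) -> float:
    """One-sided exact binomial tail P(X >= n_correct | p = NIR)."""
    return float(binomtest(n_correct, n, nir, alternative="greater").pvalue)


def _report_from_predictions(
    y: np.ndarray, probs: np.ndarray, scheme: str
) -> ModelReport:
    y = np.asarray(y, dtype=bool)
    preds = probs >= 0.5
    n = len(y)
    acc = float((preds == y).mean())
    f1 = float(f1_score(y, preds, zero_division=0))
    flags = []
    if len(np.unique(y)) < 2:
        auroc = None
        flags.append("auroc undefined: one class absent")
    else:
        auroc = float(roc_auc_score(y, probs))
    confusion = np.array([
        [int((~y & ~preds).sum()), int((~y & preds).sum())],
        [int((y & ~preds).sum()), int((y & preds).sum())],
    ])
    nir = float(max(y.mean(), 1 - y.mean()))
    p = nir_binomial_p(int((preds == y).sum()), n, nir)
    return ModelReport(scheme=scheme, n=n, accuracy=acc, f1=f1, auroc=auroc,
                       confusion=confusion, nir=nir, nir_p=p,
                       flags=tuple(flags))


def evaluate_model(
    tree: FittedTree,
    table: pd.DataFrame,
    scheme: str = "cv_pooled",
    label_col: str = "label",
    seed: int = 0,
    n_folds: int = 5,
    test_size: float = 0.25,
) -> ModelReport:
    """Evaluate a fitted tree's hyper-parameters on a cohort.

    'cv_pooled' (default) refits a tree with identical parameters on each
    stratified training fold and pools the out-of-fold leaf probabilities, so
    every patient is scored exactly once out-of-sample.  'holdout' uses a
    single stratified train/test split.  AUROC uses the rank statistic with
    tie correction on leaf event-probabilities; the confusion matrix cuts at
    probability 0.5; NIR p is the exact one-sided binomial tail.
    """
    X = _validate_features(table, tree.features).to_numpy(float)
    y = table[label_col].to_numpy(dtype=bool)
    _check_labels(y)
    if scheme == "cv_pooled":
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed % (2**32))
        probs = np.zeros(len(y))
        for tr, te in skf.split(X, y):
            est = clone(tree.estimator)
            est.fit(X[tr], y[tr])
            proba = est.predict_proba(X[te])
            classes = list(est.classes_)
            probs[te] = (proba[:, classes.index(True)]
                         if True in classes else 0.0)
        return _report_from_predictions(y, probs, scheme)
    if scheme == "holdout":
        idx_tr, idx_te = train_test_split(
            np.arange(len(y)), test_size=test_size, stratify=y,
            random_state=seed % (2**32),
        )
        est = clone(tree.estimator)
        est.fit(X[idx_tr], y[idx_tr])
        proba = est.predict_proba(X[idx_te])
        classes = list(est.classes_)
        probs = proba[:, classes.index(True)] if True in classes else np.zeros(
            len(idx_te))
        return _report_from_predictions(y[idx_te], probs, scheme)
    raise ConfigurationError(
        f"unknown evaluation scheme {scheme!r}; use 'cv_pooled' or 'holdout'"
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Settings for the end-to-end risk-modeling pipeline.

    A seed is mandatory: every stochastic stage (forest, fold shuffling,
    splits) derives its stream from it, making repeated runs byte-identical.
    """

    seed: int | None = None
    feature_cols: tuple[str, ...] = DEFAULT_FEATURES
    label_col: str = "label"
    group_col: str | None = None
    top_k: int = 3
    n_trees: int = 500
    n_folds: int = 5
    scheme: str = "cv_pooled"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory in the pipeline config")


@dataclass
class GroupResult:
    ranking: ImportanceRanking
    tree: FittedTree
    report: ModelReport
    prepost: pd.DataFrame | None


@dataclass
class PipelineResult:
    groups: dict[str, GroupResult] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {}
        for g, res in self.groups.items():
            payload[g] = {
                "ranking": res.ranking.as_frame().to_dict(orient="records"),
                "selected_features": list(res.tree.features),
                "ccp_alpha": res.tree.ccp_alpha,
                "removed_features": list(res.tree.removed_features),
                "tree": res.tree.to_text(),
                "report": res.report.as_dict(),
                "prepost": (res.prepost.to_dict(orient="records")
                            if res.prepost is not None else None),
            }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_pipeline(cohort: pd.DataFrame, config: PipelineConfig) -> PipelineResult:
    """Rank features, fit and prune a top-k tree, and evaluate -- per group.

    When ``config.group_col`` names a column, each group (e.g. RT-alone-like
    vs CCRT-like) is modeled separately.  A paired pre/post comparison report
    is attached when the cohort carries pre and post biomarker columns.
    Artifacts (importances CSV, tree text, report JSON, confusion CSV) are
    written under ``config.out_dir`` when set.
    """
    ss = np.random.SeedSequence(config.seed)
    rank_seed, tree_seed, eval_seed = (int(s) % (2**31) for s in
                                       ss.generate_state(3))
    groups = (
        [(str(g), sub.reset_index(drop=True))
         for g, sub in cohort.groupby(config.group_col)]
        if config.group_col else [("all", cohort)]
    )
    result = PipelineResult()
    for gname, sub in groups:
        try:
            ranking = rank_features(
                sub, config.feature_cols, config.label_col,
                seed=rank_seed, n_folds=config.n_folds, n_trees=config.n_trees,
            )
            selected = ranking.top(config.top_k)
            tree = fit_pruned_tree(sub, selected, config.label_col,
                                   seed=tree_seed, n_folds=config.n_folds)
            report = evaluate_model(tree, sub, scheme=config.scheme,
                                    label_col=config.label_col,
                                    seed=eval_seed, n_folds=config.n_folds)
        except Exception as exc:
            raise type(exc)(f"[group {gname}] {exc}") from exc
        has_prepost = all(
            c in sub.columns
            for pair in (("boxfd_pre", "boxfd_post"),
                         ("lacunarity_pre", "lacunarity_post"),
                         ("mstfd_pre", "mstfd_post"))
            for c in pair
        )
        prepost = compare_pre_post(sub) if has_prepost else None
        result.groups[gname] = GroupResult(ranking, tree, report, prepost)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "pipeline_report.json").write_text(result.to_json())
        for gname, res in result.groups.items():
            res.ranking.as_frame().to_csv(out / f"{gname}_importances.csv",
                                          index=False)
            (out / f"{gname}_tree.txt").write_text(res.tree.to_text())
            pd.DataFrame(
                res.report.confusion,
                index=["actual_neg", "actual_pos"],
                columns=["pred_neg", "pred_pos"],
            ).to_csv(out / f"{gname}_confusion.csv")
    return result
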