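"""Nested-CV classification harness with Shapley-driven feature elimination.

The evaluation protocol is stratified nested 10-fold cross-validation.  For
each outer fold, the inner stratified 10-fold loop on the outer-train data
drives (a) recursive feature elimination — starting from the full feature
set, the two least important features by mean |Shapley value| are removed
per iteration until six features remain, and the subset with the best
inner-CV accuracy wins — and (b) randomized hyperparameter search for the
gradient-boosted-tree family on the selected subset.  The ten fold models
(each with its own feature subset and parameters) are combined by soft
voting into the final ensemble.

Three classifier families are supported: a linear-kernel SVM and logistic
regression at default parameters, and gradient-boosted decision trees with
four tuned hyperparameters (bagging temperature, tree depth, L2 leaf
regularization, random strength).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler, label_binarize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import cross_val_predict
from sklearn.svm import SVC

from . import aggregate as agg
from .shapley import linear_shap, mean_abs_importance

FAMILIES = ("svm_linear", "logreg", "gradient_boosted_trees")

#: randomized-search ranges for the tree family
TREE_PARAM_RANGES = {
    "tree_depth": (4, 10),                 # integer, inclusive
    "l2_leaf_regularization": (1.0, 10.0),  # log-uniform
    "bagging_temperature": (0.0, 1.0),     # uniform
    "random_strength": (0.0, 10.0),        # uniform
}


def _lgbm_class():
    """LGBMClassifier variant that presents stable column names to the
    booster, so array/frame input mixes never trip sklearn's
    feature-name consistency check."""
    global _LGBM
    if _LGBM is None:
        from lightgbm import LGBMClassifier

        class _NamedLGBM(LGBMClassifier):
            @staticmethod
            def _named(X):
                X = np.asarray(X)
                return pd.DataFrame(X, columns=[f"c{i}" for i in range(X.shape[1])])

            def fit(self, X, y, **kw):
                return super().fit(self._named(X), y, **kw)

            def predict(self, X, **kw):
                return super().predict(self._named(X), **kw)

            def predict_proba(self, X, **kw):
                return super().predict_proba(self._named(X), **kw)

        _LGBM = _NamedLGBM
    return _LGBM


_LGBM = None


class CalibratedLinearSVC(BaseEstimator, ClassifierMixin):
    """Linear-kernel SVM (default parameters) with sigmoid probability
    calibration fitted on cross-validated decision scores, so that the
    classifier can take part in soft voting.  Class decisions are the
    SVM's own; only the probabilities come from the calibrator."""

    def __init__(self, random_state: int = 0, cv: int = 5):
        self.random_state = random_state
        self.cv = cv

    def fit(self, X, y):
        y = np.asarray(y)
        self.svc_ = SVC(kernel="linear", decision_function_shape="ovr")
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        n_splits = min(self.cv, int(np.bincount(pd.factorize(y)[0]).min()))
        if n_splits >= 2:
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                 random_state=self.random_state)
            scores = cross_val_predict(SVC(kernel="linear",
                                           decision_function_shape="ovr"),
                                       X, y, cv=cv,
                                       method="decision_function")
        else:
            scores = self.svc_.decision_function(X)
        self.calibrator_ = LogisticRegression(max_iter=500)
        self.calibrator_.fit(np.atleast_2d(scores.T).T.reshape(len(y), -1), y)
        return self

    @property
    def coef_(self):
        return self.svc_.coef_

    def decision_function(self, X):
        return self.svc_.decision_function(X)

    def predict(self, X):
        return self.svc_.predict(X)

    def predict_proba(self, X):
        s = self.svc_.decision_function(X)
        return self.calibrator_.predict_proba(
            np.atleast_2d(s.T).T.reshape(np.asarray(X).shape[0], -1))


@dataclass
class ModelSpec:
    family: str = "logreg"
    tunable: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family != "gradient_boosted_trees" and self.tunable:
            raise ValueError(f"{self.family} carries no tuned parameters")


def make_estimator(spec: ModelSpec, params: dict | None = None,
                   calibrated: bool = True) -> Pipeline:
    """Imputation + standardization + classifier pipeline for one family.

    The tree family maps the four named hyperparameters onto LightGBM:
    tree_depth -> max_depth, l2_leaf_regularization -> reg_lambda,
    bagging temperature t -> row subsampling 1 - t/2, random strength r ->
    per-tree feature subsampling 1 / (1 + 0.05 r).

    ``calibrated=False`` skips the SVM's probability calibration (class
    predictions are unchanged); used inside accuracy-only CV loops.
    """
    params = params or {}
    if spec.family == "svm_linear":
        if calibrated:
            clf = CalibratedLinearSVC(random_state=spec.seed)
        else:
            clf = SVC(kernel="linear", decision_function_shape="ovr")
    elif spec.family == "logreg":
        clf = LogisticRegression(max_iter=500)
    else:
        depth = int(params.get("tree_depth", 6))
        t = float(params.get("bagging_temperature", 0.0))
        r = float(params.get("random_strength", 0.0))
        clf = _lgbm_class()(
            n_estimators=100,
            max_depth=depth,
            num_leaves=min(2 ** depth, 31),
            reg_lambda=float(params.get("l2_leaf_regularization", 3.0)),
            subsample=1.0 - 0.5 * t,
            subsample_freq=1 if t > 0 else 0,
            colsample_bytree=1.0 / (1.0 + 0.05 * r),
            min_child_samples=5,
            random_state=spec.seed,
            deterministic=True,
            n_jobs=1,
            verbose=-1,
        )
    return Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
        ("clf", clf),
    ])


# ---------------------------------------------------------------------------
# Shapley importance
# ---------------------------------------------------------------------------

def shap_importance(model: Pipeline, X: pd.DataFrame | np.ndarray,
                    background: pd.DataFrame | np.ndarray | None = None,
                    max_eval: int = 64) -> np.ndarray:
    """Per-feature importance of a fitted pipeline: mean |Shapley value| of
    the classifier margin across (up to *max_eval*) evaluation samples.

    Linear families use the exact closed form; the tree family uses the
    booster's TreeSHAP contributions.
    """
    from sklearn.utils.validation import check_is_fitted

    check_is_fitted(model)
    X = np.asarray(X, dtype=float)
    bg = X if background is None else np.asarray(background, dtype=float)
    Xe = X[:max_eval]
    pre = Pipeline(model.steps[:-1])
    Xt, bgt = pre.transform(Xe), pre.transform(bg)
    clf = model.steps[-1][1]
    if hasattr(clf, "coef_"):
        phi = linear_shap(clf.coef_, Xt, bgt)
        return mean_abs_importance(phi)
    booster = clf.booster_
    contrib = booster.predict(Xt, pred_contrib=True)
    n, p = Xt.shape
    contrib = np.asarray(contrib).reshape(n, -1, p + 1)[:, :, :p]
    return np.abs(contrib).mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# recursive feature elimination (Box-1 style)
# ---------------------------------------------------------------------------

@dataclass
class RFETrace:
    sizes: list[int]
    feature_sets: list[list[str]]
    accuracies: list[float]
    importances: list[np.ndarray]
    selected_set: list[str]

    @property
    def selected_index(self) -> int:
        return int(np.argmax(self.accuracies))


def _drop_least_important(active: list[str], imp: np.ndarray, k: int) -> list[str]:
    # ties on importance: lexicographically later names are dropped first
    by_name_desc = sorted(range(len(active)), key=lambda j: active[j], reverse=True)
    order = sorted(by_name_desc, key=lambda j: imp[j])  # stable
    drop = {active[j] for j in order[:k]}
    return [c for c in active if c not in drop]


def rfe(train: tuple[pd.DataFrame, np.ndarray],
        val: tuple[pd.DataFrame, np.ndarray],
        spec: ModelSpec, k: int = 2, min_features: int = 6,
        params: dict | None = None) -> RFETrace:
    """Shapley-driven recursive feature elimination on one train/val split.

    Evaluates the full set, then repeatedly removes the *k* least important
    features until *min_features* remain; the subset with the highest
    validation accuracy is selected (earliest iteration on ties).  With
    fewer than 8 starting features a single-iteration trace is returned.
    """
    X_tr, y_tr = train
    X_va, y_va = val

    def acc_and_imp(active: list[str]) -> tuple[float, np.ndarray]:
        est = make_estimator(spec, params)
        est.fit(X_tr[active].to_numpy(), y_tr)
        acc = float(np.mean(est.predict(X_va[active].to_numpy()) == y_va))
        return acc, shap_importance(est, X_tr[active])

    return _rfe_loop(list(X_tr.columns), acc_and_imp, k, min_features)


def _rfe_loop(columns: list[str], acc_and_imp, k: int,
              min_features: int) -> RFETrace:
    active = list(columns)
    sizes, sets, accs, imps = [], [], [], []
    single = len(active) < min_features + k
    while True:
        acc, imp = acc_and_imp(active)
        sizes.append(len(active))
        sets.append(list(active))
        accs.append(acc)
        imps.append(imp)
        if single or len(active) - k < min_features:
            break
        active = _drop_least_important(active, imp, k)
    best = int(np.argmax(accs))
    return RFETrace(sizes=sizes, feature_sets=sets, accuracies=accs,
                    importances=imps, selected_set=sets[best])


# ---------------------------------------------------------------------------
# randomized hyperparameter search
# ---------------------------------------------------------------------------

def draw_tree_params(rng: np.random.Generator) -> dict:
    lo, hi = TREE_PARAM_RANGES["l2_leaf_regularization"]
    return {
        "tree_depth": int(rng.integers(TREE_PARAM_RANGES["tree_depth"][0],
                                       TREE_PARAM_RANGES["tree_depth"][1] + 1)),
        "l2_leaf_regularization": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        "bagging_temperature": float(rng.uniform(*TREE_PARAM_RANGES["bagging_temperature"])),
        "random_strength": float(rng.uniform(*TREE_PARAM_RANGES["random_strength"])),
    }


def tune(train: tuple[pd.DataFrame, np.ndarray], spec: ModelSpec,
         n_draws: int = 30, n_inner: int = 10,
         rng: np.random.Generator | None = None) -> dict:
    """Randomized search for the tree family (best inner-CV accuracy over
    seeded draws); the linear families return their defaults unchanged."""
    if spec.family != "gradient_boosted_trees":
        return dict(spec.tunable)
    rng = rng or np.random.default_rng(spec.seed)
    X, y = train
    best_params, best_acc = {}, -np.inf
    for _ in range(max(1, n_draws)):
        params = draw_tree_params(rng)
        accs = _cv_accuracies(X, y, spec, list(X.columns), n_inner,
                              seed=spec.seed, params=params)
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best_params = acc, params
    return best_params


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldMember:
    features: list[str]
    params: dict
    model: Pipeline
    decisions: dict[str, str] | None
    validation_accuracy: float
    test_accuracy: float
    importance: pd.Series       # over the full feature-name space


@dataclass
class EnsembleModel:
    members: list[FoldMember]
    classes: np.ndarray
    feature_names: list[str]
    vote: str = "soft"


@dataclass
class EvalReport:
    val_accuracies: np.ndarray
    test_accuracies: np.ndarray
    accuracy: float              # pooled over outer folds
    confusion: np.ndarray
    classes: np.ndarray
    roc: dict | None
    ranking: pd.Series

    @property
    def val_mean(self) -> float:
        return float(self.val_accuracies.mean())

    @property
    def val_sd(self) -> float:
        return float(self.val_accuracies.std(ddof=1))

    @property
    def test_mean(self) -> float:
        return float(self.test_accuracies.mean())

    @property
    def test_sd(self) -> float:
        return float(self.test_accuracies.std(ddof=1))


def _cv_accuracies(X: pd.DataFrame, y: np.ndarray, spec: ModelSpec,
                   active: list[str], n_folds: int, seed: int,
                   params: dict | None = None) -> np.ndarray:
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    Xa = X[active].to_numpy()
    accs = []
    for tr, te in cv.split(Xa, y):
        est = make_estimator(spec, params, calibrated=False)
        est.fit(Xa[tr], y[tr])
        accs.append(float(np.mean(est.predict(Xa[te]) == y[te])))
    return np.asarray(accs)


def _fold_counts(y: np.ndarray, requested: int, what: str) -> int:
    smallest = int(np.bincount(pd.factorize(y)[0]).min())
    if smallest < requested:
        warnings.warn(f"smallest class has {smallest} members; reducing "
                      f"{what} fold count from {requested} to {smallest}",
                      stacklevel=3)
        return max(2, smallest)
    return requested


def nested_cv(X: pd.DataFrame, y: np.ndarray, spec: ModelSpec,
              n_outer: int = 10, n_inner: int = 10, n_draws: int = 30,
              recording_table: pd.DataFrame | None = None,
              alpha: float = 0.05) -> tuple[EnsembleModel, EvalReport]:
    """Stratified nested cross-validation producing a soft-voting ensemble.

    *X* is the participant feature table (138 named columns) and *y* the
    group labels.  When *recording_table* is given (recording-level values,
    one row per participant x task), the Anderson-Darling aggregation
    decisions are recomputed on each outer-train split and frozen into that
    fold's member, so held-out participants never influence them; *X* then
    only fixes the participant order (its index must be participant_id).
    """
    y = np.asarray(y)
    classes = np.unique(y)
    n_outer = _fold_counts(y, n_outer, "outer")
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=spec.seed)

    pids = list(X.index)
    members: list[FoldMember] = []
    pooled_true, pooled_proba = [], []
    all_names = list(X.columns)

    for fold, (tr, te) in enumerate(outer.split(X, y)):
        if recording_table is not None:
            tr_ids = [pids[i] for i in tr]
            rec_tr = recording_table[recording_table["participant_id"].isin(tr_ids)]
            decisions = agg.cohort_decisions(rec_tr, alpha=alpha)
            full, _ = agg.aggregate_cohort(recording_table, decisions=decisions)
            full = full.set_index("participant_id").loc[pids, all_names]
        else:
            decisions, full = None, X
        X_tr, y_tr = full.iloc[tr], y[tr]
        X_te, y_te = full.iloc[te], y[te]
        n_in = _fold_counts(y_tr, n_inner, "inner")
        fold_seed = spec.seed + 1000 * (fold + 1)

        def acc_and_imp(active: list[str]) -> tuple[float, np.ndarray]:
            accs = _cv_accuracies(X_tr, y_tr, spec, active, n_in, seed=fold_seed)
            est = make_estimator(spec, calibrated=False)
            est.fit(X_tr[active].to_numpy(), y_tr)
            return float(accs.mean()), shap_importance(est, X_tr[active])

        trace = _rfe_loop(all_names, acc_and_imp, k=2, min_features=6)
        selected = trace.selected_set

        params = tune((X_tr[selected], y_tr), spec, n_draws=n_draws,
                      n_inner=n_in, rng=np.random.default_rng(fold_seed))
        val_acc = float(_cv_accuracies(X_tr, y_tr, spec, selected, n_in,
                                       seed=fold_seed, params=params).mean())
        est = make_estimator(spec, params)
        est.fit(X_tr[selected].to_numpy(), y_tr)
        proba = est.predict_proba(X_te[selected].to_numpy())
        pred = est.classes_[np.argmax(proba, axis=1)]
        test_acc = float(np.mean(pred == y_te))

        imp = pd.Series(0.0, index=all_names)
        imp[selected] = shap_importance(est, X_tr[selected])
        members.append(FoldMember(features=selected, params=params, model=est,
                                  decisions=decisions,
                                  validation_accuracy=val_acc,
                                  test_accuracy=test_acc, importance=imp))
        pooled_true.append(y_te)
        pooled_proba.append(_align_proba(proba, est.classes_, classes))

    ensemble = EnsembleModel(members=members, classes=classes,
                             feature_names=all_names)
    y_pool = np.concatenate(pooled_true)
    p_pool = np.vstack(pooled_proba)
    frag = evaluate(y_pool, p_pool, classes)
    report = EvalReport(
        val_accuracies=np.array([m.validation_accuracy for m in members]),
        test_accuracies=np.array([m.test_accuracy for m in members]),
        accuracy=frag["accuracy"], confusion=frag["confusion"],
        classes=classes, roc=frag["roc"],
        ranking=rank_features([m.importance for m in members]),
    )
    return ensemble, report


def _align_proba(proba: np.ndarray, model_classes: np.ndarray,
                 classes: np.ndarray) -> np.ndarray:
    out = np.zeros((proba.shape[0], classes.size))
    for j, c in enumerate(model_classes):
        out[:, np.flatnonzero(classes == c)[0]] = proba[:, j]
    return out


def soft_vote(ensemble: EnsembleModel, X: pd.DataFrame) -> np.ndarray:
    """Unweighted mean of the member probability vectors.  *X* must carry
    the full feature-name space; each member selects its own subset."""
    missing = set().union(*(m.features for m in ensemble.members)) - set(X.columns)
    if missing:
        raise ValueError(f"input lacks features required by members: {sorted(missing)}")
    acc = np.zeros((len(X), ensemble.classes.size))
    for m in ensemble.members:
        p = m.model.predict_proba(X[m.features].to_numpy())
        acc += _align_proba(p, m.model.named_steps["clf"].classes_, ensemble.classes)
    return acc / len(ensemble.members)


# ---------------------------------------------------------------------------
# evaluation and comparisons
# ---------------------------------------------------------------------------

def evaluate(y_true: np.ndarray, proba: np.ndarray,
             classes: np.ndarray) -> dict:
    """Accuracy, confusion matrix and one-vs-rest ROC curves with micro-
    and macro-averaged AUC from predicted class probabilities."""
    y_true = np.asarray(y_true)
    pred = classes[np.argmax(proba, axis=1)]
    acc = float(np.mean(pred == y_true))
    cm = confusion_matrix(y_true, pred, labels=classes)
    if np.unique(y_true).size < 2:
        warnings.warn("single-class labels: ROC undefined", stacklevel=2)
        return {"accuracy": acc, "confusion": cm, "roc": None}
    Y = label_binarize(y_true, classes=classes)
    if classes.size == 2:
        Y = np.column_stack([1 - Y[:, 0], Y[:, 0]])
    roc: dict = {"per_class": {}}
    aucs = []
    for j, c in enumerate(classes):
        fpr, tpr, _ = roc_curve(Y[:, j], proba[:, j])
        a = auc(fpr, tpr)
        roc["per_class"][c] = {"fpr": fpr, "tpr": tpr, "auc": float(a)}
        aucs.append(a)
    fpr_mi, tpr_mi, _ = roc_curve(Y.ravel(), proba.ravel())
    roc["micro_auc"] = float(auc(fpr_mi, tpr_mi))
    roc["micro_curve"] = (fpr_mi, tpr_mi)
    roc["macro_auc"] = float(np.mean(aucs))
    return {"accuracy": acc, "confusion": cm, "roc": roc}


def rank_features(fold_importances: list[pd.Series]) -> pd.Series:
    """Global ranking: per-feature sum of the fold-wise mean |Shapley value|
    vectors, descending; ties broken by feature-name order."""
    total = pd.concat(fold_importances, axis=1).fillna(0.0).sum(axis=1)
    order = sorted(total.index, key=lambda name: (-total[name], name))
    return total.loc[order]


def compare_classifiers(accuracy_arrays: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis omnibus over per-fold accuracy arrays plus pairwise
    rank-sum follow-ups with Bonferroni adjustment."""
    names = list(accuracy_arrays)
    arrays = [np.asarray(accuracy_arrays[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 accuracy arrays")
    if len({a.size for a in arrays}) != 1:
        raise ValueError("accuracy arrays must have equal length")
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        omnibus = {"H": 0.0, "p": 1.0}
    else:
        H, p = stats.kruskal(*arrays)
        omnibus = {"H": float(H), "p": float(p)}
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.array_equal(arrays[i], arrays[j]):
                praw = 1.0
            else:
                praw = float(stats.ranksums(arrays[i], arrays[j]).pvalue)
            pairwise[f"{names[i]} vs {names[j]}"] = min(1.0, n_pairs * praw)
    return {"omnibus": omnibus, "pairwise": pairwise}
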