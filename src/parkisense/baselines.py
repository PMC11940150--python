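"""Alternative feature-selection models and resampling placements.

These are the comparison arms evaluated against MIEE under the identical
cross-validation harness: an unsupervised random-forest ranking (real
rows vs. a column-permuted shadow copy) with a forward scan maximizing
training balanced accuracy; a plain top-30 mutual-information ranking; a
per-feature decision-tree F1 ranking; a supervised random-forest ranking
with a forward scan minimizing AIC (binomial deviance over out-of-bag
probabilities, penalized by subset size); and random undersampling.
Imbalance resampling combines Neighborhood Cleaning Rule undersampling of
the majority class with SMOTE oversampling of the minority class, in
three placements relative to feature selection and training.

NCL and SMOTE are implemented here directly from their original
descriptions (3-NN cleaning rule; convex interpolation to k=5 minority
neighbors up to class parity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from .evaluation import ConfusionMatrix, EvaluationReport, compute_metrics
from .features import FeatureTable, TablePreprocessor
from .miee import CVConfig, MieeConfig

FS_METHODS = (
    "unsup_rf_fs_max_bacc",
    "mi_top30",
    "f1_dt_ranking",
    "sup_rf_min_aic",
    "random_undersample",
)
SAMPLING_PLACEMENTS = (
    "none",
    "sample_then_fs_train_original",
    "sample_then_fs_train_sampled",
    "fs_then_sample_train_sampled",
)


@dataclass(frozen=True)
class BaselineSpec:
    method: str
    sampling: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in FS_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.sampling not in SAMPLING_PLACEMENTS:
            raise ValueError(f"unknown sampling placement {self.sampling!r}")

    @property
    def name(self) -> str:
        return self.method if self.sampling == "none" else f"{self.method}+{self.sampling}"


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray, positive) -> float:
    cm = ConfusionMatrix.from_labels(y_true, y_pred, positive)
    if cm.n_positive == 0 or cm.n_negative == 0:
        return np.nan
    return compute_metrics(cm)["balanced_accuracy"]


# ---------------------------------------------------------------------------
# feature selectors

def unsupervised_rf_selection(
    X: pd.DataFrame,
    y: np.ndarray,
    top_k: int = 30,
    n_trees: int = 200,
    seed: int = 0,
) -> list[str]:
    """Label-free RF importance ranking, then a forward scan for the
    prefix of the top-k ranking that maximizes training balanced accuracy.

    The unsupervised ranking contrasts the real rows against a shadow copy
    whose columns are independently permuted; features that help a forest
    tell real from shadow carry multivariate structure.
    """
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy()
    shadow = np.column_stack([rng.permutation(Xv[:, j]) for j in range(Xv.shape[1])])
    contrast_X = np.vstack([Xv, shadow])
    contrast_y = np.r_[np.ones(len(Xv)), np.zeros(len(shadow))]
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed % (2**31 - 1), n_jobs=1)
    forest.fit(contrast_X, contrast_y)
    order = np.argsort(forest.feature_importances_)[::-1][:top_k]
    ranked = list(np.asarray(X.columns)[order])
    return _forward_scan_max_bacc(X, y, ranked, seed)


def _forward_scan_max_bacc(X: pd.DataFrame, y: np.ndarray, ranked: list[str], seed: int) -> list[str]:
    # training balanced accuracy is estimated out-of-bag: a fully grown
    # forest memorizes in-bag rows, so the resubstitution estimate would
    # degenerate to 1.0 at any subset size
    classes, counts = np.unique(y, return_counts=True)
    positive = classes[np.argmax(counts)]
    best_k, best_bacc = 1, -np.inf
    for k in range(1, len(ranked) + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = RandomForestClassifier(
                n_estimators=100, random_state=seed % (2**31 - 1), n_jobs=1,
                oob_score=True, bootstrap=True,
            )
            clf.fit(X[ranked[:k]].to_numpy(), y)
        oob = clf.oob_decision_function_
        seen = np.isfinite(oob).all(axis=1) & (oob.sum(axis=1) > 0)
        pred = np.asarray(clf.classes_)[np.argmax(oob[seen], axis=1)]
        bacc = _balanced_accuracy(y[seen], pred, positive)
        if bacc > best_bacc + 1e-12:
            best_k, best_bacc = k, bacc
    return ranked[:best_k]


def f1_dt_ranking(
    X: pd.DataFrame, y: np.ndarray, max_depth: int = 2, n_folds: int = 3, seed: int = 0
) -> pd.Series:
    """Rank features by the cross-validated F1 of a single-feature,
    depth-limited decision tree (rare class positive for F1)."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("f1_dt_ranking needs binary labels")
    minority = classes[np.argmin(counts)]
    n_folds = min(n_folds, counts.min())
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32 - 1))
    splits = list(skf.split(np.zeros(len(y)), y))
    Xv = X.to_numpy()
    scores = np.zeros(Xv.shape[1])
    for j in range(Xv.shape[1]):
        xj = Xv[:, [j]]
        f1s = []
        for tr, te in splits:
            tree = DecisionTreeClassifier(max_depth=max_depth, random_state=0)
            tree.fit(xj[tr], y[tr])
            pred = tree.predict(xj[te])
            tp = int(((pred == minority) & (y[te] == minority)).sum())
            fp = int(((pred == minority) & (y[te] != minority)).sum())
            fn = int(((pred != minority) & (y[te] == minority)).sum())
            f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
        scores[j] = np.mean(f1s)
    return pd.Series(scores, index=X.columns).sort_values(ascending=False)


def forest_aic(forest: RandomForestClassifier, y: np.ndarray, k: int) -> float:
    """AIC = 2k - 2 log L, with L the binomial likelihood of the labels
    under the forest's out-of-bag predicted probabilities and k the number
    of features. Forests define no native likelihood; OOB binomial
    deviance is the least-arbitrary stand-in."""
    oob = forest.oob_decision_function_
    classes = list(forest.classes_)
    idx = np.array([classes.index(v) for v in y])
    p = np.clip(oob[np.arange(len(y)), idx], 1e-6, 1 - 1e-6)
    # rows never left out of bag yield NaN; drop them from the likelihood
    p = p[np.isfinite(p)]
    return 2 * k - 2 * float(np.log(p).sum())


def supervised_rf_min_aic(
    X: pd.DataFrame,
    y: np.ndarray,
    top_k: int = 30,
    n_trees: int = 200,
    seed: int = 0,
) -> list[str]:
    """Supervised RF importance ranking, forward scan to the prefix with
    minimum AIC (two identical likelihoods -> the smaller subset wins)."""
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed % (2**31 - 1), n_jobs=1)
    forest.fit(X.to_numpy(), y)
    order = np.argsort(forest.feature_importances_)[::-1][:top_k]
    ranked = list(np.asarray(X.columns)[order])
    best_k, best_aic = 1, np.inf
    for k in range(1, len(ranked) + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=seed % (2**31 - 1),
                oob_score=True, bootstrap=True, n_jobs=1,
            )
            clf.fit(X[ranked[:k]].to_numpy(), y)
            aic = forest_aic(clf, y, k)
        if aic < best_aic - 1e-12:
            best_k, best_aic = k, aic
    return ranked[:best_k]


# ---------------------------------------------------------------------------
# resampling

def ncl_undersample(X: np.ndarray, y: np.ndarray, minority, k: int = 3) -> np.ndarray:
    """Neighborhood Cleaning Rule: retained row indices.

    Removes majority rows misclassified by their k nearest neighbors, and
    majority rows that participate in misclassifying a minority row's
    neighborhood.
    """
    n = len(y)
    if n <= k:
        return np.arange(n)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = idx[:, 1:]  # drop self
    maj_mask = y != minority
    votes_min = (y[neigh] == minority).sum(axis=1)
    drop = np.zeros(n, dtype=bool)
    # rule 1: majority rows whose neighborhood votes minority
    drop |= maj_mask & (votes_min > k / 2)
    # rule 2: majority neighbors of minority rows misclassified by their neighborhood
    for i in np.flatnonzero(~maj_mask):
        if (y[neigh[i]] != minority).sum() > k / 2:
            for j in neigh[i]:
                if maj_mask[j]:
                    drop[j] = True
    # never drop below class parity
    keep = ~drop
    n_min = int((~maj_mask).sum())
    if (keep & maj_mask).sum() < n_min:
        maj_idx = np.flatnonzero(maj_mask)
        keep[maj_idx] = True
        drop_idx = maj_idx[drop[maj_idx]][: max(0, maj_mask.sum() - n_min)]
        keep[drop_idx] = False
    return np.flatnonzero(keep)


def smote_oversample(
    X: np.ndarray, y: np.ndarray, minority, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: synthesize minority rows by convex interpolation toward
    k-nearest minority neighbors until class parity. Returns the appended
    synthetic block (X_new, y_new); skips with a warning when the minority
    has fewer than 2 rows."""
    min_idx = np.flatnonzero(y == minority)
    n_needed = int((y != minority).sum() - min_idx.size)
    if n_needed <= 0:
        return np.empty((0, X.shape[1])), np.empty(0, dtype=y.dtype)
    if min_idx.size < 2:
        warnings.warn("SMOTE skipped: minority class has fewer than 2 rows")
        return np.empty((0, X.shape[1])), np.empty(0, dtype=y.dtype)
    rng = np.random.default_rng(seed)
    Xm = X[min_idx]
    k_eff = min(k, len(Xm) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)
    base = rng.integers(0, len(Xm), n_needed)
    pick = idx[base][np.arange(n_needed), rng.integers(1, k_eff + 1, n_needed)]
    lam = rng.random((n_needed, 1))
    X_new = Xm[base] + lam * (Xm[pick] - Xm[base])
    return X_new, np.full(n_needed, minority, dtype=np.asarray(y).dtype)


def resample_strategy(
    X: pd.DataFrame, y: np.ndarray, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """NCL undersampling of the majority followed by SMOTE oversampling of
    the minority up to class parity."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("resampling needs exactly 2 classes present")
    minority = classes[np.argmin(counts)]
    Xv = X.to_numpy()
    keep = ncl_undersample(Xv, y, minority)
    Xk, yk = Xv[keep], y[keep]
    X_new, y_new = smote_oversample(Xk, yk, minority, seed=seed)
    X_out = pd.DataFrame(
        np.vstack([Xk, X_new]),
        columns=X.columns,
        index=list(X.index[keep]) + [f"smote{i}" for i in range(len(X_new))],
    )
    return X_out, np.concatenate([yk, y_new])


def random_undersample(
    X: pd.DataFrame, y: np.ndarray, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Uniform undersampling of the majority class down to minority size."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    minority = classes[np.argmin(counts)]
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    rng = np.random.default_rng(seed)
    draw = rng.choice(maj_idx, size=min_idx.size, replace=False)
    rows = np.sort(np.concatenate([min_idx, draw]))
    return X.iloc[rows], y[rows]


# ---------------------------------------------------------------------------
# harnessed evaluation

def _fit_predict_baseline(
    spec: BaselineSpec,
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    minority,
    n_trees: int,
    top_k: int,
    seed: int,
) -> np.ndarray:
    """One baseline arm inside one training fold; returns minority-class
    probabilities for the test rows. Sampling never touches test rows."""

    def select(X: pd.DataFrame, y: np.ndarray) -> list[str]:
        if spec.method == "unsup_rf_fs_max_bacc":
            return unsupervised_rf_selection(X, y, top_k, n_trees, seed)
        if spec.method == "mi_top30":
            from .miee import mutual_information_scores

            scores = mutual_information_scores(X.to_numpy(), y, seed=seed)
            order = np.argsort(scores)[::-1][:top_k]
            return list(np.asarray(X.columns)[order])
        if spec.method == "f1_dt_ranking":
            return list(f1_dt_ranking(X, y, seed=seed).index[:top_k])
        if spec.method in ("sup_rf_min_aic", "random_undersample"):
            return supervised_rf_min_aic(X, y, top_k, n_trees, seed)
        raise AssertionError(spec.method)

    if spec.method == "random_undersample":
        X_fit, y_fit = random_undersample(X_train, y_train, seed)
        feats = select(X_fit, y_fit)
        X_model, y_model = X_fit, y_fit
    elif spec.sampling == "none":
        feats = select(X_train, y_train)
        X_model, y_model = X_train, y_train
    elif spec.sampling == "sample_then_fs_train_original":
        Xs, ys = resample_strategy(X_train, y_train, seed)
        feats = select(Xs, ys)
        X_model, y_model = X_train, y_train
    elif spec.sampling == "sample_then_fs_train_sampled":
        Xs, ys = resample_strategy(X_train, y_train, seed)
        feats = select(Xs, ys)
        X_model, y_model = Xs, ys
    elif spec.sampling == "fs_then_sample_train_sampled":
        feats = select(X_train, y_train)
        Xs, ys = resample_strategy(X_train, y_train, seed)
        X_model, y_model = Xs, ys
    else:
        raise AssertionError(spec.sampling)

    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed % (2**31 - 1), n_jobs=1)
    clf.fit(X_model[feats].to_numpy(), y_model)
    col = list(clf.classes_).index(minority)
    return clf.predict_proba(X_test[feats].to_numpy())[:, col]


def run_baseline_suite(
    table: FeatureTable,
    labels: np.ndarray,
    cv_config: CVConfig | None = None,
    specs: list[BaselineSpec] | None = None,
    n_trees: int = 200,
    top_k: int = 30,
) -> pd.DataFrame:
    """Evaluate every baseline arm under the same CV harness as MIEE.

    Fold assignments reuse the CVConfig seeds, so a MIEE run with the same
    configuration sees identical train/test splits. Returns one row per
    baseline with the imbalance-aware metric set.
    """
    cv = cv_config or CVConfig()
    labels = np.asarray(labels)
    if specs is None:
        specs = [BaselineSpec(m) for m in FS_METHODS if m != "random_undersample"]
        specs += [
            BaselineSpec("sup_rf_min_aic", s) for s in SAMPLING_PLACEMENTS if s != "none"
        ]
        specs.append(BaselineSpec("random_undersample"))
    classes, counts = np.unique(labels, return_counts=True)
    minority = classes[np.argmin(counts)]
    positive = classes[np.argmax(counts)]
    n = len(labels)
    rows = []
    for spec in specs:
        probs = np.full((cv.n_repeats, n), np.nan)
        rep_labels = np.empty((cv.n_repeats, n), dtype=object)
        for r, rseed in enumerate(cv.repeat_seeds()):
            skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True,
                                  random_state=rseed % (2**32 - 1))
            for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
                prep = TablePreprocessor().fit(table, tr)
                Xtr = prep.transform(table, tr)
                Xte = prep.transform(table, te)
                p = _fit_predict_baseline(
                    spec, Xtr, labels[tr], Xte, minority, n_trees, top_k,
                    seed=(spec.seed * 97 + rseed * 31 + fold) % (2**31 - 1),
                )
                probs[r, te] = p
                rep_labels[r, te] = np.where(p >= 0.5, minority, positive)
        votes = (rep_labels == minority).sum(axis=0)
        final = np.where(votes > cv.n_repeats / 2, minority, positive).astype(str)
        cm = ConfusionMatrix.from_labels(labels, final, positive)
        metrics = compute_metrics(cm, probs.mean(axis=0), labels, positive)
        rows.append({"baseline": spec.name, **metrics})
    return pd.DataFrame(rows).set_index("baseline")
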