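"""Evaluation of the parkinsonism classifier: imbalance-aware metrics,
BCa bootstrap confidence intervals, grouped permutation importance,
feature-selection tallies, misclassification profiling, and random-forest
proximity similarity.

The positive class throughout is the majority diagnosis (PD): sensitivity
is the PD recall, specificity the non-PD recall, and balanced accuracy
their mean — the headline metric under a ~14:1 class imbalance, where raw
accuracy would be dominated by the majority class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable
from .miee import CVResult, MIEEResults


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with PD (majority diagnosis) as the positive class.

    Rows are actual classes, columns predictions: TP and FN are PD
    participants predicted PD / non-PD; FP and TN are non-PD participants
    predicted PD / non-PD.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @classmethod
    def from_labels(
        cls, true: np.ndarray, pred: np.ndarray, positive: str
    ) -> "ConfusionMatrix":
        true = np.asarray(true)
        pred = np.asarray(pred)
        pos = true == positive
        return cls(
            tp=int(((pred == positive) & pos).sum()),
            fn=int(((pred != positive) & pos).sum()),
            fp=int(((pred == positive) & ~pos).sum()),
            tn=int(((pred != positive) & ~pos).sum()),
        )


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 10_000
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")
        if self.n_replicates < 100:
            raise ValueError("n_replicates must be >= 100")


def compute_metrics(
    cm: ConfusionMatrix,
    probabilities: np.ndarray | None = None,
    true_labels: np.ndarray | None = None,
    positive: str | None = None,
) -> dict[str, float]:
    """Balanced accuracy, sensitivity, specificity, F1 (PD positive) and,
    when probabilities are supplied, rank-based AUC-ROC.

    Probabilities are the *minority* (non-PD) scores as produced by the
    ensemble; AUC is reported for discriminating the two classes and is
    orientation-corrected so 1.0 means perfect separation of PD from
    non-PD.
    """
    if cm.n_positive == 0 or cm.n_negative == 0:
        raise ValueError("both classes must be present to compute metrics")
    sens = cm.tp / cm.n_positive
    spec = cm.tn / cm.n_negative
    out = {
        "balanced_accuracy": 0.5 * (sens + spec),
        "sensitivity": sens,
        "specificity": spec,
        "f1": 2 * cm.tp / (2 * cm.tp + cm.fn + cm.fp) if (2 * cm.tp + cm.fn + cm.fp) else np.nan,
    }
    if probabilities is not None and true_labels is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        true_labels = np.asarray(true_labels)
        if positive is None:
            raise ValueError("positive class label needed for AUC")
        out["auc_roc"] = auc_mann_whitney(
            probabilities[true_labels != positive], probabilities[true_labels == positive]
        )
    return out


def auc_mann_whitney(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic: the probability that
    a positive-class score exceeds a negative-class one (ties count half)."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both score groups must be non-empty")
    diff = scores_pos[:, None] - scores_neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def bca_bootstrap_ci(
    class_outcomes: list[np.ndarray],
    metric,
    config: BootstrapConfig | None = None,
    vectorized: bool = False,
) -> tuple[float, float, str]:
    """Balanced-bootstrap BCa confidence interval for a metric.

    ``class_outcomes`` holds one per-participant outcome vector per class;
    each class is resampled with replacement at its own size (the balanced
    bootstrap — every replicate keeps the study's imbalance ratio, so
    balanced accuracy stays defined). ``metric`` maps one resample per
    class to a scalar; with ``vectorized=True`` it must also accept an
    ``axis`` keyword and is evaluated on all replicates at once. Returns
    (lower, upper, flag); a degenerate bootstrap distribution falls back
    to the percentile interval with a flag.
    """
    cfg = config or BootstrapConfig()
    data = [np.asarray(c) for c in class_outcomes]
    if any(c.size < 2 for c in data):
        raise ValueError("need at least 2 participants per class")

    point = metric(*data)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.bootstrap(
                data,
                metric,
                n_resamples=cfg.n_replicates,
                confidence_level=cfg.level,
                method="BCa",
                vectorized=vectorized,
                paired=False,
                random_state=np.random.default_rng(cfg.seed),
            )
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
        if np.isnan(lo) or np.isnan(hi):
            raise ValueError("degenerate BCa interval")
        return lo, hi, ""
    except Exception:
        rng = np.random.default_rng(cfg.seed)
        reps = np.array(
            [
                metric(*[c[rng.integers(0, c.size, c.size)] for c in data])
                for _ in range(cfg.n_replicates)
            ]
        )
        alpha = (1 - cfg.level) / 2
        if np.allclose(reps, reps[0]):
            return float(reps[0]), float(reps[0]), "degenerate-distribution"
        return (
            float(np.quantile(reps, alpha)),
            float(np.quantile(reps, 1 - alpha)),
            "percentile-fallback",
        )


def group_permutation_importance(
    results: MIEEResults,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    group_map: dict[str, list[str]],
    n_permutations: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Mean decrease in balanced accuracy when a whole feature group
    (one mobility task) is permuted simultaneously.

    All member columns of a group are shuffled with the same row
    permutation, preserving within-group dependence while breaking the
    link to the outcome. Groups must cover every feature the model uses.
    """
    used = sorted({f for mem in results.members for f in mem.features})
    col_group: dict[str, str] = {}
    for g, cols in group_map.items():
        for c in cols:
            col_group[c] = g
    unmapped = [f for f in used if f not in col_group]
    if unmapped:
        raise ValueError(f"features not mapped to any group: {unmapped[:5]} ...")
    y_test = np.asarray(y_test)
    positive = results.model.majority_label

    def bacc(pred: np.ndarray) -> float:
        cm = ConfusionMatrix.from_labels(y_test, pred, positive)
        return compute_metrics(cm)["balanced_accuracy"]

    base = bacc(results.predict(X_test))
    rng = np.random.default_rng(seed)
    out = {}
    for g in group_map:
        cols = [c for c in group_map[g] if c in X_test.columns and c in set(used)]
        if not cols:
            out[g] = 0.0
            continue
        drops = []
        for _ in range(n_permutations):
            perm = rng.permutation(len(X_test))
            Xp = X_test.copy()
            Xp[cols] = X_test[cols].to_numpy()[perm]
            drops.append(base - bacc(results.predict(Xp)))
        out[g] = float(np.mean(drops))
    return pd.Series(out, name="mean_bacc_decrease").sort_values(ascending=False)


def selection_tally(cv_result: CVResult, metadata: pd.DataFrame) -> dict[str, pd.Series]:
    """Fractions of selected features per task, subtask and derivation.

    Counts pool over replicates x folds x subsets and are normalized to
    fractions (each breakdown sums to 1).
    """
    sel = cv_result.selections
    if sel.empty:
        return {"task": pd.Series(dtype=float), "subtask": pd.Series(dtype=float),
                "derivation": pd.Series(dtype=float)}
    meta = metadata.loc[sel["feature"]]
    out = {}
    for key in ("task", "subtask", "derivation"):
        counts = meta[key].value_counts()
        out[key] = (counts / counts.sum()).sort_values(ascending=False)
    return out


def misclassification_comparison(
    final_labels: np.ndarray,
    true_labels: np.ndarray,
    covariates: pd.DataFrame,
    categorical: tuple[str, ...] = (),
    chi2_correction: bool = False,
) -> pd.DataFrame:
    """Compare correctly vs incorrectly classified participants per class.

    Continuous covariates: two-tailed Student's t-test (pooled variance),
    reported as mean +/- SD per group. Categorical covariates: Pearson
    chi-squared on the contingency table (no continuity correction by
    default). Groups with n < 2 are flagged and the test skipped.
    """
    final_labels = np.asarray(final_labels)
    true_labels = np.asarray(true_labels)
    correct = final_labels == true_labels
    rows = []
    for cls in np.unique(true_labels):
        in_cls = true_labels == cls
        g_ok = covariates[in_cls & correct]
        g_bad = covariates[in_cls & ~correct]
        for col in covariates.columns:
            row = {"class": cls, "covariate": col,
                   "n_correct": len(g_ok), "n_incorrect": len(g_bad)}
            if col in categorical:
                tab = pd.crosstab(
                    correct[in_cls], covariates.loc[in_cls, col]
                )
                if tab.shape[0] == 2 and tab.shape[1] >= 2:
                    chi2, p, _, _ = stats.chi2_contingency(tab, correction=chi2_correction)
                    row.update(test="chi2", statistic=float(chi2), p_value=float(p), flag="")
                else:
                    row.update(test="chi2", statistic=np.nan, p_value=np.nan,
                               flag="insufficient-groups")
            else:
                a = g_ok[col].dropna().to_numpy(dtype=float)
                b = g_bad[col].dropna().to_numpy(dtype=float)
                row.update(
                    mean_correct=a.mean() if a.size else np.nan,
                    sd_correct=a.std(ddof=1) if a.size > 1 else np.nan,
                    mean_incorrect=b.mean() if b.size else np.nan,
                    sd_incorrect=b.std(ddof=1) if b.size > 1 else np.nan,
                )
                if a.size >= 2 and b.size >= 2:
                    t, p = stats.ttest_ind(a, b, equal_var=True)
                    row.update(test="t", statistic=float(t), p_value=float(p), flag="")
                else:
                    row.update(test="t", statistic=np.nan, p_value=np.nan,
                               flag="group-too-small")
            rows.append(row)
    return pd.DataFrame(rows)


def forest_proximity(forest, X_a: np.ndarray, X_b: np.ndarray) -> np.ndarray:
    """Random-forest proximity: fraction of trees in which two samples land
    in the same terminal leaf. Shape (len(X_a), len(X_b)), values in [0, 1]."""
    leaves_a = forest.apply(X_a)  # (na, n_trees)
    leaves_b = forest.apply(X_b)
    return (leaves_a[:, None, :] == leaves_b[None, :, :]).mean(axis=2)


def proximity_nearest_class(
    results: MIEEResults,
    X_query: pd.DataFrame,
    X_minority: pd.DataFrame,
    subtype_labels: np.ndarray,
) -> pd.DataFrame:
    """For each query row (e.g. a misclassified PD participant), the
    parkinsonism subtype whose members have the highest mean ensemble
    proximity.

    Proximities are averaged over all member forests, each restricted to
    its own selected features.
    """
    subtype_labels = np.asarray(subtype_labels)
    if len(X_minority) == 0:
        raise ValueError("minority reference set is empty")
    prox = np.zeros((len(X_query), len(X_minority)))
    for mem in results.members:
        prox += forest_proximity(
            mem.forest, X_query[mem.features].to_numpy(), X_minority[mem.features].to_numpy()
        )
    prox /= len(results.members)
    rows = []
    for i, pid in enumerate(X_query.index):
        by_subtype = {
            s: float(prox[i, subtype_labels == s].mean()) for s in np.unique(subtype_labels)
        }
        best = max(by_subtype, key=by_subtype.get)
        rows.append({"participant": pid, "nearest_subtype": best, **by_subtype})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Bundle of the classifier evaluation: confusion matrix, metrics with
    BCa intervals, selection tallies and group importances."""

    confusion: ConfusionMatrix
    metrics: dict[str, float]
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    selection_fractions: dict[str, pd.Series] = field(default_factory=dict)
    group_importance: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, value in self.metrics.items():
            lo, hi = self.intervals.get(name, (np.nan, np.nan))
            rows.append({"metric": name, "value": value, "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Classification report (PD positive)",
            f"  confusion: TP={self.confusion.tp} FN={self.confusion.fn} "
            f"FP={self.confusion.fp} TN={self.confusion.tn}",
        ]
        for _, r in self.to_frame().iterrows():
            ci = "" if np.isnan(r["ci_low"]) else f"  (CI {r['ci_low']:.3f}, {r['ci_high']:.3f})"
            lines.append(f"  {r['metric']:<18}{r['value']:.4f}{ci}")
        if self.group_importance is not None:
            lines.append("  group importance (mean bacc decrease):")
            for g, v in self.group_importance.items():
                lines.append(f"    {g:<14}{v:+.4f}")
        return "\n".join(lines)


def evaluate_cv(
    cv_result: CVResult,
    metadata: pd.DataFrame | None = None,
    bootstrap: BootstrapConfig | None = None,
) -> EvaluationReport:
    """Full evaluation of a cross-validation result: metrics from the
    majority-vote labels, BCa intervals from per-participant outcomes, and
    selection tallies when column metadata is given."""
    positive = [l for l in np.unique(cv_result.true_labels) if l != cv_result.minority_label][0]
    cm = ConfusionMatrix.from_labels(cv_result.true_labels, cv_result.final_labels, positive)
    mean_prob = cv_result.mean_probability()
    metrics = compute_metrics(cm, mean_prob, cv_result.true_labels, positive)
    intervals = {}
    if bootstrap is not None:
        pos_mask = cv_result.true_labels == positive
        ok = (cv_result.final_labels == cv_result.true_labels).astype(float)
        pos_out, neg_out = ok[pos_mask], ok[~pos_mask]
        pos_scores, neg_scores = mean_prob[pos_mask], mean_prob[~pos_mask]
        defs = {
            "balanced_accuracy": ([pos_out, neg_out], lambda a, b: 0.5 * (a.mean() + b.mean())),
            "sensitivity": ([pos_out], lambda a: a.mean()),
            "specificity": ([neg_out], lambda b: b.mean()),
            "auc_roc": ([pos_scores, neg_scores], lambda a, b: auc_mann_whitney(a, b)),
        }
        for i, (name, (data, fn)) in enumerate(defs.items()):
            if all(d.size >= 2 for d in data):
                cfg = bootstrap if i == 0 else BootstrapConfig(
                    bootstrap.n_replicates, bootstrap.level, bootstrap.seed + i
                )
                lo, hi, _ = bca_bootstrap_ci(data, fn, cfg)
                intervals[name] = (lo, hi)
    fractions = selection_tally(cv_result, metadata) if metadata is not None else {}
    return EvaluationReport(cm, metrics, intervals, fractions)
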