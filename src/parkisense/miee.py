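"""Mutual-information feature selection for EasyEnsemble (MIEE).

The classifier for a severely imbalanced two-class cohort: draw several
balanced subsets by undersampling the majority class (EasyEnsemble), rank
features within each subset by mutual information with the class label,
keep the top k, train a random forest per subset, and average the member
probabilities at prediction time. The repeated stratified cross-validation
harness trains everything — preprocessing, selection, forests — inside
each training fold, records per-repeat test probabilities, and takes a
per-participant majority vote over repeats.

The model API follows the fit/results convention: :class:`MIEE` is built
from a (preprocessed) feature matrix and labels, ``fit()`` returns an
:class:`MIEEResults` carrying the per-subset selections and forests plus
prediction and summary methods.

Mutual information uses the nearest-neighbor estimator for a continuous
feature against a discrete label (Kraskov/Ross type, k=3), vectorized
across feature columns; a tiny deterministic jitter breaks ties the same
way sklearn's estimator does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable, TablePreprocessor


@dataclass(frozen=True)
class MieeConfig:
    n_subsets: int = 5
    top_k: int = 30
    n_trees: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1 or self.top_k < 1 or self.n_trees < 1:
            raise ValueError("n_subsets, top_k and n_trees must all be >= 1")


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 3
    n_repeats: int = 5
    seeds: tuple[int, ...] | None = None  # one per repeat; derived from seed if None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats % 2 == 0:
            raise ValueError("n_repeats must be odd so the majority vote is well-defined")
        if self.seeds is not None and len(self.seeds) != self.n_repeats:
            raise ValueError("need one seed per repeat")

    def repeat_seeds(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return [(self.seed * 1_000_003 + 7919 * r) % (2**31 - 1) for r in range(self.n_repeats)]


# ---------------------------------------------------------------------------
# mutual information

def mutual_information_scores(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    k: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Nearest-neighbor MI (nats) between each continuous column and a
    discrete label.

    Ross-type estimator: for each sample, the distance to its k-th nearest
    same-class neighbor defines a radius; counting how many samples of any
    class fall strictly inside it yields the digamma correction terms.
    Vectorized over columns; non-negative by construction (clipped at 0).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("mutual information needs at least 2 classes present")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    scale = np.maximum(1.0, np.mean(np.abs(X), axis=0))
    X = X + 1e-10 * scale * rng.standard_normal(X.shape)

    k_all = np.zeros(n)
    label_counts = np.zeros(n)
    usable = np.zeros(n, dtype=bool)
    class_idx = []
    for ci in range(classes.size):
        idx = np.flatnonzero(y_idx == ci)
        label_counts[idx] = idx.size
        if idx.size >= 2:
            usable[idx] = True
            k_all[idx] = min(k, idx.size - 1)
        class_idx.append(idx)
    m_all = np.zeros((n, p))
    radius = np.zeros((n, p))
    chunk = max(1, int(2_000_000 / max(1, n * n)))
    dbuf = np.empty((n, n, chunk))
    bbuf = np.empty((n, n, chunk), dtype=bool)
    for a in range(0, p, chunk):
        sl = slice(a, min(a + chunk, p))
        c = sl.stop - sl.start
        d = dbuf[:, :, :c]
        np.subtract(X[:, None, sl], X[None, :, sl], out=d)  # d[i, j, col]
        np.abs(d, out=d)
        for idx in class_idx:
            if idx.size < 2:
                continue
            kc = min(k, idx.size - 1)
            dc = d[np.ix_(idx, idx)]  # same-class distances
            radius[idx, sl] = np.partition(dc, kc, axis=1)[:, kc, :]
        b = bbuf[:, :, :c]
        np.less(d, radius[:, sl][:, None, :], out=b)
        m_all[:, sl] = b.sum(axis=1)
    u = usable
    n_u = int(u.sum())
    mi = (
        digamma(n_u)
        + np.mean(digamma(k_all[u]))
        - np.mean(digamma(label_counts[u]))
        - digamma(np.maximum(m_all[u], 1)).mean(axis=0)
    )
    return np.maximum(mi, 0.0)


def build_balanced_subsets(
    labels: np.ndarray,
    config: MieeConfig | None = None,
    seed: int | None = None,
    minority: object | None = None,
) -> list[np.ndarray]:
    """EasyEnsemble subsets: every minority row plus an equal-size uniform
    draw (without replacement) of majority rows, independently per subset.

    Positions index the given label vector. If a nominal ``minority`` class
    is supplied but actually outnumbers the other class, the roles are
    swapped with a warning.
    """
    config = config or MieeConfig()
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("build_balanced_subsets needs exactly 2 classes present")
    if minority is None:
        minority = classes[np.argmin(counts)]
    elif (labels == minority).sum() > (labels != minority).sum():
        warnings.warn("nominal minority class outnumbers majority; swapping roles")
        minority = classes[classes != minority][0]
    min_idx = np.flatnonzero(labels == minority)
    maj_idx = np.flatnonzero(labels != minority)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    subsets = []
    for _ in range(config.n_subsets):
        draw = rng.choice(maj_idx, size=min(min_idx.size, maj_idx.size), replace=False)
        subsets.append(np.sort(np.concatenate([min_idx, draw])))
    return subsets


# ---------------------------------------------------------------------------
# model / results

class MIEE:
    """MIEE model over a preprocessed feature matrix and binary labels."""

    def __init__(
        self,
        X: pd.DataFrame,
        y: np.ndarray,
        config: MieeConfig | None = None,
    ) -> None:
        self.X = X
        self.y = np.asarray(y)
        if len(X) != len(self.y):
            raise ValueError("X and y length mismatch")
        self.config = config or MieeConfig()
        classes, counts = np.unique(self.y, return_counts=True)
        if classes.size != 2:
            raise ValueError("MIEE is a binary classifier; need both classes present")
        self.minority_label = classes[np.argmin(counts)]
        self.majority_label = classes[np.argmax(counts)]

    def fit(self) -> "MIEEResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        subset_seed, mi_seed, forest_seed = (int(s.generate_state(1)[0] % (2**31 - 1))
                                             for s in ss.spawn(3))
        subsets = build_balanced_subsets(self.y, cfg, seed=subset_seed)
        columns = np.asarray(self.X.columns)
        top_k = cfg.top_k
        if top_k > columns.size:
            warnings.warn(
                f"top_k={top_k} exceeds {columns.size} available features; using all"
            )
            top_k = columns.size
        members = []
        Xv = self.X.to_numpy()
        for si, rows in enumerate(subsets):
            scores = mutual_information_scores(Xv[rows], self.y[rows], seed=mi_seed + si)
            order = np.argsort(scores)[::-1][:top_k]
            feats = list(columns[order])
            forest = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                random_state=(forest_seed + si) % (2**31 - 1),
                n_jobs=1,
            )
            forest.fit(Xv[np.ix_(rows, order)], self.y[rows])
            members.append(MieeMember(feats, forest, scores[order]))
        return MIEEResults(self, members)


@dataclass
class MieeMember:
    features: list[str]
    forest: RandomForestClassifier
    mi_scores: np.ndarray


@dataclass
class MIEEResults:
    """Fitted MIEE ensemble: per-subset feature lists and forests."""

    model: MIEE
    members: list[MieeMember]

    @property
    def minority_label(self):
        return self.model.minority_label

    def predict_probability(self, X: pd.DataFrame) -> np.ndarray:
        """Arithmetic mean over members of the minority-class probability."""
        missing = set()
        for mem in self.members:
            missing |= set(mem.features) - set(X.columns)
        if missing:
            raise KeyError(f"unknown feature columns: {sorted(missing)[:5]} ...")
        probs = np.zeros(len(X))
        for mem in self.members:
            cls = list(mem.forest.classes_)
            col = cls.index(self.minority_label)
            probs += mem.forest.predict_proba(X[mem.features].to_numpy())[:, col]
        return probs / len(self.members)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Label = minority iff averaged probability >= 0.5 (ties favor the
        rare class — imbalance-conservative)."""
        p = self.predict_probability(X)
        return np.where(p >= 0.5, self.minority_label, self.model.majority_label)

    def selected_features(self) -> pd.DataFrame:
        rows = [
            {"subset": i, "feature": f, "mi": float(s)}
            for i, mem in enumerate(self.members)
            for f, s in zip(mem.features, mem.mi_scores)
        ]
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        """Serialize the fitted ensemble (config, labels, per-subset
        features and forests) to a single joblib archive."""
        import joblib

        joblib.dump(
            {
                "config": self.model.config,
                "minority_label": self.model.minority_label,
                "majority_label": self.model.majority_label,
                "members": self.members,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "MIEEResults":
        import joblib

        blob = joblib.load(path)
        shell = MIEE.__new__(MIEE)
        shell.config = blob["config"]
        shell.minority_label = blob["minority_label"]
        shell.majority_label = blob["majority_label"]
        shell.X = shell.y = None
        return cls(shell, blob["members"])

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "MIEE ensemble",
            f"  subsets: {len(self.members)}  top_k: {cfg.top_k}  trees/forest: {cfg.n_trees}",
            f"  minority class: {self.minority_label!r}",
        ]
        for i, mem in enumerate(self.members):
            lines.append(
                f"  subset {i}: {len(mem.features)} features, "
                f"best MI {mem.mi_scores.max():.3f} nats ({mem.features[0]})"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cross-validation harness

@dataclass
class CVResult:
    """Per-participant probabilities and labels across repeats, plus the
    per-repeat x fold x subset selection records."""

    participant_ids: list[str]
    true_labels: np.ndarray
    probabilities: np.ndarray  # (n_repeats, n)
    repeat_labels: np.ndarray  # (n_repeats, n) predicted labels
    final_labels: np.ndarray  # majority vote over repeats
    selections: pd.DataFrame  # repeat, fold, subset, feature
    fold_of: np.ndarray  # (n_repeats, n) test-fold id per participant
    minority_label: str

    def mean_probability(self) -> np.ndarray:
        return self.probabilities.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        n_rep = self.probabilities.shape[0]
        rows = []
        for r in range(n_rep):
            for i, pid in enumerate(self.participant_ids):
                rows.append(
                    {
                        "participant": pid, "repeat": r,
                        "probability": self.probabilities[r, i],
                        "label": self.repeat_labels[r, i],
                        "final_label": self.final_labels[i],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        correct = (self.final_labels == self.true_labels)
        mino = self.true_labels == self.minority_label
        lines = [
            "Cross-validated MIEE",
            f"  participants: {len(self.participant_ids)} "
            f"({int(mino.sum())} minority)",
            f"  repeats: {self.probabilities.shape[0]}",
            f"  majority-vote accuracy, majority class: {correct[~mino].mean():.3f}",
            f"  majority-vote accuracy, minority class: {correct[mino].mean():.3f}",
        ]
        return "\n".join(lines)


def cross_validate(
    table: FeatureTable,
    labels: np.ndarray,
    cv_config: CVConfig | None = None,
    miee_config: MieeConfig | None = None,
    participant_ids: list[str] | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV of the full MIEE pipeline.

    Preprocessing, MI selection and forest training happen inside each
    training fold only; every participant is scored exactly once per
    repeat; the final label is the majority vote over repeats.
    """
    cv = cv_config or CVConfig()
    mc = miee_config or MieeConfig()
    labels = np.asarray(labels)
    n = len(labels)
    ids = participant_ids or list(table.values.index.astype(str))
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < cv.n_folds:
        raise ValueError("each class needs at least n_folds members")
    minority = classes[np.argmin(counts)]
    probs = np.full((cv.n_repeats, n), np.nan)
    rep_labels = np.empty((cv.n_repeats, n), dtype=object)
    fold_of = np.full((cv.n_repeats, n), -1)
    sel_rows = []
    for r, rseed in enumerate(cv.repeat_seeds()):
        skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=rseed % (2**32 - 1))
        for fold, (train_rows, test_rows) in enumerate(skf.split(np.zeros(n), labels)):
            prep = TablePreprocessor().fit(table, train_rows)
            Xtr = prep.transform(table, train_rows)
            fold_cfg = MieeConfig(mc.n_subsets, mc.top_k, mc.n_trees,
                                  seed=(mc.seed * 7 + rseed * 31 + fold) % (2**31 - 1))
            res = MIEE(Xtr, labels[train_rows], fold_cfg).fit()
            Xte = prep.transform(table, test_rows)
            p = res.predict_probability(Xte)
            probs[r, test_rows] = p
            rep_labels[r, test_rows] = np.where(
                p >= 0.5, res.minority_label, res.model.majority_label
            )
            fold_of[r, test_rows] = fold
            for si, mem in enumerate(res.members):
                sel_rows += [
                    {"repeat": r, "fold": fold, "subset": si, "feature": f}
                    for f in mem.features
                ]
    votes = (rep_labels == minority).sum(axis=0)
    majority_cls = classes[np.argmax(counts)]
    final = np.where(votes > cv.n_repeats / 2, minority, majority_cls)
    return CVResult(
        participant_ids=ids,
        true_labels=labels,
        probabilities=probs,
        repeat_labels=rep_labels.astype(str),
        final_labels=final.astype(str),
        selections=pd.DataFrame(sel_rows),
        fold_of=fold_of,
        minority_label=str(minority),
    )


def predict_held_out(
    results: MIEEResults,
    preprocessor: TablePreprocessor,
    table: FeatureTable,
    excluded_rows: np.ndarray | list[int],
    reference_probs: np.ndarray,
    reference_labels: np.ndarray,
) -> pd.DataFrame:
    """Score excluded participants with a model trained on the rest.

    Each excluded participant gets the averaged minority probability, the
    implied label, and the percentile of their score among all reference
    participants assigned the same predicted class (weak percentile: the
    maximum scores 100). A single-member or empty reference class is
    flagged.
    """
    from scipy.stats import percentileofscore

    X = preprocessor.transform(table, excluded_rows)
    p = results.predict_probability(X)
    lab = np.where(p >= 0.5, results.minority_label, results.model.majority_label)
    reference_probs = np.asarray(reference_probs)
    reference_labels = np.asarray(reference_labels)
    rows = []
    for pid, pi, li in zip(X.index, p, lab):
        ref = reference_probs[reference_labels == li]
        if ref.size == 0:
            pct, flag = np.nan, "empty-reference-class"
        elif ref.size == 1:
            pct, flag = 100.0, "single-member-reference-class"
        else:
            pct, flag = float(percentileofscore(ref, pi, kind="weak")), ""
        rows.append(
            {"participant": pid, "probability": float(pi), "label": str(li),
             "percentile": pct, "flag": flag}
        )
    return pd.DataFrame(rows)
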