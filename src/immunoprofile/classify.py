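"""Two-stage marker-selection classifier distinguishing PLWH from PWOH.

Stage 1 down-selects markers by repeated recursive feature elimination with
a random-forest learner: each repeat ranks markers, scores a ladder of
subset sizes by stratified k-fold CV-AUC, and records the best-size subset;
markers appearing in the best subset in more than a threshold fraction of
repeats (default 0.90 of 200) survive. If more than 20 survive, the
procedure recurses on the survivors. Stage 2 runs backward elimination
under a super-learner ensemble (random forest, RBF support-vector machine,
extremely randomized trees; convex weights fitted on cross-validated
predictions to maximize CV-AUC), removing redundant markers while the mean
CV-AUC does not degrade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocess import NormalizedMatrix

__all__ = [
    "SelectionFrequencyTable",
    "ClassifierReport",
    "rfe_frequency_selection",
    "backward_superlearner_selection",
    "TwoStageClassifier",
    "cv_auc",
    "rank_auc",
]


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, NormalizedMatrix) else pd.DataFrame(matrix)


def rank_auc(scores, labels) -> float:
    """AUC via the Wilcoxon rank statistic; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    r = stats.rankdata(scores)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def cv_auc(scores, labels, folds: int = 10):
    """Mean cross-validated AUC of a fixed score vector with a normal 95% CI
    from the fold distribution. Folds with a single class are skipped with a
    warning. Returns (mean_auc, (lo, hi))."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    aucs = []
    for _, test in skf.split(scores.reshape(-1, 1), y):
        if len(np.unique(y[test])) < 2:
            warnings.warn("fold with a single class skipped")
            continue
        aucs.append(rank_auc(scores[test], y[test]))
    aucs = np.asarray(aucs)
    mean = float(aucs.mean())
    se = float(aucs.std(ddof=1) / np.sqrt(aucs.size)) if aucs.size > 1 else np.nan
    return mean, (mean - 1.96 * se, mean + 1.96 * se)


def _size_ladder(m: int) -> list[int]:
    sizes = set(range(1, min(10, m) + 1))
    s = m
    while s >= 1:
        sizes.add(s)
        s //= 2
    return sorted(sizes, reverse=True)


def _effective_folds(y, k):
    smallest = min(int(y.sum()), int(len(y) - y.sum()))
    if smallest < k:
        warnings.warn(f"reducing folds from {k} to {smallest}")
        return max(2, smallest)
    return k


@dataclass
class SelectionFrequencyTable:
    """Per-marker appearance frequency in the best subset across repeats."""

    counts: pd.Series
    repeats: int
    threshold: float

    @property
    def frequencies(self) -> pd.Series:
        return self.counts / self.repeats

    def selected(self) -> list:
        f = self.frequencies
        return list(f[f > self.threshold].index)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": self.counts, "frequency": self.frequencies,
             "selected": self.frequencies > self.threshold}
        ).sort_values("frequency", ascending=False)


def rfe_frequency_selection(
    matrix,
    labels,
    repeats: int = 200,
    k_folds: int = 10,
    threshold: float = 0.90,
    seed: int | None = None,
    n_estimators: int = 60,
    recurse_limit: int = 20,
    _depth: int = 0,
) -> SelectionFrequencyTable:
    """Stage-1 selection: repeated RFE with random forests.

    Per repeat: rank markers by full-data random-forest importance, score
    every ladder size (m halved down to 1, plus sizes 1-10) by stratified
    k-fold CV-AUC of a random forest refit on the top-size markers, and keep
    the size maximizing CV-AUC (ties to the smaller size). Marker counts are
    tallied over the best subsets of all repeats.
    """
    df = _as_frame(matrix)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 markers")
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    k = _effective_folds(y, k_folds)
    X = df.to_numpy(dtype=float)
    m = X.shape[1]
    ladder = _size_ladder(m)
    ss = np.random.SeedSequence(seed)
    counts = pd.Series(0, index=df.columns, dtype=int)

    for rep_seed in ss.spawn(repeats):
        rng = np.random.default_rng(rep_seed)
        rs = int(rng.integers(2**31 - 1))
        rf = RandomForestClassifier(n_estimators=n_estimators, random_state=rs)
        rf.fit(X, y)
        order = np.argsort(-rf.feature_importances_)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        fold_scores = np.zeros((len(ladder), k))
        for f, (tr, te) in enumerate(skf.split(X, y)):
            for si, size in enumerate(ladder):
                cols = order[:size]
                clf = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=rs
                )
                clf.fit(X[np.ix_(tr, cols)], y[tr])
                prob = clf.predict_proba(X[np.ix_(te, cols)])[:, 1]
                fold_scores[si, f] = rank_auc(prob, y[te])
        mean_scores = fold_scores.mean(axis=1)
        # ties to the smaller size: ladder is descending, so take the last argmax
        best = len(mean_scores) - 1 - int(np.argmax(mean_scores[::-1]))
        counts[df.columns[order[: ladder[best]]]] += 1

    table = SelectionFrequencyTable(counts, repeats, threshold)
    selected = table.selected()
    if len(selected) > recurse_limit and _depth < 3 and len(selected) < m:
        return rfe_frequency_selection(
            df[selected], labels, repeats, k_folds, threshold, seed,
            n_estimators, recurse_limit, _depth + 1,
        )
    return table


def _rank01(v: np.ndarray) -> np.ndarray:
    n = v.size
    if n == 1:
        return np.array([0.5])
    return (stats.rankdata(v) - 1.0) / (n - 1.0)


def _simplex_grid(step: float = 0.05):
    ws = []
    k = int(round(1 / step))
    for i in range(k + 1):
        for j in range(k + 1 - i):
            ws.append((i * step, j * step, 1.0 - i * step - j * step))
    return np.asarray(ws)


class SuperLearner:
    """Convex blend of random forest, RBF-SVM, and extremely randomized trees.

    Base-learner scores are rank-scaled to [0, 1] before blending; weights
    are chosen on the 2-simplex (grid resolution 0.05) to maximize the AUC
    of the blended cross-validated predictions.
    """

    def __init__(self, k_folds: int = 10, n_estimators: int = 100,
                 random_state: int = 0):
        self.k_folds = k_folds
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.weights_ = None

    def _learners(self):
        rs = self.random_state
        return [
            RandomForestClassifier(n_estimators=self.n_estimators, random_state=rs),
            SVC(kernel="rbf", gamma="scale", random_state=rs),
            ExtraTreesClassifier(n_estimators=self.n_estimators, random_state=rs),
        ]

    def _scores(self, clf, X):
        if hasattr(clf, "predict_proba"):
            return clf.predict_proba(X)[:, 1]
        return clf.decision_function(X)

    def cv_predictions(self, X, y):
        """Out-of-fold predictions of each base learner, rank-scaled per fold."""
        k = _effective_folds(y, self.k_folds)
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=self.random_state)
        preds = np.zeros((len(y), 3))
        fold_of = np.zeros(len(y), dtype=int)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            fold_of[te] = f
            for li, clf in enumerate(self._learners()):
                clf.fit(X[tr], y[tr])
                preds[te, li] = _rank01(self._scores(clf, X[te]))
        return preds, fold_of

    @staticmethod
    def _best_weights(preds, y):
        best_auc, best_w = -np.inf, None
        for w in _simplex_grid():
            auc = rank_auc(preds @ w, y)
            if auc > best_auc + 1e-12:
                best_auc, best_w = auc, w
        return np.asarray(best_w), best_auc

    def fit_weights(self, preds, y):
        self.weights_, best_auc = self._best_weights(preds, y)
        return best_auc

    def cv_auc(self, X, y):
        """Fold-wise AUC of the weighted blend.

        The weights scoring fold f are fitted on the out-of-fold predictions
        of the other folds only (leave-one-fold-out), so the fold AUCs carry
        no weight-fitting optimism; ``weights_`` keeps the all-fold weights
        for reporting. Returns (fold AUCs, blended preds).
        """
        preds, fold_of = self.cv_predictions(X, y)
        self.fit_weights(preds, y)
        aucs = []
        blend = np.zeros(len(y))
        for f in np.unique(fold_of):
            te = fold_of == f
            w, _ = self._best_weights(preds[~te], y[~te])
            blend[te] = preds[te] @ w
            if len(np.unique(y[te])) < 2:
                continue
            aucs.append(rank_auc(blend[te], y[te]))
        return np.asarray(aucs), blend


def _evaluate_set(X, y, k_folds, repeats, seed, n_estimators=100):
    """Mean CV-AUC of a candidate set over repeated super-learner CV."""
    ss = np.random.SeedSequence(seed)
    repeat_means = []
    blends = []
    for rep in ss.spawn(repeats):
        rs = int(np.random.default_rng(rep).integers(2**31 - 1))
        sl = SuperLearner(k_folds, n_estimators, random_state=rs)
        aucs, blend = sl.cv_auc(X, y)
        repeat_means.append(aucs.mean())
        blends.append(blend)
    return np.asarray(repeat_means), np.mean(blends, axis=0)


@dataclass
class ClassifierReport:
    """Final marker subset with its cross-validated performance."""

    selected_stage1: list
    selected: list
    cv_auc: float
    ci: tuple
    roc: pd.DataFrame
    k_folds: int
    repeats: int
    frequency_table: SelectionFrequencyTable | None = None
    elimination_path: list = field(default_factory=list)

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "n_selected_stage1": len(self.selected_stage1),
                "selected": ", ".join(map(str, self.selected)),
                "cv_auc": self.cv_auc,
                "ci_lower": self.ci[0],
                "ci_upper": self.ci[1],
                "k_folds": self.k_folds,
                "repeats": self.repeats,
            }
        )


def backward_superlearner_selection(
    matrix,
    labels,
    candidates,
    k_folds: int = 10,
    repeats: int = 30,
    seed: int | None = None,
    n_estimators: int = 100,
) -> ClassifierReport:
    """Stage-2 backward elimination under super-learner CV-AUC.

    At each step the marker whose removal maximizes the mean CV-AUC is
    dropped, as long as removal does not decrease the mean CV-AUC; the 95%
    CI comes from the normal approximation over the repeat means.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be nonempty")
    df = _as_frame(matrix)
    y = np.asarray(labels).astype(int)
    current = candidates[:]
    ss = np.random.SeedSequence(seed)
    search_ss, final_ss = ss.spawn(2)
    eval_seed = int(np.random.default_rng(search_ss).integers(2**31 - 1))
    final_seed = int(np.random.default_rng(final_ss).integers(2**31 - 1))

    means, _ = _evaluate_set(df[current].to_numpy(), y, k_folds, repeats,
                             eval_seed, n_estimators)
    search_auc = float(means.mean())
    path = [(tuple(current), search_auc)]

    while len(current) > 1:
        trial = []
        for i, mk in enumerate(current):
            subset = current[:i] + current[i + 1:]
            m_i, _ = _evaluate_set(df[subset].to_numpy(), y, k_folds,
                                   repeats, eval_seed, n_estimators)
            trial.append((float(m_i.mean()), mk, subset))
        best = max(trial, key=lambda t: t[0])
        if best[0] >= search_auc:
            search_auc = best[0]
            current = best[2]
            path.append((tuple(current), search_auc))
        else:
            break

    # The search maximizes CV-AUC over subsets, which biases the maximized
    # value upward; the reported performance is a fresh cross-validation of
    # the final subset on folds the search never saw.
    final_means, final_blend = _evaluate_set(
        df[current].to_numpy(), y, k_folds, repeats, final_seed, n_estimators
    )
    final_auc = float(final_means.mean())
    se = final_means.std(ddof=1) / np.sqrt(final_means.size) \
        if final_means.size > 1 else 0.0
    ci = (final_auc - 1.96 * se, final_auc + 1.96 * se)
    fpr, tpr, _ = roc_curve(y, final_blend)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return ClassifierReport(candidates, current, final_auc, ci, roc,
                            k_folds, repeats, elimination_path=path)


class TwoStageClassifier:
    """Model object running both selection stages on a marker matrix."""

    def __init__(self, matrix, labels, repeats: int = 200, k_folds: int = 10,
                 threshold: float = 0.90, backward_repeats: int = 30,
                 n_estimators: int = 60, seed: int | None = None):
        self.matrix = _as_frame(matrix)
        self.labels = np.asarray(labels).astype(int)
        self.repeats = repeats
        self.k_folds = k_folds
        self.threshold = threshold
        self.backward_repeats = backward_repeats
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self) -> ClassifierReport:
        ss = np.random.SeedSequence(self.seed)
        s1, s2 = (int(np.random.default_rng(c).integers(2**31 - 1))
                  for c in ss.spawn(2))
        table = rfe_frequency_selection(
            self.matrix, self.labels, self.repeats, self.k_folds,
            self.threshold, s1, self.n_estimators,
        )
        selected = table.selected()
        if not selected:
            # no marker is stably selected; fall back to the top-frequency one
            selected = [table.frequencies.idxmax()]
        report = backward_superlearner_selection(
            self.matrix, self.labels, selected, self.k_folds,
            self.backward_repeats, s2,
        )
        report.frequency_table = table
        report.selected_stage1 = selected
        return report
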