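"""Immunotherapy-response modelling: mRMR selection inside cross-validation,
balanced-accuracy sweep over the number of kept features, boosted-trees
classification, and occurrence/rank aggregation of the selected features.

The protocol, sized for small cohorts (tens of patients):

1. stratified 3-fold cross-validation (train = 2/3, test = 1/3);
2. inside each training fold: median imputation, then greedy mRMR ranking
   of the candidate features;
3. for each N in the sweep range, an XGBoost classifier with default
   hyperparameters is fit on the top-N features of the fold ranking and
   scored by balanced accuracy on the held-out test fold; N_best is the N
   with the best fold-averaged balanced accuracy (smallest N on ties);
4. the per-fold top-N_best feature lists are aggregated: each feature gets
   an occurrence count c (in how many folds it was selected) and a rank
   score s = log10(sum over folds of 10^(N_best - rank)), so features
   selected earlier in a fold dominate by whole decades; features are
   ranked by (c, s) descending.

Everything that learns from data (imputation medians, selection, model
fitting) sees the training fold only.

The mRMR variant is FCQ-style: relevance is the one-way ANOVA F statistic
of a feature against the binary label, redundancy the mean absolute Pearson
correlation with the already-selected features, and the greedy step picks
the feature maximizing relevance / redundancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.metrics import balanced_accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

__all__ = [
    "CVPlan",
    "SelectionResult",
    "SelectionAggregate",
    "SweepResult",
    "EvalResult",
    "median_impute",
    "mrmr_select",
    "sweep_n_features",
    "aggregate_scores",
    "fit_and_evaluate",
    "feature_group_test",
]

#: Floor on the mean absolute correlation in the mRMR quotient, so that a
#: feature uncorrelated with everything selected is not boosted without bound.
_REDUNDANCY_FLOOR = 0.01


@dataclass
class CVPlan:
    """Stratified L-fold cross-validation plan (default L = 3)."""

    n_folds: int = 3
    seed: int = 0

    def splits(self, labels: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        labels = np.asarray(labels)
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        out = []
        for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
            for part, nm in ((train_idx, "train"), (test_idx, "test")):
                if len(np.unique(labels[part])) < 2:
                    raise ValueError(
                        f"degenerate {nm} fold: only one label present; "
                        "cohort too small or too imbalanced for this plan"
                    )
            out.append((train_idx, test_idx))
        return out


@dataclass
class SelectionResult:
    """Per-split ordered selected-feature lists (rank 1 = first selected)."""

    per_split: list[list[str]]
    n_best: int

    def __post_init__(self) -> None:
        for lst in self.per_split:
            if len(lst) != self.n_best:
                raise ValueError("each split list must have exactly n_best features")
            if len(set(lst)) != len(lst):
                raise ValueError("duplicate features within a split list")


@dataclass
class SelectionAggregate:
    """Occurrence counts and rank scores aggregated over CV splits."""

    counts: dict[str, int]
    scores: dict[str, float]
    ranking: list[str]  # by (count desc, score desc, name)
    n_best: int
    n_splits: int


@dataclass
class SweepResult:
    n_values: list[int]
    mean_balanced_accuracy: list[float]
    n_best: int
    selection: SelectionResult


@dataclass
class EvalResult:
    fold_aucs: list[float]
    mean_auc: float
    std_auc: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    fold_curves: list[tuple[np.ndarray, np.ndarray]]


def median_impute(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[pd.DataFrame, ...]:
    """Fill NaNs with the train-fold column medians (0 if a column is all-NaN)."""
    med = train.median(numeric_only=True)
    med = med.fillna(0.0)
    filled = tuple(df.fillna(med).fillna(0.0) for df in (train, *others))
    return filled


def _relevance(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """ANOVA F statistic per feature; constant features get relevance 0."""
    import warnings

    with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore", UserWarning)
        f_vals, _ = f_classif(X.to_numpy(dtype=float), y)
    return np.nan_to_num(f_vals, nan=0.0, posinf=np.finfo(float).max / 1e6)


def mrmr_select(feature_table: pd.DataFrame, labels, n: int) -> list[str]:
    """Greedy FCQ-style mRMR ranking of the top-n features.

    Step 1 picks the most relevant feature; step t maximizes
    relevance / mean(|Pearson corr| with the selected set).  Deterministic:
    ties resolve to the earliest column.  NaNs are median-imputed on the
    given table before scoring (callers doing cross-validation should impute
    with train-fold medians beforehand).
    """
    y = np.asarray(labels)
    if n < 1 or n > feature_table.shape[1]:
        raise ValueError(
            f"n must be in [1, {feature_table.shape[1]}], got {n}"
        )
    X = feature_table.astype(float)
    if X.isna().any().any():
        (X,) = median_impute(X)
    cols = list(X.columns)
    rel = _relevance(X, y)

    mat = X.to_numpy(dtype=float)
    sd = mat.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zs = (mat - mat.mean(axis=0)) / sd
    zs[:, sd == 0] = 0.0  # constant features: zero correlation with anything

    selected: list[int] = []
    remaining = list(range(len(cols)))
    abs_corr_sum = np.zeros(len(cols))
    first = int(np.argmax(rel))
    selected.append(first)
    remaining.remove(first)
    while len(selected) < n:
        last = selected[-1]
        corr_last = np.abs(zs.T @ zs[:, last]) / len(y)
        abs_corr_sum += corr_last
        mean_red = abs_corr_sum / len(selected)
        score = rel / np.maximum(mean_red, _REDUNDANCY_FLOOR)
        score[selected] = -np.inf
        nxt = int(np.argmax(score))
        selected.append(nxt)
        remaining.remove(nxt)
    return [cols[i] for i in selected]


def _default_xgb(seed: int) -> XGBClassifier:
    # default hyperparameters; only determinism/threading knobs are pinned
    return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss")


def sweep_n_features(
    cohort_features: pd.DataFrame,
    labels,
    plan: CVPlan | None = None,
    n_range: list[int] | None = None,
) -> SweepResult:
    """Fold-averaged balanced accuracy for each candidate N; returns N_best.

    Selection, imputation and model fitting all happen inside the training
    fold.  The greedy mRMR ranking is nested, so one ranking per fold serves
    every N.  N_best is the smallest N achieving the maximal mean balanced
    accuracy; the per-fold top-N_best lists are returned as the
    SelectionResult for aggregation.
    """
    plan = plan or CVPlan()
    y = np.asarray(labels)
    n_features = cohort_features.shape[1]
    if n_range is None:
        n_range = list(range(1, n_features + 1))
    n_range = sorted(set(int(n) for n in n_range))
    if n_range[0] < 1 or n_range[-1] > n_features:
        raise ValueError(f"n_range must lie within [1, {n_features}]")
    n_max = n_range[-1]

    fold_rankings: list[list[str]] = []
    acc = np.zeros((plan.n_folds, len(n_range)))
    for k, (tr, te) in enumerate(plan.splits(y)):
        X_tr, X_te = median_impute(
            cohort_features.iloc[tr], cohort_features.iloc[te]
        )
        ranking = mrmr_select(X_tr, y[tr], n_max)
        fold_rankings.append(ranking)
        for j, n in enumerate(n_range):
            feats = ranking[:n]
            model = _default_xgb(plan.seed)
            model.fit(X_tr[feats], y[tr])
            acc[k, j] = balanced_accuracy_score(y[te], model.predict(X_te[feats]))
    mean_acc = acc.mean(axis=0)
    n_best = n_range[int(np.argmax(mean_acc))]
    selection = SelectionResult(
        per_split=[r[:n_best] for r in fold_rankings], n_best=n_best
    )
    return SweepResult(
        n_values=n_range,
        mean_balanced_accuracy=list(mean_acc),
        n_best=n_best,
        selection=selection,
    )


def aggregate_scores(selection: SelectionResult) -> SelectionAggregate:
    """Occurrence counts c and rank scores s over the CV splits.

    c_f counts the splits whose selected list contains f.  With 1-based
    ranks, a feature's pre-score in a split is 10^(N_best - rank) and
    s_f = log10(sum of pre-scores over the splits containing f), so a
    feature ranked first everywhere scores ~ N_best - 1 + log10(L).  The
    ranking orders by count, then score, descending (name as final,
    order-stable tiebreak).
    """
    n_best = selection.n_best
    counts: dict[str, int] = {}
    scores: dict[str, float] = {}
    pre_sums: dict[str, float] = {}
    for split in selection.per_split:
        for rank, feat in enumerate(split, start=1):
            counts[feat] = counts.get(feat, 0) + 1
            pre_sums[feat] = pre_sums.get(feat, 0.0) + 10.0 ** (n_best - rank)
    for feat, total in pre_sums.items():
        scores[feat] = math.log10(total)
    ranking = sorted(counts, key=lambda f: (-counts[f], -scores[f], f))
    return SelectionAggregate(
        counts=counts,
        scores=scores,
        ranking=ranking,
        n_best=n_best,
        n_splits=len(selection.per_split),
    )


def fit_and_evaluate(
    cohort_features: pd.DataFrame,
    labels,
    plan: CVPlan | None = None,
    n_best: int = 19,
) -> EvalResult:
    """Per-fold ROC of the top-n_best classifier and the vertically averaged
    mean curve; reports mean AUROC and its standard deviation over folds."""
    plan = plan or CVPlan()
    y = np.asarray(labels)
    grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    aucs = []
    curves = []
    for tr, te in plan.splits(y):
        X_tr, X_te = median_impute(
            cohort_features.iloc[tr], cohort_features.iloc[te]
        )
        feats = mrmr_select(X_tr, y[tr], n_best)
        model = _default_xgb(plan.seed)
        model.fit(X_tr[feats], y[tr])
        prob = model.predict_proba(X_te[feats])[:, 1]
        fpr, tpr, _ = roc_curve(y[te], prob)
        curves.append((fpr, tpr))
        aucs.append(float(roc_auc_score(y[te], prob)))
        tprs.append(np.interp(grid, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return EvalResult(
        fold_aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        std_auc=float(np.std(aucs)),
        fpr_grid=grid,
        mean_tpr=mean_tpr,
        fold_curves=curves,
    )


def feature_group_test(values, labels) -> tuple[float, float]:
    """Convenience Mann-Whitney U test of one feature between the two groups.

    Returns (U, p).  NaNs are dropped pairwise.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    ok = np.isfinite(v)
    a = v[ok & (y == 1)]
    b = v[ok & (y == 0)]
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
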