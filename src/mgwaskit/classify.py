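"""Random-forest case/control classification with importance-ranked subsets.

Features are abundance profiles (features x samples). Importance is
permutation-based mean decrease in accuracy; model performance is the AUC of
pooled out-of-fold scores under repeated stratified cross-validation, with a
percentile-bootstrap confidence interval.

Note: the feature ranking is computed once on the full data, which
optimistically biases the subset curve; reports carry a flag saying so and
``subset_auc_curve`` accepts externally supplied (e.g. nested) rankings.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedStratifiedKFold

logger = logging.getLogger(__name__)

DEFAULT_SUBSET_SIZES = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 30, 40, 60, 80, 100]


def _xy(features: pd.DataFrame, cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = features.T.to_numpy(dtype=float)
    y = (cohort.loc[features.columns, "group"] == "case").to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return x, y


def rf_importance(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    n_trees: int = 10000,
    seed: int | None = None,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Rank features by permutation mean-decrease-accuracy importance.

    A seeded forest is fit on all samples; each feature column is permuted
    ``n_repeats`` times and the mean accuracy drop is its importance.
    Ties are broken by feature id.
    """
    x, y = _xy(features, cohort)
    if min(np.bincount(y)) < 5:
        raise ValueError("need >= 5 samples per group")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(x, y)
    imp = permutation_importance(
        forest, x, y, scoring="accuracy", n_repeats=n_repeats, random_state=seed
    )
    table = pd.DataFrame(
        {"feature_id": features.index, "importance": imp.importances_mean}
    ).sort_values(["importance", "feature_id"], ascending=[False, True], kind="mergesort")
    return table.reset_index(drop=True).set_index("feature_id", drop=False)


def cv_scores(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    n_trees: int = 500,
    cv_folds: int = 5,
    cv_repeats: int = 10,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold case probabilities under repeated stratified CV.

    Returns (scores, labels); each sample contributes ``cv_repeats``
    out-of-fold predictions to the pool.
    """
    x, y = _xy(features, cohort)
    n_min = min(np.bincount(y))
    folds = min(cv_folds, n_min)
    if folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=cv_repeats, random_state=seed)
    scores, labels = [], []
    for fold_i, (train, test) in enumerate(splitter.split(x, y)):
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=None if seed is None else seed + fold_i
        )
        forest.fit(x[train], y[train])
        scores.append(forest.predict_proba(x[test])[:, 1])
        labels.append(y[test])
    return np.concatenate(scores), np.concatenate(labels)


def auc_rank(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formulation; ties count 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def subset_auc_curve(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    ranking: list[str],
    sizes: list[int] | None = None,
    cv_folds: int = 5,
    cv_repeats: int = 10,
    n_trees: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cross-validated AUC for top-k feature subsets along the ranking.

    Returns a table (size, auc), sizes strictly increasing and truncated to
    the number of available features.
    """
    sizes = sorted({s for s in (sizes or DEFAULT_SUBSET_SIZES) if 1 <= s <= len(ranking)})
    if not sizes:
        raise ValueError("no valid subset sizes")
    rows = []
    for k in sizes:
        subset = features.loc[ranking[:k]]
        scores, labels = cv_scores(
            subset, cohort, n_trees=n_trees, cv_folds=cv_folds, cv_repeats=cv_repeats, seed=seed
        )
        rows.append({"size": k, "auc": auc_rank(scores, labels)})
    return pd.DataFrame(rows)


def roc_auc_ci(
    scores, labels, n_boot: int = 10000, seed: int | None = None
) -> tuple[float, float, float, pd.DataFrame]:
    """AUC with a stratified percentile-bootstrap 95% CI and ROC points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = auc_rank(scores, labels)
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.flatnonzero(labels == 1), np.flatnonzero(labels == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        boot[b] = auc_rank(scores[idx], labels[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return auc, float(lo), float(hi), roc


def classifier_report(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    sizes: list[int] | None = None,
    n_trees: int = 500,
    n_boot: int = 1000,
    cv_folds: int = 5,
    cv_repeats: int = 10,
    seed: int | None = None,
) -> dict:
    """Full classification report: ranking, AUC curve, best subset, ROC + CI."""
    ranking = rf_importance(features, cohort, n_trees=n_trees, seed=seed)
    ranked_ids = list(ranking["feature_id"])
    curve = subset_auc_curve(
        features, cohort, ranked_ids, sizes=sizes,
        cv_folds=cv_folds, cv_repeats=cv_repeats, n_trees=n_trees, seed=seed,
    )
    best_row = curve.loc[curve["auc"].idxmax()]
    best_size = int(best_row["size"])
    scores, labels = cv_scores(
        features.loc[ranked_ids[:best_size]], cohort,
        n_trees=n_trees, cv_folds=cv_folds, cv_repeats=cv_repeats, seed=seed,
    )
    auc, lo, hi, roc = roc_auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    return {
        "ranking": ranked_ids,
        "importance": ranking["importance"].tolist(),
        "auc_curve": curve.to_dict(orient="records"),
        "best_size": best_size,
        "auc": auc,
        "ci_low": lo,
        "ci_high": hi,
        "roc_points": roc.to_dict(orient="records"),
        "cv": {"folds": cv_folds, "repeats": cv_repeats, "n_trees": n_trees},
        "ranking_note": "feature ranking computed once on the full data (optimistic bias)",
    }


def classify_with_covariate(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    covariate: str = "pbmi",
    n_trees: int = 500,
    cv_folds: int = 5,
    cv_repeats: int = 10,
    seed: int | None = None,
) -> dict:
    """AUCs of covariate-alone, features-alone, and features+covariate models."""
    if covariate not in cohort.columns:
        raise ValueError(f"covariate {covariate!r} not in cohort")
    cov_row = pd.DataFrame(
        [cohort.loc[features.columns, covariate].to_numpy(dtype=float)],
        index=[covariate], columns=features.columns,
    )
    combined = pd.concat([features, cov_row])
    out = {}
    for name, mat in [("covariate", cov_row), ("features", features), ("combined", combined)]:
        scores, labels = cv_scores(
            mat, cohort, n_trees=n_trees, cv_folds=cv_folds, cv_repeats=cv_repeats, seed=seed
        )
        out[name] = auc_rank(scores, labels)
    return out
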