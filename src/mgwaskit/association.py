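"""Phenotype-level statistics on MLG and taxon profiles.

Co-occurrence network of MLG abundances, gross abundance ratio against
glucose, per-feature phenotype correlations, Bray-Curtis distances, a
permutation MANOVA on the distance matrix, and distance-based redundancy
analysis constrained on case status.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["glucose_0", "glucose_60", "glucose_120", "pbmi", "age"]
EXACT_SPEARMAN_MAX_N = 9


def spearman_rho_p(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p.

    Exact p by enumeration of all rank permutations for n <= 9, otherwise
    the t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        # exhaustive permutation null of the rank correlation
        null = np.array([np.corrcoef(rx, ry[list(perm)])[0, 1]
                         for perm in itertools.permutations(range(n))])
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def mlg_network(mlg_abund: pd.DataFrame, rho_cut: float = 0.4) -> pd.DataFrame:
    """Spearman co-occurrence edges: all unordered MLG pairs with |rho| > rho_cut.

    Computed over all samples, both groups pooled. Pairs involving a
    constant profile are skipped with a warning.
    """
    if mlg_abund.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    ids = list(mlg_abund.index)
    ranks = stats.rankdata(mlg_abund.to_numpy(dtype=float), axis=1)
    constant = ranks.std(axis=1) == 0
    if constant.any():
        logger.warning("skipping %d constant MLG profile(s): %s",
                       int(constant.sum()), [ids[i] for i in np.flatnonzero(constant)[:5]])
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    edges = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        if constant[i] or constant[j]:
            continue
        r = rho[i, j]
        if abs(r) > rho_cut:
            a, b = sorted((ids[i], ids[j]))
            edges.append({"mlg_a": a, "mlg_b": b, "rho": float(r),
                          "sign": "positive" if r > 0 else "negative"})
    return pd.DataFrame(edges, columns=["mlg_a", "mlg_b", "rho", "sign"])


def network_to_graphml(edges: pd.DataFrame, path) -> None:
    import networkx as nx

    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["mlg_a"], row["mlg_b"], rho=float(row["rho"]), sign=row["sign"])
    nx.write_graphml(g, path)


def gross_abundance_ratio(mlg_abund: pd.DataFrame, directions: pd.Series) -> pd.Series:
    """Per-sample ratio of summed case-enriched to summed control-enriched abundance."""
    directions = directions.reindex(mlg_abund.index)
    case_ids = directions[directions == "case-enriched"].index
    ctrl_ids = directions[directions == "control-enriched"].index
    if len(case_ids) == 0 or len(ctrl_ids) == 0:
        raise ValueError("need at least one MLG in each enrichment direction")
    num = mlg_abund.loc[case_ids].sum(axis=0)
    den = mlg_abund.loc[ctrl_ids].sum(axis=0)
    zero = den == 0
    if zero.any():
        logger.warning("%d sample(s) with zero control-enriched abundance -> missing ratio",
                       int(zero.sum()))
    return (num / den.where(~zero)).rename("gross_abundance_ratio")


def feature_phenotype_correlation(
    abund: pd.DataFrame,
    cohort: pd.DataFrame,
    min_mean_abund: float = 1e-5,
    phenotypes: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each feature with each phenotype.

    Returns a long table (feature, phenotype, rho, p, mark) with marks '+'
    for p < 0.05 and '++' for p < 0.01. Features are kept only if their mean
    abundance reaches ``min_mean_abund`` and at least one phenotype
    correlates at p < 0.05. All-missing phenotypes are skipped.
    """
    phenotypes = phenotypes or [c for c in PHENOTYPE_COLUMNS if c in cohort.columns]
    pheno = cohort.loc[abund.columns, phenotypes]
    usable = []
    for col in phenotypes:
        if pheno[col].notna().sum() < 3:
            logger.warning("phenotype %s is all-missing or too sparse; skipped", col)
        else:
            usable.append(col)

    keep = abund.mean(axis=1) >= min_mean_abund
    rows = []
    for feat in abund.index[keep]:
        vals = abund.loc[feat]
        feat_rows = []
        for col in usable:
            mask = pheno[col].notna()
            rho, p = spearman_rho_p(vals[mask.index[mask]], pheno.loc[mask, col])
            mark = "++" if p < 0.01 else ("+" if p < 0.05 else "")
            feat_rows.append({"feature_id": feat, "phenotype": col, "rho": rho, "p": p, "mark": mark})
        if any(r["mark"] for r in feat_rows):
            rows.extend(feat_rows)
    return pd.DataFrame(rows, columns=["feature_id", "phenotype", "rho", "p", "mark"])


def bray_curtis(abund: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distance matrix between sample columns."""
    x = abund.to_numpy(dtype=float).T  # samples x features
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("distance undefined between two all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=1.0)  # all-zero vs non-zero -> maximal dissimilarity
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=abund.columns, columns=abund.columns)


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = len(labels)
    sst = d2.sum() / (2 * n)
    ssw = 0.0
    for g in np.unique(labels):
        mask = labels == g
        ssw += d2[np.ix_(mask, mask)].sum() / (2 * mask.sum())
    return sst - ssw, ssw


def permanova_pseudo_f(dist: pd.DataFrame, labels: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from a distance matrix and group labels."""
    d2 = dist.to_numpy(dtype=float) ** 2
    groups = np.unique(labels)
    a, n = len(groups), len(labels)
    ssa, ssw = _permanova_ss(d2, labels)
    return (ssa / (a - 1)) / (ssw / (n - a))


def permanova(
    dist: pd.DataFrame, cohort: pd.DataFrame, n_perm: int = 10000, seed: int | None = None
) -> tuple[float, float]:
    """Permutation test of group separation in a distance matrix.

    Returns (pseudo_F, p) with ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    labels = cohort.loc[dist.index, "group"].to_numpy()
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 samples in each of >= 2 groups")
    f_obs = permanova_pseudo_f(dist, labels)
    rng = np.random.default_rng(seed)
    d2 = dist.to_numpy(dtype=float) ** 2
    a, n = len(counts), len(labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ssa, ssw = _permanova_ss(d2, perm)
        f = (ssa / (a - 1)) / (ssw / (n - a))
        if f >= f_obs - 1e-12:
            count += 1
    return f_obs, (1 + count) / (1 + n_perm)


@dataclass
class DbRdaResult:
    scores: pd.Series  # sample scores on the constrained axis
    axis_variance: tuple[float, float]  # fraction of total inertia: constrained, first residual
    loadings: pd.Series | None  # feature correlations with the constrained axis


def dbrda(dist: pd.DataFrame, cohort: pd.DataFrame, features: pd.DataFrame | None = None) -> DbRdaResult:
    """Distance-based redundancy analysis constrained on the group indicator.

    Principal-coordinate embedding of the distance matrix (axes with
    negative eigenvalues are dropped with a warning), followed by a
    redundancy step projecting the coordinates on the centered case/control
    indicator. Feature loadings, if ``features`` is given, are Pearson
    correlations of each feature's abundance with the constrained scores.
    """
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    neg = eigvals < -1e-9 * max(1.0, abs(eigvals[0]))
    if neg.any():
        logger.warning("discarding %d negative PCoA eigenvalue(s)", int(neg.sum()))
    pos = eigvals > 1e-9 * max(1.0, abs(eigvals[0]))
    if pos.sum() < 2:
        raise ValueError("rank-deficient embedding: fewer than 2 positive eigenvalues")
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    total_inertia = eigvals[pos].sum()

    groups = cohort.loc[dist.index, "group"].to_numpy()
    x = (groups == "case").astype(float)
    x = x - x.mean()
    if np.allclose(x, 0):
        raise ValueError("group indicator is constant; nothing to constrain on")
    # fitted coordinates under the single-column constraint
    beta = (x @ coords) / (x @ x)
    fitted = np.outer(x, beta)
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    scores = pd.Series(u[:, 0] * s[0], index=dist.index, name="constrained_axis")
    constrained_var = float(s[0] ** 2 / total_inertia)

    residual = coords - fitted
    s_res = np.linalg.svd(residual, compute_uv=False)
    residual_var = float(s_res[0] ** 2 / total_inertia) if len(s_res) else 0.0

    loadings = None
    if features is not None:
        vals = features.loc[:, dist.index].to_numpy(dtype=float)
        sc = scores.to_numpy()
        sc_c = sc - sc.mean()
        fv = vals - vals.mean(axis=1, keepdims=True)
        denom = np.sqrt((fv**2).sum(axis=1)) * np.sqrt((sc_c**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (fv @ sc_c) / denom
        loadings = pd.Series(corr, index=features.index, name="loading")
    return DbRdaResult(scores=scores, axis_variance=(constrained_var, residual_var), loadings=loadings)
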