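"""Marker-gene discovery: stratification adjustment, rank tests, FDR.

The adjustment follows the EIGENSTRAT idea applied to abundances: gene rows
are standardized, a sample-by-sample covariance is eigendecomposed, and the
top axes are projected out of every gene row before testing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def stratification_adjust(abund: pd.DataFrame, k_axes: int) -> pd.DataFrame:
    """Remove the top `k_axes` covariance eigenvectors from each gene row.

    Rows are centered and scaled to unit variance first (zero-variance rows
    are left centered). Returned rows are orthogonal to the removed axes and
    may contain negative values. ``k_axes=0`` returns the standardized input.
    """
    n_samples = abund.shape[1]
    if k_axes < 0:
        raise ValueError("k_axes must be >= 0")
    if k_axes >= n_samples:
        raise ValueError(f"k_axes={k_axes} must be < n_samples={n_samples}")
    if k_axes > 0 and n_samples < k_axes + 2:
        raise ValueError("need at least k_axes + 2 samples")

    x = abund.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mean) / np.where(sd == 0, 1.0, sd), x - mean)
    if k_axes == 0:
        return pd.DataFrame(z, index=abund.index, columns=abund.columns)

    cov = z.T @ z / z.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    top = eigvecs[:, np.argsort(eigvals)[::-1][:k_axes]]  # n_samples x k
    adjusted = z - (z @ top) @ top.T
    return pd.DataFrame(adjusted, index=abund.index, columns=abund.columns)


def scree_k_axes(abund: pd.DataFrame, max_axes: int = 10) -> int:
    """Heuristic axis count: eigenvalues exceeding twice the median eigenvalue."""
    x = abund.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mean) / np.where(sd == 0, 1.0, sd), x - mean)
    eigvals = np.linalg.eigvalsh(z.T @ z / z.shape[0])[::-1]
    eigvals = eigvals[eigvals > 0]
    if len(eigvals) == 0:
        return 0
    return int(min(max_axes, (eigvals > 2.0 * np.median(eigvals)).sum()))


def mannwhitney_p(x, y) -> float:
    """Two-tailed Mann-Whitney U p-value.

    Exact distribution when n1+n2 <= 12 and there are no ties, otherwise the
    normal approximation with tie and continuity corrections. Complete ties
    (all values equal) return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def mannwhitney(values: pd.Series, cohort: pd.DataFrame) -> float:
    """Mann-Whitney p for a per-sample series split by the cohort's group label."""
    groups = cohort.loc[values.index, "group"]
    return mannwhitney_p(values[groups == "case"], values[groups == "control"])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min over p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def storey_pi0(p_values, lambdas=None) -> float:
    """Estimate the null proportion pi0 by Storey's smoother convention.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` over a lambda grid,
    smoothed with a cubic polynomial and read off at the largest lambda,
    clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    lambdas = np.asarray(lambdas if lambdas is not None else np.arange(0.05, 0.96, 0.05))
    m = len(p)
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, deg=3)
    return float(np.clip(np.polyval(coeffs, lambdas[-1]), 0.0, 1.0))


def save_pvalue_histogram(p_values, path, bins: int = 50) -> float:
    """Write a p-value density histogram with the pi0 reference line; returns pi0."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pi0 = storey_pi0(p_values)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(np.asarray(p_values, dtype=float), bins=bins, density=True,
            color="#7799bb", edgecolor="white")
    ax.axhline(pi0, color="black", linestyle="--", label=f"pi0 = {pi0:.3f}")
    ax.set_xlabel("p-value")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return pi0


def select_markers(
    abund: pd.DataFrame,
    cohort: pd.DataFrame,
    k_axes: int = 2,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Marker table: adjust -> per-gene Mann-Whitney -> BH -> keep q < threshold.

    Zero-variance genes are skipped (reported in the log), not tested.
    Direction comes from the unadjusted group means; the effect column is
    the difference of mean adjusted abundance (case minus control).
    """
    groups = cohort.loc[abund.columns, "group"]
    case_mask = (groups == "case").to_numpy()
    ctrl_mask = (groups == "control").to_numpy()
    if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
        raise ValueError("both case and control groups must be non-empty")

    raw = abund.to_numpy(dtype=float)
    variable = raw.std(axis=1) > 0
    n_skipped = int((~variable).sum())
    if n_skipped:
        logger.info("skipping %d zero-variance genes", n_skipped)
    testable = abund.loc[variable]

    adjusted = stratification_adjust(testable, k_axes)
    adj = adjusted.to_numpy()
    pvals = np.array(
        [mannwhitney_p(adj[i, case_mask], adj[i, ctrl_mask]) for i in range(adj.shape[0])]
    )
    qvals = bh_fdr(pvals)

    raw_sub = testable.to_numpy(dtype=float)
    mean_case_raw = raw_sub[:, case_mask].mean(axis=1)
    mean_ctrl_raw = raw_sub[:, ctrl_mask].mean(axis=1)
    effect = adj[:, case_mask].mean(axis=1) - adj[:, ctrl_mask].mean(axis=1)

    table = pd.DataFrame(
        {
            "gene_id": testable.index,
            "p_value": pvals,
            "q_value": qvals,
            "direction": np.where(
                mean_case_raw >= mean_ctrl_raw, "case-enriched", "control-enriched"
            ),
            "effect": effect,
        }
    ).set_index("gene_id", drop=False)
    markers = table[table["q_value"] < q_threshold].copy()
    logger.info(
        "tested %d genes, skipped %d, selected %d markers at q<%g",
        len(table), n_skipped, len(markers), q_threshold,
    )
    return markers
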