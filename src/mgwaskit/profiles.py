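"""Gene, taxon, and functional relative-abundance profiles plus diversity.

Abundance matrices are pandas DataFrames of features (rows) by samples
(columns). Every aggregation step conserves total abundance 1 per sample by
pooling leftovers into an explicit ``unclassified`` / ``unannotated`` row.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# DNA-identity thresholds for assigning a gene's best genome hit to a rank
RANK_IDENTITY_THRESHOLDS = {"species": 95.0, "genus": 85.0, "phylum": 65.0}
MIN_ALIGNMENT_COVERAGE = 0.70
UNCLASSIFIED = "unclassified"
UNANNOTATED = "unannotated"


def gene_relative_abundance(
    counts: pd.DataFrame, catalog: pd.DataFrame, renormalize: bool = True
) -> pd.DataFrame:
    """Length-corrected relative abundances from unique-read counts.

    ``a_gs = (r_gs / L_g) / sum_g'(r_g's / L_g')`` with columns summing to 1.
    With ``renormalize=False`` the denominator is instead the sample's total
    mapped read count, i.e. the literal reads/(length * total-reads) variant
    without re-normalization.
    """
    missing = counts.index.difference(catalog.index)
    if len(missing) > 0:
        raise ValueError(f"genes missing from catalog: {list(missing[:5])}")
    lengths = catalog.loc[counts.index, "length_bp"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        bad = counts.index[lengths <= 0]
        raise ValueError(f"non-positive gene length for: {list(bad[:5])}")

    rate = counts.to_numpy(dtype=float) / lengths[:, None]
    if renormalize:
        denom = rate.sum(axis=0)
    else:
        denom = counts.to_numpy(dtype=float).sum(axis=0)
    zero_cols = denom == 0
    if zero_cols.any():
        logger.warning(
            "%d sample(s) have zero mapped reads and stay all-zero: %s",
            int(zero_cols.sum()),
            list(counts.columns[zero_cols][:5]),
        )
    denom = np.where(zero_cols, 1.0, denom)
    abund = pd.DataFrame(rate / denom[None, :], index=counts.index, columns=counts.columns)
    abund.index.name = "gene_id"
    return abund


def _rank_assignment(catalog: pd.DataFrame, rank: str) -> pd.Series:
    """Taxon label per gene at `rank`, or UNCLASSIFIED if the hit fails thresholds."""
    if rank not in RANK_IDENTITY_THRESHOLDS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {list(RANK_IDENTITY_THRESHOLDS)}")
    col = {"species": "taxon_id", "genus": "genus", "phylum": "phylum"}[rank]
    ok = (catalog["dna_identity"] >= RANK_IDENTITY_THRESHOLDS[rank]) & (
        catalog["coverage"] >= MIN_ALIGNMENT_COVERAGE
    )
    labels = catalog[col].where(ok, UNCLASSIFIED)
    return labels.fillna(UNCLASSIFIED)


def taxon_profile(abund: pd.DataFrame, catalog: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Aggregate gene abundances to a taxonomic rank.

    A gene contributes to the taxon of its best DNA-identity hit iff the hit
    covers >= 70% of the gene and its identity clears the rank threshold
    (species 95 / genus 85 / phylum 65); everything else pools into
    ``unclassified``. Columns re-sum to 1.
    """
    labels = _rank_assignment(catalog.loc[abund.index], rank)
    out = abund.groupby(labels.to_numpy()).sum()
    out.index.name = rank
    return out.sort_index()


def functional_profile(abund: pd.DataFrame, catalog: pd.DataFrame, level: str) -> pd.DataFrame:
    """Sum gene abundances per functional feature (KO / module / pathway).

    Genes without an assignment pool into ``unannotated``.
    """
    col = {"KO": "ko_id", "ko": "ko_id", "module": "module_id", "pathway": "module_id"}.get(level)
    if col is None:
        raise ValueError(f"unknown functional level {level!r}")
    labels = catalog.loc[abund.index, col]
    labels = labels.where(labels.notna() & (labels.astype(str) != ""), UNANNOTATED)
    out = abund.groupby(labels.to_numpy()).sum()
    out.index.name = level
    return out.sort_index()


def rarefied_gene_count(
    counts: pd.DataFrame, depth: int, draws: int = 30, seed: int | None = None
) -> pd.Series:
    """Mean number of genes detected after subsampling `depth` reads per sample.

    Each draw subsamples ``depth`` reads without replacement from the
    sample's gene-labelled reads (multivariate hypergeometric) and counts
    genes with at least one read; the mean over ``draws`` draws is returned.
    Samples with fewer than ``depth`` total reads are returned as NaN with a
    warning.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    result = {}
    mat = counts.to_numpy(dtype=np.int64)
    for j, sample in enumerate(counts.columns):
        col = mat[:, j]
        total = int(col.sum())
        if total < depth:
            logger.warning("sample %s has %d < %d reads; reported missing", sample, total, depth)
            result[sample] = np.nan
            continue
        if total == depth:
            result[sample] = float((col > 0).sum())
            continue
        nz = col[col > 0]
        hits = 0
        for _ in range(draws):
            sub = rng.multivariate_hypergeometric(nz, depth, method="marginals")
            hits += int((sub > 0).sum())
        result[sample] = hits / draws
    return pd.Series(result, name="rarefied_gene_count")


def shannon_index(abund: pd.DataFrame) -> pd.Series:
    """Shannon diversity ``H = -sum a ln a`` per sample (natural log).

    Zero-abundance features contribute 0; all-zero samples return NaN.
    """
    a = abund.to_numpy(dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundances are not allowed")
    colsum = a.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(a > 0, -a * np.log(a), 0.0)
    h = terms.sum(axis=0)
    h = np.where(colsum == 0, np.nan, h)
    return pd.Series(h, index=abund.columns, name="shannon")


def compare_groups(
    abund: pd.DataFrame, cohort: pd.DataFrame, min_mean_abund: float = 0.0
) -> pd.DataFrame:
    """Per-feature two-group comparison: Mann-Whitney p, BH q, direction.

    Features whose overall mean relative abundance falls below
    ``min_mean_abund`` are excluded before testing.
    """
    from .mgwas import bh_fdr, mannwhitney_p

    groups = cohort.loc[abund.columns, "group"]
    bad = set(groups.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    case_cols = groups[groups == "case"].index
    ctrl_cols = groups[groups == "control"].index
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 samples per group")

    keep = abund.mean(axis=1) >= min_mean_abund
    sub = abund.loc[keep]
    if sub.empty:
        return pd.DataFrame(
            columns=[
                "feature_id", "mean_case", "mean_control",
                "median_case", "median_control", "p", "q", "direction",
            ]
        ).set_index(pd.Index([], name="feature_id"), drop=False)

    case = sub[case_cols].to_numpy(dtype=float)
    ctrl = sub[ctrl_cols].to_numpy(dtype=float)
    pvals = np.array([mannwhitney_p(case[i], ctrl[i]) for i in range(sub.shape[0])])
    qvals = bh_fdr(pvals)
    mean_case, mean_ctrl = case.mean(axis=1), ctrl.mean(axis=1)
    out = pd.DataFrame(
        {
            "feature_id": sub.index,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "median_case": np.median(case, axis=1),
            "median_control": np.median(ctrl, axis=1),
            "p": pvals,
            "q": qvals,
            "direction": np.where(mean_case >= mean_ctrl, "case-enriched", "control-enriched"),
        }
    ).set_index("feature_id", drop=False)
    return out
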