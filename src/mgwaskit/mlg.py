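"""Metagenomic linkage groups: co-abundance clustering of marker genes.

An MLG is a set of marker genes whose abundances co-vary across samples,
serving as a species-level proxy. Clustering is a deterministic greedy
medoid procedure on Spearman correlations: seed with the unclustered gene
of highest mean abundance, gather genes correlated with the seed at
``rho >= rho_min``, re-center on the medoid until stable, and accept the
cluster if it reaches ``min_size`` members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mgwas import mannwhitney_p

logger = logging.getLogger(__name__)

SPECIES_GENE_FRACTION = 0.90
SPECIES_DNA_IDENTITY = 95.0
SPECIES_COVERAGE = 0.70
GENUS_GENE_FRACTION = 0.80
GENUS_IDENTITY = 85.0  # required of both DNA and protein identity
MAX_MEDOID_ITER = 20


@dataclass
class TaxonomyCall:
    rank: str  # "species" | "genus" | "unclassified"
    taxon: str | None
    fraction: float


@dataclass
class MLG:
    mlg_id: str
    members: list[str]
    taxonomy: TaxonomyCall | None = None
    direction: str = "none"
    p_value: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.members)


def _spearman_matrix(abund: pd.DataFrame) -> np.ndarray:
    ranks = stats.rankdata(abund.to_numpy(dtype=float), axis=1)  # average ranks for ties
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    return np.nan_to_num(rho, nan=0.0)  # constant rows correlate with nothing


def cluster_mlgs(
    abund: pd.DataFrame,
    rho_min: float = 0.7,
    min_size: int = 5,
    seed: int | None = None,
) -> tuple[list[MLG], list[str]]:
    """Greedy medoid clustering of marker genes on Spearman correlation.

    Returns the accepted MLGs (ids assigned in discovery order) and the list
    of unclustered gene ids. Deterministic given the data: seeds are chosen
    by descending mean abundance with gene-id tie-break, and the medoid is
    the member maximizing summed correlation to the other members. The
    ``seed`` argument is accepted for interface symmetry; the procedure
    itself is deterministic.
    """
    if not 0 < rho_min <= 1:
        raise ValueError("rho_min must lie in (0, 1]")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if abund.shape[1] < 8:
        raise ValueError("need >= 8 samples for co-abundance clustering")
    if abund.shape[0] < min_size:
        return [], list(abund.index)

    gene_ids = abund.index.to_numpy()
    # canonical gene order: mean abundance desc, gene id asc
    order = sorted(range(len(gene_ids)), key=lambda i: (-abund.iloc[i].mean(), gene_ids[i]))
    rho = _spearman_matrix(abund)

    available = np.ones(len(gene_ids), dtype=bool)
    exhausted = np.zeros(len(gene_ids), dtype=bool)  # failed seeds, never reused as seeds
    mlgs: list[MLG] = []

    while True:
        seed_idx = next((i for i in order if available[i] and not exhausted[i]), None)
        if seed_idx is None:
            break
        members = _gather(rho, seed_idx, available, rho_min)
        medoid = seed_idx
        for _ in range(MAX_MEDOID_ITER):
            new_medoid = _medoid(rho, members, gene_ids)
            new_members = _gather(rho, new_medoid, available, rho_min)
            if new_medoid == medoid and np.array_equal(new_members, members):
                break
            medoid, members = new_medoid, new_members
        if len(members) >= min_size:
            member_ids = sorted(gene_ids[members])
            mlgs.append(MLG(mlg_id=f"MLG{len(mlgs) + 1:04d}", members=member_ids))
            available[members] = False
        else:
            exhausted[seed_idx] = True

    unclustered = sorted(gene_ids[available])
    logger.info("clustered %d genes into %d MLGs; %d unclustered",
                int((~available).sum()), len(mlgs), len(unclustered))
    return mlgs, unclustered


def _gather(rho: np.ndarray, center: int, available: np.ndarray, rho_min: float) -> np.ndarray:
    mask = available & (rho[center] >= rho_min)
    mask[center] = available[center]
    return np.flatnonzero(mask)


def _medoid(rho: np.ndarray, members: np.ndarray, gene_ids: np.ndarray) -> int:
    sub = rho[np.ix_(members, members)].sum(axis=1)
    best = np.flatnonzero(sub == sub.max())
    if len(best) > 1:  # tie-break by gene id
        best = [min(best, key=lambda i: gene_ids[members[i]])]
    return int(members[best[0]])


def mlg_abundance(members: list[str], abund: pd.DataFrame) -> pd.Series:
    """Robust per-sample MLG abundance: interquartile mean x member count.

    The middle 50% of member-gene abundances is averaged (25% trimmed mean)
    and scaled by the member count, estimating the summed abundance of the
    gene set while damping outlier genes.
    """
    if len(members) == 0:
        raise ValueError("MLG has no members")
    sub = abund.loc[members].to_numpy(dtype=float)
    return pd.Series(
        stats.trim_mean(sub, 0.25, axis=0) * len(members), index=abund.columns, name="abundance"
    )


def mlg_abundance_matrix(mlgs: list[MLG], abund: pd.DataFrame) -> pd.DataFrame:
    mat = pd.DataFrame({m.mlg_id: mlg_abundance(m.members, abund) for m in mlgs}).T
    mat.index.name = "mlg_id"
    return mat


def assign_mlg_taxonomy(members: list[str], catalog: pd.DataFrame) -> TaxonomyCall:
    """Taxonomy call by gene-vote thresholds.

    Species: >= 90% of member genes hit one species at DNA identity >= 95
    and coverage >= 0.70. Else genus: >= 80% of member genes hit one genus
    at >= 85% identity in both DNA and protein. Else unclassified (the best
    fraction seen is still reported).
    """
    rows = catalog.loc[members]
    n = len(rows)

    sp_ok = rows[(rows["dna_identity"] >= SPECIES_DNA_IDENTITY) & (rows["coverage"] >= SPECIES_COVERAGE)]
    best_fraction = 0.0
    if len(sp_ok) > 0:
        counts = sp_ok["taxon_id"].value_counts()
        frac = counts.iloc[0] / n
        best_fraction = max(best_fraction, frac)
        if frac >= SPECIES_GENE_FRACTION:
            return TaxonomyCall("species", str(counts.index[0]), float(frac))

    gen_ok = rows[(rows["dna_identity"] >= GENUS_IDENTITY) & (rows["protein_identity"] >= GENUS_IDENTITY)]
    if len(gen_ok) > 0:
        counts = gen_ok["genus"].value_counts()
        frac = counts.iloc[0] / n
        best_fraction = max(best_fraction, frac)
        if frac >= GENUS_GENE_FRACTION:
            return TaxonomyCall("genus", str(counts.index[0]), float(frac))

    return TaxonomyCall("unclassified", None, float(best_fraction))


def mlg_enrichment(abundance: pd.Series, cohort: pd.DataFrame, alpha: float = 0.05) -> tuple[str, float]:
    """Enrichment direction by two-tailed Mann-Whitney at P < alpha.

    Returns (direction, p): 'case-enriched' / 'control-enriched' by the
    higher-median group when p < alpha, else 'none'.
    """
    groups = cohort.loc[abundance.index, "group"]
    case = abundance[groups == "case"].to_numpy(dtype=float)
    ctrl = abundance[groups == "control"].to_numpy(dtype=float)
    p = mannwhitney_p(case, ctrl)
    if p >= alpha:
        return "none", p
    med_case, med_ctrl = np.median(case), np.median(ctrl)
    if med_case == med_ctrl:  # fall back to means if medians tie
        med_case, med_ctrl = case.mean(), ctrl.mean()
    return ("case-enriched" if med_case > med_ctrl else "control-enriched"), p


def build_mlgs(
    marker_abund: pd.DataFrame,
    catalog: pd.DataFrame,
    cohort: pd.DataFrame,
    rho_min: float = 0.7,
    min_size: int = 5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full MLG stage: cluster, profile, classify taxonomy, call direction.

    Returns (mlg table, MLG-by-sample abundance matrix, membership table).
    """
    mlgs, _ = cluster_mlgs(marker_abund, rho_min=rho_min, min_size=min_size, seed=seed)
    abund_mat = mlg_abundance_matrix(mlgs, marker_abund) if mlgs else pd.DataFrame(
        columns=marker_abund.columns
    )
    records, memberships = [], []
    for m in mlgs:
        m.taxonomy = assign_mlg_taxonomy(m.members, catalog)
        m.direction, m.p_value = mlg_enrichment(abund_mat.loc[m.mlg_id], cohort)
        records.append(
            {
                "mlg_id": m.mlg_id,
                "size": m.size,
                "rank": m.taxonomy.rank,
                "taxon": m.taxonomy.taxon if m.taxonomy.taxon is not None else "",
                "fraction": m.taxonomy.fraction,
                "direction": m.direction,
                "p": m.p_value,
            }
        )
        memberships.extend({"mlg_id": m.mlg_id, "gene_id": g} for g in m.members)
    table = pd.DataFrame(
        records, columns=["mlg_id", "size", "rank", "taxon", "fraction", "direction", "p"]
    )
    members = pd.DataFrame(memberships, columns=["mlg_id", "gene_id"])
    if not table.empty:
        table = table.set_index("mlg_id", drop=False)
    return table, abund_mat, members
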