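"""Synthetic dataset generator with planted ground truth.

Produces a toy gene catalogue, a genes-by-samples unique-read count matrix,
and a cohort table whose glucose phenotype is coupled to the planted
case/control abundance effects. Every downstream stage of the pipeline can
therefore be tested against known truth without any external data.

Generative model
----------------
Genes are partitioned into latent species. Per-sample species abundances are
log-normal; planted differential species are shifted by ``2**(+-effect_log2fc)``
in case samples; an optional rank-one confounder axis perturbs the
log-abundances of a random half of the species. Read counts are Poisson
around length-proportional rates (negative-binomial overdispersion behind
one knob, off by default), with per-sample depth log-normal around
``depth_mean`` (cv 0.2). Glucose is an affine function of the per-sample log
ratio of case-enriched to control-enriched species abundance, with a slope
proportional to ``effect_log2fc`` so that a zero effect yields a
label-independent phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io

GLUCOSE_BASELINES = {"glucose_0": 4.7, "glucose_60": 8.0, "glucose_120": 6.8}
GLUCOSE_SLOPE_SCALE = {"glucose_0": 1.0, "glucose_60": 1.6, "glucose_120": 1.3}


class DegenerateSignalError(ValueError):
    """The planted signal is constant across samples; no phenotype can couple to it."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic dataset.

    ``genes_per_species`` may be a single count or a ``(low, high)`` range
    sampled uniformly per species.
    """

    n_case: int = 20
    n_control: int = 20
    n_species: int = 20
    genes_per_species: int | tuple[int, int] = 20
    gene_length_range: tuple[int, int] = (500, 1500)
    depth_mean: float = 2e5
    n_diff_species: int = 2
    effect_log2fc: float = 2.0
    confounder_strength: float = 0.0
    phenotype_noise_sd: float = 0.3
    annotation_noise: float = 0.0
    seed: int = 0
    depth_cv: float = 0.2
    overdispersion: float = 0.0
    ko_fraction: float = 0.6
    species_per_genus: int = 3
    genera_per_phylum: int = 4
    kos_per_module: int = 5
    glucose_coupling: float = 0.5
    confounder_glucose_coupling: float = 0.4
    species_log_sd: float = 1.0
    sample_log_sd: float = 1.0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be >= 1")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_diff_species > self.n_species:
            raise ValueError("n_diff_species must be <= n_species")
        if self.n_diff_species < 0:
            raise ValueError("n_diff_species must be >= 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0 <= self.annotation_noise <= 1:
            raise ValueError("annotation_noise must be in [0, 1]")
        if self.confounder_strength < 0:
            raise ValueError("confounder_strength must be >= 0")
        if self.phenotype_noise_sd < 0:
            raise ValueError("phenotype_noise_sd must be >= 0")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("gene_length_range must be a positive interval")
        gps = self.genes_per_species
        if isinstance(gps, int):
            if gps < 1:
                raise ValueError("genes_per_species must be >= 1")
        else:
            if gps[0] < 1 or gps[1] < gps[0]:
                raise ValueError("genes_per_species range must be a positive interval")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic dataset."""

    species_of_gene: dict[str, str]
    differential_species: list[tuple[str, str]]  # (species id, "case"|"control")
    confounder_score: dict[str, float]
    phenotype_coefficients: dict[str, float]
    planted_case_samples: list[str] = field(default_factory=list)
    log_ratio: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["differential_species"] = [list(t) for t in self.differential_species]
        return d


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generation stage
    return np.random.default_rng([config.seed, stream])


def _species_sizes(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    gps = config.genes_per_species
    if isinstance(gps, int):
        return np.full(config.n_species, gps, dtype=int)
    return rng.integers(gps[0], gps[1] + 1, size=config.n_species)


def species_ids(config: SyntheticConfig) -> list[str]:
    return [f"sp{k:04d}" for k in range(config.n_species)]


def generate_catalog(config: SyntheticConfig) -> pd.DataFrame:
    """Build a toy gene catalogue with genome-hit and functional annotations.

    Each gene belongs to exactly one latent species. Clean genes get a
    best hit on their own species' genome passing the species rule
    (DNA identity >= 95, coverage >= 0.70); an ``annotation_noise``
    fraction instead get sub-threshold hits. Species carry genus and
    phylum labels; genes carry 0 or 1 KO, and KOs group into modules.
    """
    config.validate()
    rng = _rng(config, 0)
    sizes = _species_sizes(config, rng)
    sp_ids = species_ids(config)

    gene_rows = []
    gene_counter = 0
    for k, sp in enumerate(sp_ids):
        genus = f"gen{k // config.species_per_genus:03d}"
        phylum = f"phy{(k // config.species_per_genus) // config.genera_per_phylum:02d}"
        for _ in range(sizes[k]):
            gene_rows.append((f"g{gene_counter:06d}", sp, genus, phylum))
            gene_counter += 1
    n_genes = gene_counter

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n_genes
    )
    noisy = rng.random(n_genes) < config.annotation_noise
    dna_id = np.where(noisy, rng.uniform(40.0, 60.0, n_genes), rng.uniform(95.5, 99.9, n_genes))
    prot_id = np.where(noisy, rng.uniform(30.0, 60.0, n_genes), rng.uniform(90.0, 99.9, n_genes))
    coverage = np.where(noisy, rng.uniform(0.20, 0.65, n_genes), rng.uniform(0.75, 0.99, n_genes))

    has_ko = rng.random(n_genes) < config.ko_fraction
    n_kos = max(1, n_genes // 10)
    ko_index = rng.integers(0, n_kos, size=n_genes)
    ko = np.where(has_ko, np.char.add("K", np.char.zfill(ko_index.astype(str), 5)), "")
    module_index = ko_index // config.kos_per_module
    module = np.where(has_ko, np.char.add("M", np.char.zfill(module_index.astype(str), 4)), "")

    catalog = pd.DataFrame(
        {
            "gene_id": [r[0] for r in gene_rows],
            "length_bp": lengths,
            "taxon_id": [r[1] for r in gene_rows],
            "genus": [r[2] for r in gene_rows],
            "phylum": [r[3] for r in gene_rows],
            "dna_identity": np.round(dna_id, 2),
            "protein_identity": np.round(prot_id, 2),
            "coverage": np.round(coverage, 3),
            "ko_id": ko,
            "module_id": module,
        }
    ).set_index("gene_id", drop=False)
    return catalog


def _sample_ids(config: SyntheticConfig) -> list[str]:
    return [f"S{i:04d}" for i in range(config.n_samples)]


def _species_relative_abundance(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Latent species relative abundances plus the planted effect metadata."""
    sp = species_ids(config)
    samples = _sample_ids(config)
    n_s, n_k = config.n_samples, config.n_species

    mu = rng.normal(0.0, config.species_log_sd, size=n_k)
    log_abund = mu[:, None] + rng.normal(0.0, config.sample_log_sd, size=(n_k, n_s))

    diff = []
    case_mask = np.zeros(n_s, dtype=bool)
    case_mask[: config.n_case] = True  # planted cases occupy the leading block
    for j in range(config.n_diff_species):
        direction = "case" if j % 2 == 0 else "control"
        diff.append((sp[j], direction))
        shift = np.log(2.0) * config.effect_log2fc * (1.0 if direction == "case" else -1.0)
        log_abund[j, case_mask] += shift

    conf_score = rng.normal(0.0, 1.0, size=n_s)
    conf_species = rng.choice(n_k, size=n_k // 2, replace=False)
    if config.confounder_strength > 0 and len(conf_species) > 0:
        log_abund[conf_species, :] += config.confounder_strength * conf_score[None, :]

    rel = np.exp(log_abund)
    rel /= rel.sum(axis=0, keepdims=True)
    frame = pd.DataFrame(rel, index=sp, columns=samples)
    return frame, diff, conf_score, case_mask


def generate_counts(
    catalog: pd.DataFrame, config: SyntheticConfig, return_rates: bool = False
):
    """Simulate the genes-by-samples unique-read count matrix.

    Rate of gene g in sample s: ``depth_s * A_ks * L_g / (n_k * L0)`` where
    ``A_ks`` is the species relative abundance, ``n_k`` the species' gene
    count and ``L0`` the catalogue's nominal mean gene length — so counts
    are linear in gene length and per-sample totals land near ``depth_s``.

    Returns ``(counts, truth)``, or ``(counts, truth, rates)`` with the
    expected-count matrix when ``return_rates`` is set.
    """
    config.validate()
    rng = _rng(config, 1)
    species_rel, diff, conf_score, case_mask = _species_relative_abundance(config, rng)
    samples = list(species_rel.columns)

    sigma2 = np.log1p(config.depth_cv**2)
    depth = rng.lognormal(
        mean=np.log(config.depth_mean) - sigma2 / 2.0, sigma=np.sqrt(sigma2), size=len(samples)
    )

    sp_of_gene = catalog["taxon_id"].to_numpy()
    lengths = catalog["length_bp"].to_numpy(dtype=float)
    l0 = float(np.mean(config.gene_length_range))
    genes_in_species = pd.Series(sp_of_gene).value_counts()
    n_k = genes_in_species.reindex(sp_of_gene).to_numpy(dtype=float)

    sp_index = species_rel.index.get_indexer(sp_of_gene)
    rel_per_gene = species_rel.to_numpy()[sp_index, :]  # genes x samples
    rate = depth[None, :] * rel_per_gene * (lengths / (n_k * l0))[:, None]

    poisson_mean = rate
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        poisson_mean = rng.gamma(shape, rate / shape)
    counts = rng.poisson(poisson_mean)

    counts_df = pd.DataFrame(counts, index=catalog.index, columns=samples)
    counts_df.index.name = "gene_id"

    log_ratio = _planted_log_ratio(species_rel, diff)
    truth = SyntheticTruth(
        species_of_gene=dict(zip(catalog["gene_id"], catalog["taxon_id"])),
        differential_species=diff,
        confounder_score=dict(zip(samples, conf_score.tolist())),
        phenotype_coefficients={},
        planted_case_samples=[s for s, m in zip(samples, case_mask) if m],
        log_ratio=dict(zip(samples, log_ratio.tolist())),
    )
    if return_rates:
        rates_df = pd.DataFrame(rate, index=catalog.index, columns=samples)
        return counts_df, truth, rates_df
    return counts_df, truth


def _planted_log_ratio(species_rel: pd.DataFrame, diff: list[tuple[str, str]]) -> np.ndarray:
    """Per-sample log ratio of case-enriched to control-enriched species abundance."""
    case_sp = [s for s, d in diff if d == "case"]
    ctrl_sp = [s for s, d in diff if d == "control"]
    n = species_rel.shape[1]
    if not case_sp and not ctrl_sp:
        return np.zeros(n)
    if case_sp and ctrl_sp:
        return np.log(species_rel.loc[case_sp].sum(axis=0).to_numpy()) - np.log(
            species_rel.loc[ctrl_sp].sum(axis=0).to_numpy()
        )
    if case_sp:
        return np.log(species_rel.loc[case_sp].sum(axis=0).to_numpy())
    return -np.log(species_rel.loc[ctrl_sp].sum(axis=0).to_numpy())


def generate_cohort(
    config: SyntheticConfig, truth: SyntheticTruth, counts: pd.DataFrame
) -> pd.DataFrame:
    """Derive the cohort table: glucose coupled to the planted log ratio.

    Glucose at 0/60/120 min is an affine function of the standardized
    planted log ratio plus Gaussian noise; the slope is
    ``glucose_coupling * effect_log2fc``. When a confounder axis is planted
    (``confounder_strength > 0``), its per-sample score also enters glucose
    with slope ``confounder_glucose_coupling * confounder_strength`` — a
    confounder must touch both the microbiome and the outcome to confound.
    The case label goes to the ``n_case`` samples with the highest fasting
    glucose.
    """
    config.validate()
    rng = _rng(config, 2)
    samples = list(counts.columns)
    ratio = np.array([truth.log_ratio[s] for s in samples])

    slope = config.glucose_coupling * config.effect_log2fc
    sd = ratio.std()
    if slope != 0 and sd == 0:
        raise DegenerateSignalError(
            "planted abundance log-ratio is constant across samples; "
            "cannot couple a phenotype to it"
        )
    z = (ratio - ratio.mean()) / sd if sd > 0 else np.zeros_like(ratio)

    conf = np.array([truth.confounder_score[s] for s in samples])
    conf_slope = config.confounder_glucose_coupling * config.confounder_strength

    coeffs: dict[str, float] = {"slope": slope, "confounder_slope": conf_slope}
    glucose = {}
    for name in GLUCOSE_BASELINES:
        b = slope * GLUCOSE_SLOPE_SCALE[name]
        coeffs[f"{name}_intercept"] = GLUCOSE_BASELINES[name]
        coeffs[f"{name}_slope"] = b
        glucose[name] = (
            GLUCOSE_BASELINES[name]
            + b * z
            + conf_slope * GLUCOSE_SLOPE_SCALE[name] * conf
            + rng.normal(0.0, config.phenotype_noise_sd, size=len(samples))
        )
    truth.phenotype_coefficients = coeffs

    g0 = glucose["glucose_0"]
    if np.ptp(g0) == 0:
        raise DegenerateSignalError("fasting glucose is constant; cannot place a quantile cut")
    # case label = top n_case fasting glucose values (stable tie-break on order)
    order = np.lexsort((np.arange(len(samples)), -g0))
    group = np.array(["control"] * len(samples), dtype=object)
    group[order[: config.n_case]] = "case"

    pbmi_sigma2 = np.log1p(0.15**2)
    pbmi = rng.lognormal(np.log(21.0) - pbmi_sigma2 / 2.0, np.sqrt(pbmi_sigma2), len(samples))
    age = np.clip(rng.normal(29.0, 3.5, len(samples)), 18.0, 45.0)

    cohort = pd.DataFrame(
        {
            "sample_id": samples,
            "group": group,
            "glucose_0": np.round(glucose["glucose_0"], 4),
            "glucose_60": np.round(glucose["glucose_60"], 4),
            "glucose_120": np.round(glucose["glucose_120"], 4),
            "pbmi": np.round(pbmi, 2),
            "age": np.round(age, 1),
        }
    ).set_index("sample_id", drop=False)
    return cohort


def generate_dataset(
    config: SyntheticConfig, outdir=None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate catalogue, counts, cohort, and truth; optionally write TSVs."""
    catalog = generate_catalog(config)
    counts, truth = generate_counts(catalog, config)
    cohort = generate_cohort(config, truth, counts)
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_catalog(catalog, outdir / "catalog.tsv")
        io.write_matrix(counts, outdir / "counts.tsv", index_name="gene_id")
        io.write_cohort(cohort, outdir / "cohort.tsv")
        io.write_json(truth.to_dict(), outdir / "truth.json")
    return catalog, counts, cohort, truth
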