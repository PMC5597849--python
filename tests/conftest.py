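import numpy as np
import pandas as pd
import pytest

from mgwaskit.synth import SyntheticConfig, generate_dataset


def power_config(seed: int = 1, **overrides) -> SyntheticConfig:
    """Settings under which planted effects are reliably recoverable."""
    base = dict(
        n_case=40,
        n_control=40,
        n_species=50,
        genes_per_species=20,
        depth_mean=2e5,
        n_diff_species=2,
        effect_log2fc=2.0,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def null_config(seed: int = 3, **overrides) -> SyntheticConfig:
    """Global null: no planted effect, independent genes (one per species)."""
    base = dict(
        n_case=40,
        n_control=40,
        n_species=2000,
        genes_per_species=1,
        depth_mean=2e5,
        n_diff_species=0,
        effect_log2fc=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def power_dataset():
    cfg = power_config(seed=1)
    catalog, counts, cohort, truth = generate_dataset(cfg)
    return cfg, catalog, counts, cohort, truth


@pytest.fixture(scope="session")
def tiny_dataset():
    cfg = SyntheticConfig(
        n_case=10, n_control=10, n_species=5, genes_per_species=6,
        depth_mean=5e4, n_diff_species=2, effect_log2fc=2.0, seed=7,
    )
    catalog, counts, cohort, truth = generate_dataset(cfg)
    return cfg, catalog, counts, cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_catalog(records) -> pd.DataFrame:
    """Catalog frame from (gene_id, length, taxon, genus, phylum, dna, prot, cov, ko, module)."""
    cols = ["gene_id", "length_bp", "taxon_id", "genus", "phylum",
            "dna_identity", "protein_identity", "coverage", "ko_id", "module_id"]
    df = pd.DataFrame(records, columns=cols)
    return df.set_index("gene_id", drop=False)


def make_cohort(sample_ids, groups, **phenos) -> pd.DataFrame:
    n = len(sample_ids)
    data = {
        "sample_id": sample_ids,
        "group": groups,
        "glucose_0": phenos.get("glucose_0", np.full(n, 5.0)),
        "glucose_60": phenos.get("glucose_60", np.full(n, 8.0)),
        "glucose_120": phenos.get("glucose_120", np.full(n, 7.0)),
        "pbmi": phenos.get("pbmi", np.full(n, 21.0)),
        "age": phenos.get("age", np.full(n, 29.0)),
    }
    return pd.DataFrame(data).set_index("sample_id", drop=False)
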