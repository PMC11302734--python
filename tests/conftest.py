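import logging

import numpy as np
import pandas as pd
import pytest

from gutpair.containers import AbundanceTable
from gutpair.simulate import (
    CohortConfig,
    CommunityConfig,
    SiteEffect,
    generate_annotation,
    generate_cohort,
    generate_paired_abundances,
    simulate_dataset,
)

logging.getLogger("gutpair").setLevel(logging.ERROR)


def small_community(seed: int = 0, **overrides) -> CommunityConfig:
    """Compact community for fast structural tests."""
    params = dict(
        n_genes=400,
        n_phyla=4,
        n_genera=10,
        n_species=20,
        n_kos=30,
        n_pathways=4,
        mucosa_occupancy=0.3,
        feces_occupancy=0.8,
        unclassified_species_fraction=0.0,
        seed=seed,
    )
    params.update(overrides)
    return CommunityConfig(**params)


def small_cohort(n: int = 8) -> CohortConfig:
    low = high = max(1, n // 4)
    return CohortConfig(n_subjects=n, polyp_group_sizes=(low, n - low - high, high))


@pytest.fixture(scope="session")
def default_dataset():
    """One study-scale simulated cohort shared across read-only tests."""
    return simulate_dataset(seed=11)


@pytest.fixture()
def small_dataset():
    cfg = small_community(seed=7, site_effect_features=(SiteEffect("g02", 2.0, "mucosa"),))
    metadata = generate_cohort(small_cohort(), seed=7)
    annotation, pathway_map = generate_annotation(cfg)
    table, truth = generate_paired_abundances(metadata, cfg, annotation)
    return metadata, table, annotation, pathway_map, truth


def random_table(rng: np.random.Generator, n_features: int = 20, n_samples: int = 6,
                 level: str = "gene", normalize: bool = True) -> AbundanceTable:
    values = rng.gamma(0.5, size=(n_features, n_samples))
    if normalize:
        values = values / values.sum(axis=0)
    return AbundanceTable(
        pd.DataFrame(
            values,
            index=[f"f{i:03d}" for i in range(n_features)],
            columns=[f"s{j:02d}" for j in range(n_samples)],
        ),
        level=level,
        normalized=normalize,
    )
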