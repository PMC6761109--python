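"""Shared fixtures: small seeded genomes and cohorts, generated at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from psionic import features as feat
from psionic import simulate as sim


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="no genes on chromosome")
        warnings.filterwarnings("ignore", message="dropping .* zero-variance")
        yield


@pytest.fixture(scope="session")
def small_genome():
    """~200 genes, 30 TFs, with decoys; shared across read-only tests."""
    genes, atlas, hits = sim.simulate_regulatory_genome(
        n_genes=200, n_tfs=30, mean_peaks_per_gene=6.0, hit_prob=0.15, seed=42
    )
    return genes, atlas, hits


@pytest.fixture(scope="session")
def small_assignment(small_genome):
    genes, atlas, _ = small_genome
    return feat.assign_peaks_to_genes(atlas, genes)


@pytest.fixture(scope="session")
def small_X(small_genome, small_assignment):
    _, _, hits = small_genome
    return feat.aggregate_motif_scores(
        small_assignment, hits, motif_ids=sorted(hits["motif_id"].unique())
    )


@pytest.fixture(scope="session")
def small_cohort(small_X):
    """Desk-scale planted cohort: 200 genes x 30 TFs, 20 samples, K_true=3."""
    return sim.simulate_cohort(
        small_X, K_true=3, T=20, n_groups=3, support_size=2,
        target_r2=0.5, seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
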