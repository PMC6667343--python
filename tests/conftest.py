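import numpy as np
import pytest
from hypothesis import settings

import mtx_arena as ma
from mtx_arena.workflows import BenchmarkConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_catalog_db():
    """A 20-gene catalog over 10 orthologs / 4 families / 2 subsystems."""
    return ma.generate_catalog(
        n_genes=20, n_orthologs=10, n_families=4, n_subsystems=2,
        decoys_per_ortholog=1, decoy_identity=0.70, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_config():
    """A minutes-scale configuration for end-to-end workflow tests."""
    return BenchmarkConfig(
        n_genes=30, n_orthologs=15, n_families=5, n_subsystems=3,
        background_per_family=1, n_samples=6, coverage=8.0,
        ncrna_fraction=0.05, n_ncrna=2, ncrna_length=300,
        min_kmer_count=2, n_segcv_subsystems=1, seed=11,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
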