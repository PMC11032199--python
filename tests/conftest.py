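import numpy as np
import pytest

from stkflux.io import SpeciesTree
from stkflux.synthetic_data import SimConfig


@pytest.fixture
def tree_abc() -> SpeciesTree:
    """((A,B),C); — internal nodes N0 (root) and N1."""
    return SpeciesTree.from_string("((A,B),C);")


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(
        seed=42,
        n_taxa=6,
        n_families=200,
        n_genes=8,
        gene_length_codons=200,
        kinase_counts={c: 10 for c in (
            "functional", "missing_K", "missing_D1", "missing_D2",
            "fragmented_functional", "fragmented_incomplete")},
        n_arch_proteins=40,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240328)
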