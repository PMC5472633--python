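import numpy as np
import pytest

from salinidelim.synthetic_genus import SimParams, simulate_genus


@pytest.fixture(scope="session")
def small_genus():
    """3 species x 2 strains, clean (no recombination, no paralogs)."""
    params = SimParams(
        n_species=3, strains_per_species=(2, 2, 2),
        n_core_genes=12, n_accessory_genes=6,
        within_species_div=0.01, between_species_div=0.06,
        gene_len=300, marker_len=800, seed=11,
    )
    return simulate_genus(params)


@pytest.fixture(scope="session")
def recombinant_genus():
    """3 species x 3 strains with half-gene cross-clade transfers."""
    params = SimParams(
        n_species=3, strains_per_species=(3, 3, 3),
        n_core_genes=20, n_accessory_genes=0,
        within_species_div=0.01, between_species_div=0.06,
        gene_len=900, seed=2,
        recomb_gene_fraction=0.5, recomb_tract_fraction=0.5,
    )
    return simulate_genus(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
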