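import numpy as np
import pytest

from genemediate import simulate


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused by read-only tests (never mutated)."""
    spec = simulate.SimulationSpec(
        n_samples=300,
        n_gene_snps=40,
        n_background_snps=1200,
        n_chromosomes=6,
        n_related_pairs=15,
        seed=11,
    )
    g = simulate.gen_genotypes(spec)
    phen = simulate.gen_phenotypes(g, spec)
    return spec, g, phen


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
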