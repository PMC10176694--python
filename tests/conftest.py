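import numpy as np
import pytest

from cnvpop import synthetic_data as sd


@pytest.fixture(scope="session")
def small_genome():
    """Two 2-Mb chromosomes, 80 genes, TE track — shared read-only genome."""
    return sd.simulate_genome(2, 2_000_000, 80, 0.3, seed=11)


@pytest.fixture(scope="session")
def population_study(small_genome):
    """Jitter-free two-population call set with fully recoverable loci."""
    calls, truth = sd.simulate_population_cnvs(
        small_genome,
        n_pop1=40,
        n_pop2=40,
        n_loci=15,
        freq_spec=((0.4, 0.9), (0.4, 0.9)),
        jitter_sd=0.0,
        seed=12,
    )
    return calls, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
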