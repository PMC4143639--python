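import pytest

from permclass.simulate import SimulationConfig, simulate_cohort


SMALL = dict(
    n_individuals=60,
    n_pedigrees=6,
    n_snps=30,
    n_causal=2,
    n_rare_causal=1,
    n_ld_tagged=2,
    ld_block_size=1,
    n_perfect_duplicates=2,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-individual cohort with planted causal, rare and LD structure."""
    cohort, truth = simulate_cohort(SimulationConfig(seed=7, **SMALL))
    return cohort, truth
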