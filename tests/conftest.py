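import numpy as np
import pytest

from autozyg import pedigree, roh, simulate


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-scale study-like cohort used across test modules."""
    return simulate.SimConfig(
        seed=7,
        n_founders=40,
        n_generations=6,
        sires_per_generation=4,
        offspring_per_generation=40,
        n_chromosomes=4,
        chrom_length_mb=80.0,
        snps_per_chromosome=1200,
        dpr_additive=[simulate.TraitLocus("2", 44_000_000, -0.15)],
        dpr_recessive=[simulate.TraitLocus("3", 40_000_000, -0.4)],
        scs_additive=[simulate.TraitLocus("1", 52_000_000, 0.03)],
        scs_recessive=[simulate.TraitLocus("4", 8_000_000, 0.07)],
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    sim, traits = simulate.simulate_cohort(small_cfg)
    return sim, traits


@pytest.fixture(scope="session")
def small_fped(small_cohort):
    sim, _ = small_cohort
    ped = pedigree.Pedigree.from_frame(
        sim.pedigree[["animal", "sire", "dam", "birth_year"]]
    )
    return pedigree.compute_fped(ped, sim.ids).to_numpy()


@pytest.fixture(scope="session")
def small_H(small_cohort):
    sim, _ = small_cohort
    segments = roh.detect_roh(sim.genotypes, roh.ROHDefinition(min_snps=50))
    return roh.roh_state_matrix(segments, sim.genotypes)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
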