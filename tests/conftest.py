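import numpy as np
import pytest

from dmafscan import GenotypeMatrix, Phenotype, RegionParams, simulate_region


@pytest.fixture
def two_variant_gm():
    """2 cases with counts [1,1] / 2 controls with [0,0] at variant 1;
    variant 2 balanced; hand-checkable frequencies."""
    counts = np.array(
        [
            [1, 1],
            [1, 0],
            [0, 1],
            [0, 0],
        ]
    )
    gm = GenotypeMatrix(
        counts=counts,
        sample_ids=["s1", "s2", "s3", "s4"],
        variant_ids=["v1", "v2"],
        positions=np.array([100, 200]),
    )
    return gm, Phenotype(np.array([1, 1, 0, 0]))


@pytest.fixture
def random_gm():
    """60 subjects x 40 variants with realistic MAF spectrum, no missing."""
    rng = np.random.default_rng(42)
    mafs = rng.uniform(0.01, 0.4, 40)
    counts = rng.binomial(2, mafs, size=(60, 40))
    # ensure polymorphism
    counts[0, counts.sum(axis=0) == 0] = 1
    gm = GenotypeMatrix(
        counts=counts,
        sample_ids=[f"s{i}" for i in range(60)],
        variant_ids=[f"v{j}" for j in range(40)],
        positions=np.arange(40) * 50 + 1,
    )
    phen = Phenotype(np.array([1] * 30 + [0] * 30))
    return gm, phen


@pytest.fixture(scope="session")
def small_pool():
    """Small coalescent pool (600 diploids, 20 kb) for simulation tests."""
    return simulate_region(
        RegionParams(length_bp=20_000, n_diploids=600), seed=314
    )
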