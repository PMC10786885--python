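import pytest

from phenoclust.simulate import (MethSimConfig, ScreenSimConfig,
                                 simulate_methylation, simulate_screen)


@pytest.fixture(scope="session")
def small_screen():
    """A small but fully featured screen with planted effects."""
    config = ScreenSimConfig(n_genes=300, n_ntc_pairs=30, seed=11)
    library, samples, counts, truth = simulate_screen(config)
    return config, library, samples, counts, truth


@pytest.fixture(scope="session")
def cohort():
    """The default methylation cohort scenario (25/8/86 samples, seed 1)."""
    config = MethSimConfig(seed=1)
    beta, annotation, detection_p, truth = simulate_methylation(config)
    return config, beta, annotation, detection_p, truth


@pytest.fixture(scope="session")
def two_blocks():
    """Two clearly separated 6+6 sample blocks."""
    config = MethSimConfig(
        group_sizes=(6, 6), n_probes=800, n_informative_per_group=80,
        n_flagged={"sex_chrom": 20, "snp_overlap": 10, "multimap": 10,
                   "detection_fail": 5},
        seed=3,
    )
    beta, annotation, detection_p, truth = simulate_methylation(config)
    return config, beta, annotation, detection_p, truth
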