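import numpy as np
import pytest

from mi2p import CohortDesign, generate_catalog, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny zero-error cohort for read-level unit tests."""
    catalog = generate_catalog(30, 6, length_range=(300, 600), seed=5)
    design = CohortDesign(
        n_case=5,
        n_control=5,
        n_genes=30,
        n_markers=6,
        fold_change=4.0,
        reads_per_sample=2000,
        substitution_error_rate=0.0,
        abundance_dispersion=0.3,
        seed=5,
    )
    reads, truth = simulate_cohort(catalog, design)
    return catalog, design, reads, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
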