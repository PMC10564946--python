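import pytest

from m6ascape.simulate import CohortSpec, make_toy_annotation, simulate_cohort


@pytest.fixture(scope="session")
def toy_annotation():
    """Ten-gene toy genome with planted motif windows and m6Am TSS contexts."""
    return make_toy_annotation(n_genes=10, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with planted tumor/subtype/driver structure."""
    spec = CohortSpec(
        n_tumor=40, n_normal_paired=20, n_peaks=200, n_hyper_planted=20,
        n_hypo_planted=10, n_rbps=15, driver_effect=0.6, seed=7,
    )
    return simulate_cohort(spec)
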