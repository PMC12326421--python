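import numpy as np
import pytest

from twinvolve import CohortDesign, TraitSpec, generate_cohort, simulate_phenotypes
from twinvolve.reshape import to_family_records


@pytest.fixture(scope="session")
def default_design():
    return CohortDesign()


@pytest.fixture(scope="session")
def small_twin_design():
    """Twin-heavy design for cheap, informative likelihood tests."""
    return CohortDesign(n_mz_pairs=60, n_dz_pairs=40, n_singletons=50)


def make_cohort(design, traits, cross=None, seed=0):
    cohort = generate_cohort(design, seed)
    return simulate_phenotypes(cohort, traits, cross or [], seed=seed + 1)


@pytest.fixture(scope="session")
def vermis_trait():
    return TraitSpec("Cbm_Vermis", mean=5547.65, total_sd=640.50,
                     a2=0.64, c2=0.16, e2=0.20)


@pytest.fixture(scope="session")
def small_cohort(small_twin_design, vermis_trait):
    return make_cohort(small_twin_design, [vermis_trait], seed=11)


@pytest.fixture(scope="session")
def small_records(small_cohort):
    return to_family_records(small_cohort, ["Cbm_Vermis"])
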