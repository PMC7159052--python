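import numpy as np
import pytest

from elastocad import CohortSpec, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def small_phantom_spec():
    return PhantomSpec(
        true_hard_fraction=0.8,
        seed=17,
        height=64,
        width=64,
        lesion_area_px=600,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return generate_phantom(small_phantom_spec)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact benign/malignant cohort used by several suites."""
    spec = CohortSpec(
        seed=5,
        n_malignant=6,
        n_benign=8,
        phantom=PhantomSpec(
            true_hard_fraction=0.5, seed=0, height=64, width=64, lesion_area_px=600
        ),
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
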