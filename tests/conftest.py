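import numpy as np
import pytest

from l3bodycomp.synthetic import CohortSimSpec, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse 6-slice phantom, analytically known nested-cylinder geometry."""
    spec = PhantomSpec(shape=(128, 128), pixel_spacing_mm=1.0, n_slices=6,
                       thickness_mm=5.0, vat_radius_mm=20.0, sm_outer_radius_mm=30.0,
                       sat_outer_radius_mm=40.0, seed=11)
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (106 F / 97 M) plus its ground truth."""
    return generate_cohort(CohortSimSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230804)
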