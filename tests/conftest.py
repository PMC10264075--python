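import numpy as np
import pytest

from osteomorph import PopulationSpec, build_ideal_femur, generate_population


@pytest.fixture(scope="session")
def small_template():
    """A reduced-census femur template (8/12/60 landmarks) with mesh,
    for tests where the full 619-point census would be needless work."""
    return build_ideal_femur(counts=(8, 12, 60), with_mesh=True)


@pytest.fixture(scope="session")
def femur_template():
    """The full-census complete-femur template (25/99/495, 619 points)."""
    return build_ideal_femur()


@pytest.fixture(scope="session")
def default_population(small_template):
    """Default dimorphic population (n=40, seed 0) on the small template."""
    return generate_population(PopulationSpec(n=40, seed=0), small_template)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
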