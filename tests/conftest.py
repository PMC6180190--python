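"""Shared fixtures: phantoms are expensive (registration runs ~20 s), so the
ones used by several tests are generated and registered once per session."""
import numpy as np
import pytest

from hsquant.preprocess import rigid_coregister
from hsquant.synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_phantom, load_table1_fixture


@pytest.fixture(scope="session")
def null_phantom():
    """Symmetric, noise-free, aligned phantom: no pathology, no degradation."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def hs_phantom():
    """Left-sided HS triple effect: atrophy 0.7, FLAIR boost 1.3, PET drop 0.8."""
    return generate_phantom(
        PhantomSpec(atrophy_factor=(1.0, 0.7), flair_boost=(1.0, 1.3), pet_drop=(1.0, 0.8))
    )


@pytest.fixture(scope="session")
def offset_phantom():
    """Phantom whose FLAIR/PET carry a (4, -3, 2) mm, 3 deg rigid offset plus noise."""
    return generate_phantom(
        PhantomSpec(rigid_offset=(4.0, -3.0, 2.0, 3.0, 0.0, 0.0), noise_sd=2.0, seed=1)
    )


@pytest.fixture(scope="session")
def recovered_transform(offset_phantom):
    """FLAIR -> T1 rigid registration result for the offset phantom."""
    t1, flair, _, _, _ = offset_phantom
    return rigid_coregister(flair, t1)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def separated_cohort():
    """10-SD separation on every modality: the perfect-classification limit."""
    return generate_cohort(
        CohortSpec(effect={"volume": 10.0, "flair": 10.0, "suvr": 10.0}, seed=1)
    )


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A 48-cube phantom for tests that run full registration twice."""
    defaults = dict(
        grid_shape=(48, 48, 48),
        brain_radius_mm=18.0,
        hippocampus_center_mm=(9.0, -3.0, -1.0),
        hippocampus_radii_mm=(8.0, 4.0, 3.5),
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)
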