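import numpy as np
import pytest

from optonose import (
    AssaySchedule,
    FilmModel,
    SmoothConfig,
    VOCKinetics,
    default_film_set,
    default_voc_library,
)


@pytest.fixture(scope="session")
def schedule():
    """The default acquisition schedule: 45 x (5 s + 15 s) at 90 Hz."""
    return AssaySchedule()


@pytest.fixture(scope="session")
def small_schedule():
    """A cheap schedule for tests that only need structure, not scale."""
    return AssaySchedule(n_cycles=4, exposure_s=2.0, recovery_s=3.0, sampling_hz=30.0)


@pytest.fixture(scope="session")
def films():
    return default_film_set()


@pytest.fixture(scope="session")
def film(films):
    return films[1]  # the 30 um film


@pytest.fixture(scope="session")
def voc_library():
    return default_voc_library(seed=0)


@pytest.fixture(scope="session")
def quiet_voc():
    """A noiseless, drift-free VOC profile for deterministic shape tests."""
    return VOCKinetics(
        name="heptane", amplitude=10.0, rise_rate=1.5, decay_rate=0.8,
        matrix_shift=0.0, noise_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
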