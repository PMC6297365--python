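import numpy as np
import pytest

from primatefaces import synthdata as sd


@pytest.fixture(scope="session")
def small_panel():
    return sd.generate_species_panel(4, seed=11)


@pytest.fixture(scope="session")
def small_study():
    """A compact but complete synthetic study reused across tests."""
    return sd.make_study(
        group_sizes={"prosimian": 5, "platyrrhine": 5, "catarrhine": 6},
        n_beauty_raters=60,
        n_humanlikeness_raters=20,
        image_size=(48, 64),
        seed=7,
    )


@pytest.fixture(scope="session")
def full_study():
    """Default-regime study (107 species, 286 raters), images skipped."""
    return sd.make_study(seed=42, render=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
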