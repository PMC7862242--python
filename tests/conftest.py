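import numpy as np
import pandas as pd
import pytest

import slicksurvey as ss


@pytest.fixture
def tiny_survey() -> ss.Survey:
    """Three hand-built tows: two slick, one ambient."""
    tows = pd.DataFrame({
        "tow_id": ["t1", "t2", "t3"],
        "habitat": ["slick", "slick", "ambient"],
        "site": ["A", "A", "A"],
        "volume_filtered_m3": [400.0, 200.0, 100.0],
    })
    counts = pd.DataFrame({
        "tow_id": ["t1", "t2", "t2", "t3"],
        "taxon_id": ["carangidae", "mullidae", "carangidae", "carangidae"],
        "count": [10, 3, 5, 2],
    })
    taxa = pd.DataFrame({
        "taxon_id": ["carangidae", "mullidae"],
        "family": ["Carangidae", "Mullidae"],
        "natal_habitat": ["coral_reef", "coral_reef"],
        "functional_group": ["fish", "fish"],
    })
    return ss.Survey(tows=tows, counts=counts, taxa=taxa, debris=pd.DataFrame())


@pytest.fixture(scope="session")
def sim_survey():
    """One default synthetic survey (80 slick / 54 ambient) plus its truth."""
    return ss.simulate_survey(ss.default_config(seed=11))


@pytest.fixture(scope="session")
def worked() -> ss.Survey:
    return ss.worked_example_fixture()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
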