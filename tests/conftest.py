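import pandas as pd
import pytest

import percsim as ps
from percsim import pipeline


@pytest.fixture(scope="session")
def small_config() -> ps.StudyConfig:
    """A reduced cohort that keeps the full design structure."""
    return ps.StudyConfig(n_observers=6, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config) -> "ps.synthetic.StudyData":
    return ps.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_behaviour_rdms(small_study) -> dict[int, pd.DataFrame]:
    return pipeline.behaviour_rdms_from_arrangements(small_study.arrangements)


@pytest.fixture(scope="session")
def small_brain_rdms(small_study) -> dict[str, dict[int, pd.DataFrame]]:
    return pipeline.brain_rdms_from_patterns(small_study.patterns)
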