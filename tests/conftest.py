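import numpy as np
import pytest
from hypothesis import settings

from nanossl.event_io import EventRecord, EventSet
from nanossl.evaluation import ExperimentConfig
from nanossl.preprocess import preprocess_events
from nanossl.synthetic_data import dataset_from_recipe

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_events(rng) -> EventSet:
    """A small variable-length labeled event set."""
    events = []
    for i in range(12):
        T = int(rng.integers(20, 60))
        events.append(
            EventRecord(
                id=f"ev{i:03d}",
                trace=rng.normal(-0.3, 0.1, size=T),
                label=["alpha", "beta", "gamma"][i % 3],
                source=f"pore{i % 2}",
            )
        )
    return EventSet.from_events(events)


@pytest.fixture(scope="session")
def abeta_events() -> EventSet:
    """The three-class peptide benchmark, globally standardized at F=500."""
    events, _ = dataset_from_recipe("abeta3-default")
    return preprocess_events(events, "interp", 500, "zscore_global")


@pytest.fixture(scope="session")
def scaled_cfg() -> ExperimentConfig:
    return ExperimentConfig.scaled_down()
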