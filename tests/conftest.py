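import numpy as np
import pytest

from miia import (
    CommunityObservation,
    ObservationSet,
    make_fixture,
    random_dataset,
)


@pytest.fixture(scope="session")
def kato_dataset():
    """Synthetic dataset following the four-member interdependent-growth
    pattern (only PT and BA grow axenically)."""
    return random_dataset(make_fixture("kato4"), seed=11)


@pytest.fixture(scope="session")
def wang_dataset():
    """Synthetic dataset following the three-member all-growth pattern."""
    return random_dataset(make_fixture("wang3"), seed=3)


@pytest.fixture
def kato_obs(kato_dataset):
    return kato_dataset.observations


@pytest.fixture
def wang_obs(wang_dataset):
    return wang_dataset.observations


def build_observation_set(abundances, detection_limit=0.0):
    """Helper: {(member tuple): {species: value-or-list}} -> ObservationSet."""
    observations = []
    for members, values in abundances.items():
        obs_values = {
            sp: tuple(v) if isinstance(v, (list, tuple)) else (float(v),)
            for sp, v in values.items()
        }
        observations.append(CommunityObservation(tuple(members), obs_values))
    return ObservationSet(observations, detection_limit=detection_limit)


@pytest.fixture
def simple_ternary():
    """Three species all growing everywhere, with hand-picked abundances:
    ternary partner abundances of focal A are (B, C) = (2, 1)."""
    return build_observation_set(
        {
            ("A",): {"A": 1.0},
            ("B",): {"B": 1.0},
            ("C",): {"C": 1.0},
            ("A", "B"): {"A": 2.0, "B": 4.0},
            ("A", "C"): {"A": 1.5, "C": 2.0},
            ("B", "C"): {"B": 3.0, "C": 1.0},
            ("A", "B", "C"): {"A": 3.0, "B": 2.0, "C": 1.0},
        }
    )
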