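import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cgrphylo import (
    SequenceRecord,
    build_dataset_sequence,
    compute_fcgr,
    evolve_sequences,
    two_clade_scenario,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def profiles_from_scenario(scn, k):
    """Raw FCGR profiles (revcomp appended) for every leaf of a scenario."""
    profiles = []
    for label, seq in evolve_sequences(scn):
        ss = build_dataset_sequence([SequenceRecord(label, seq)], label)
        profiles.append((label, compute_fcgr(ss, k)))
    return profiles


@pytest.fixture(scope="session")
def two_clade_small():
    """One small two-clade instance: scenario plus k=5 profiles."""
    scn = two_clade_scenario(seed=11, root_length=5_000)
    return scn, profiles_from_scenario(scn, 5)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_926)
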