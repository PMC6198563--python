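"""Shared fixtures: small simulated records reused across test modules."""

import numpy as np
import pytest

from commondrive import (
    DriveSimConfig,
    IntramuscularCoherence,
    simulate_common_drive_emg,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def driven_record():
    """A 30 s two-channel record with strong beta-band common drive."""
    return simulate_common_drive_emg(
        DriveSimConfig(duration_s=30.0, kappa=0.8, seed=101)
    )


@pytest.fixture(scope="session")
def driven_fit(driven_record):
    return IntramuscularCoherence(driven_record).fit()


@pytest.fixture(scope="session")
def independent_record():
    """A 30 s record with no common drive and no cross-talk."""
    return simulate_common_drive_emg(
        DriveSimConfig(duration_s=30.0, kappa=0.0, seed=102)
    )


@pytest.fixture(scope="session")
def independent_fit(independent_record):
    return IntramuscularCoherence(independent_record).fit()
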