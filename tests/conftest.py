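import numpy as np
import pytest

import posturekit as pk
from posturekit.synthetic import (
    DEFAULT_DYNAMICS,
    MountModel,
    PostureSpec,
    default_protocol,
)


@pytest.fixture(scope="session")
def benchmark15():
    """The full 15-participant-day labelled benchmark (shared across tests)."""
    return pk.make_benchmark(n_days=15, seed=1)


@pytest.fixture(scope="session")
def prepared15(benchmark15):
    return pk.prepare_benchmark(benchmark15)


@pytest.fixture(scope="session")
def small_benchmark():
    """Three short days (20 s segments) for cheap unit-level checks."""
    return pk.make_benchmark(n_days=3, seed=7, segment_s=20.0)


def exact_postures(angle_rows):
    """Posture specs with zero jitter, for exact parameter-recovery tests."""
    return {
        label: PostureSpec(label, dict(zip(("waist", "thigh", "ankle"), angles)), jitter_sd=0.0)
        for label, angles in angle_rows.items()
    }


@pytest.fixture
def noiseless_day():
    """Identity mount, zero jitter/noise day: angles are exactly recoverable."""
    postures = exact_postures(
        {
            "standing": (0.0, 0.0, 0.0),
            "sitting": (10.0, 85.0, 20.0),
            "lying": (85.0, 88.0, 88.0),
            "legs_outstretched": (40.0, 85.0, 80.0),
        }
    )
    protocol = default_protocol(segment_s=10.0)
    rec, track = pk.simulate_day(
        protocol,
        postures=postures,
        dynamics=DEFAULT_DYNAMICS,
        mount=MountModel.identity(("waist", "thigh", "ankle")),
        noise_sd=0.0,
        rng=0,
    )
    return rec, track, postures
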