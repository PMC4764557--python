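import numpy as np
import pytest

from walltrack.behavior import (
    CorridorTrial,
    CouplingParams,
    TrackingPolicy,
    simulate_session,
)


@pytest.fixture(scope="session")
def coupling() -> CouplingParams:
    return CouplingParams()


@pytest.fixture(scope="session")
def open_loop_session(coupling):
    """30 open-loop trials with hold distances tiling the corridor (ideal runner).

    The shared fixture for tuning-recovery tests: 4-s trials (1 s in,
    2 s hold, 1 s out), hold distances spanning 4-34 mm, constant
    20 cm/s running.
    """
    trials = [
        CorridorTrial(mode="open_loop", open_loop_distance=float(d))
        for d in np.linspace(coupling.min_wall_distance, coupling.max_wall_distance, 30)
    ]
    policy = TrackingPolicy(kind="ideal", speed=20.0)
    return simulate_session(trials, policy, coupling, seed=0)
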