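import numpy as np
import pandas as pd
import pytest

from echowing.simulate import FlightPlan, SegmentSpec, generate_flight, simulate_recording


@pytest.fixture(scope="session")
def commute_plan():
    """10 s of commuting flight: 7 Hz wingbeat, one call per wingbeat at 176 deg."""
    return FlightPlan(
        [SegmentSpec("commute", 10.0, 7.0, 5.0, calls_per_wingbeat=1, sl_efd_db=82.0)],
        seed=11,
    )


@pytest.fixture(scope="session")
def commute_truth(commute_plan):
    return generate_flight(commute_plan)


@pytest.fixture(scope="session")
def commute_recording(commute_plan):
    """Noise-free accel + low-noise-floor audio for round-trip checks."""
    return simulate_recording(commute_plan, accel_noise_sd=0.0, noise_floor_db=30.0)


def make_calls(times_s, sl_efd=82.0):
    """Minimal call table from explicit peak times."""
    t = np.asarray(times_s, dtype=float)
    df = pd.DataFrame({"t_peak": t})
    df["sl_efd"] = sl_efd
    df["sl_rms"] = df["sl_efd"] + 25.0
    df["interval_prev_ms"] = df["t_peak"].diff() * 1e3
    return df


@pytest.fixture
def call_table_factory():
    return make_calls
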