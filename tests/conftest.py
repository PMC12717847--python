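import numpy as np
import pandas as pd
import pytest

from driftforage import SimConfig, simulate_world
from driftforage.pipeline import replicate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(n_seals=3, days_per_seal=25, dives_per_day_mean=25,
                     transmitted_dives_range=(8, 25), emit_profiles=True,
                     seed=42)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return simulate_world(tiny_config)


@pytest.fixture(scope="session")
def study_bundle():
    """One bundle at the study scale (30 seals x 180 days)."""
    return simulate_world(SimConfig(seed=11))


@pytest.fixture(scope="session")
def chain_data():
    """Mid-sized simulation pushed through the full analysis chain."""
    return replicate_dataset(SimConfig(n_seals=10, days_per_seal=90, seed=2),
                             windows=(1, 2))


def make_valid_dive(i: int, seal="sealA") -> dict:
    """A structurally valid summarised V/U dive for filter tests."""
    depth = 300.0 + (i % 7) * 25.0
    dur = 1200.0 + (i % 5) * 60.0
    return {
        "seal_id": seal, "start_time": 2000.0 * i,
        "t1": 260.0, "d1": 0.9 * depth, "t2": 500.0, "d2": depth,
        "t3": 700.0, "d3": 0.8 * depth, "t4": dur - 250.0, "d4": 0.85 * depth,
        "max_depth": depth, "duration": dur, "surface_interval": 120.0,
    }


@pytest.fixture()
def valid_dives():
    return pd.DataFrame([make_valid_dive(i) for i in range(100)])
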