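import numpy as np
import pandas as pd
import pytest

from freedecode.synth import (
    BehaviorConfig,
    EventTable,
    SignalConfig,
    VolumeLayout,
    simulate_behavior,
    simulate_subject_bold,
)


@pytest.fixture(scope="session")
def small_layout() -> VolumeLayout:
    """12^3 grid with a radius-5 mask and a radius-2.5 informative region."""
    return VolumeLayout(shape=(12, 12, 12), mask_radius=5.0, region_radius=2.5)


@pytest.fixture(scope="session")
def behavior_cfg() -> BehaviorConfig:
    return BehaviorConfig(n_runs=10, seed=11)


@pytest.fixture(scope="session")
def events(behavior_cfg) -> list[EventTable]:
    return simulate_behavior(behavior_cfg)


@pytest.fixture(scope="session")
def signal_cfg() -> SignalConfig:
    return SignalConfig(seed=11)


@pytest.fixture(scope="session")
def bold_runs(events, small_layout, signal_cfg):
    return simulate_subject_bold(events, small_layout, signal_cfg)


def make_events(onsets, choices, run_id=0, valid=None, probe_delay=1.5):
    """Hand-built event table for targeted design-matrix tests."""
    onsets = np.asarray(onsets, float)
    n = len(onsets)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    trials = pd.DataFrame(
        {
            "onset": onsets,
            "choice": np.asarray(choices, str),
            "valid": valid,
            "probe_onset": onsets + probe_delay,
            "probe_side": np.asarray(choices, str),
            "letter_offset": np.zeros(n, int),
        }
    )
    return EventTable(run_id=run_id, trials=trials)
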