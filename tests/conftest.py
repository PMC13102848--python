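import dataclasses

import numpy as np
import pytest

from erpkit import (
    SubjectParams,
    SystemProfile,
    make_sequence,
    simulate_subject_epochs,
    system_presets,
)


@pytest.fixture(scope="session")
def short_sequence():
    """One 20-stimulus block (14 Standard / 3 Target / 3 Novel)."""
    return make_sequence(1, 20, seed=0)


@pytest.fixture(scope="session")
def mini_profile():
    """Small frontocentral montage at 250 Hz for fast simulations."""
    return SystemProfile("mini", ["Fz", "FCz", "Cz", "F3", "F4", "Pz"],
                         fs_hz=250.0, lag_ms=0.0, noise_scale_uv=10.0)


@pytest.fixture(scope="session")
def noiseless_profile(mini_profile):
    return dataclasses.replace(mini_profile, noise_scale_uv=0.0)


def flat_params(n100_uv=-5.0, p300_uv=4.0, n100_lat_ms=100.0,
                p300_lat_ms=300.0, seed=0, **kw) -> SubjectParams:
    """SubjectParams with the same amplitudes for every condition."""
    conds = ("Standard", "Target", "Novel")
    return SubjectParams(
        n100_amp_uv={c: n100_uv for c in conds},
        p300_amp_uv={c: p300_uv for c in conds},
        n100_lat_ms=n100_lat_ms,
        p300_lat_ms=p300_lat_ms,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def noiseless_epochs(noiseless_profile, short_sequence):
    return simulate_subject_epochs(
        noiseless_profile, flat_params(), short_sequence,
        epoch_window_s=(-0.1, 0.7), run_id=0)


@pytest.fixture(scope="session")
def presets():
    return system_presets()


def make_epochs_array(data, fs_hz=250.0, epoch_start_s=-0.1, conditions=None,
                      channel_names=None):
    """EpochsSet straight from an array, for unit tests."""
    from erpkit import EpochsSet

    data = np.asarray(data, dtype=float)
    n_trials, n_ch, _ = data.shape
    if conditions is None:
        conditions = ["Standard"] * n_trials
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    return EpochsSet(data=data, fs_hz=fs_hz, epoch_start_s=epoch_start_s,
                     conditions=np.asarray(conditions, dtype=object),
                     channel_names=channel_names)
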