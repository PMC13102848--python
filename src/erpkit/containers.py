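"""In-memory containers for epoched EEG and averaged ERPs.

Conventions used throughout the package:

* voltages are in microvolts (µV),
* epoched data are ``(n_trials, n_channels, n_samples)`` arrays,
* the epoch time axis always contains t = 0 (stimulus onset) exactly on
  the sampling grid, i.e. ``epoch_start_s`` is an integer number of
  sample periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

CONDITIONS = ("Standard", "Target", "Novel")


def epoch_sample_range(window_s: tuple[float, float], fs_hz: float) -> tuple[int, int]:
    """Snap an epoch window (start, end) in seconds to the sampling grid.

    Returns (start_index, end_index) relative to stimulus onset; the epoch
    then covers samples ``start_index ... end_index - 1`` and always
    includes sample 0.
    """
    start, end = window_s
    if not start < 0 < end:
        raise ValueError(f"epoch window {window_s} must contain t=0")
    i0 = int(round(start * fs_hz))
    i1 = int(round(end * fs_hz))
    return i0, i1


@dataclass
class EpochsSet:
    """Trials x channels x samples of epoched EEG in µV."""

    data: np.ndarray
    fs_hz: float
    epoch_start_s: float
    conditions: np.ndarray
    channel_names: list[str]
    rejected_mask: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.n_trials, dtype=bool)
        self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)
        self.validate()

    # -- shape helpers -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def t0_index(self) -> int:
        """Sample index of stimulus onset."""
        return int(round(-self.epoch_start_s * self.fs_hz))

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in seconds; contains 0 exactly."""
        i0 = int(round(self.epoch_start_s * self.fs_hz))
        return np.arange(i0, i0 + self.n_samples) / self.fs_hz

    def validate(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match data")
        if len(self.conditions) != self.n_trials:
            raise ValueError("conditions length does not match data")
        if len(self.rejected_mask) != self.n_trials:
            raise ValueError("rejected_mask length does not match data")
        # onset must sit on the sampling grid, within one sample
        if abs(self.epoch_start_s + self.t0_index / self.fs_hz) > 1.0 / self.fs_hz:
            raise ValueError("epoch_start_s is not aligned with the sampling grid")

    # -- selection -----------------------------------------------------
    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present in this recording") from None

    def condition_data(self, condition: str, include_rejected: bool = False) -> np.ndarray:
        """Data of (non-rejected) trials of one condition."""
        sel = self.conditions == condition
        if not include_rejected:
            sel &= ~self.rejected_mask
        return self.data[sel]

    def copy(self, **changes) -> "EpochsSet":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "rejected_mask" not in changes:
            out.rejected_mask = self.rejected_mask.copy()
        return out


@dataclass
class Erp:
    """Per-subject, per-condition average waveform (channels x samples, µV)."""

    mean: np.ndarray
    sem: np.ndarray
    n_trials_used: int
    condition: str
    baseline_window_s: tuple[float, float]
    fs_hz: float
    epoch_start_s: float
    channel_names: list[str]
    subject: str | None = None

    @property
    def times(self) -> np.ndarray:
        i0 = int(round(self.epoch_start_s * self.fs_hz))
        return np.arange(i0, i0 + self.mean.shape[1]) / self.fs_hz

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present in this ERP") from None

    def waveform(self, electrode: str) -> np.ndarray:
        return self.mean[self.channel_index(electrode)]


# -- HDF5 serialization -----------------------------------------------

def save_epochs(path: str | Path, epochs: EpochsSet) -> None:
    """Write an :class:`EpochsSet` to a self-describing HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.attrs["fs_hz"] = epochs.fs_hz
        f.attrs["epoch_start_s"] = epochs.epoch_start_s
        f.create_dataset(
            "conditions", data=np.array([c.encode() for c in epochs.conditions])
        )
        f.create_dataset(
            "channel_names", data=np.array([c.encode() for c in epochs.channel_names])
        )
        f.create_dataset("rejected_mask", data=epochs.rejected_mask)
        meta = f.create_group("meta")
        for k, v in epochs.meta.items():
            meta.attrs[k] = v


def load_epochs(path: str | Path) -> EpochsSet:
    with h5py.File(path, "r") as f:
        return EpochsSet(
            data=f["data"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            epoch_start_s=float(f.attrs["epoch_start_s"]),
            conditions=np.array([c.decode() for c in f["conditions"][()]], dtype=object),
            channel_names=[c.decode() for c in f["channel_names"][()]],
            rejected_mask=f["rejected_mask"][()],
            meta=dict(f["meta"].attrs) if "meta" in f else {},
        )
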