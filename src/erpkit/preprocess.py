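"""Epoch-level preprocessing: re-referencing, filtering, artifact
rejection by within-trial standard deviation, and per-condition averaging.

All filters are zero-phase (forward-backward) Butterworth cascades, so
component latencies are never shifted by preprocessing.  The band-pass is
realized as separate high-pass and low-pass stages to stay numerically
stable at the 0.5 Hz edge.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .containers import CONDITIONS, EpochsSet, Erp

#: candidate channel pairs per reference scheme, tried in order; the first
#: pair fully present in the recording is used (mastoid/earlobe electrodes
#: are external in many montages, so close scalp sites stand in for them).
REFERENCE_CANDIDATES = {
    "linked_mastoids": [("M1", "M2"), ("TP9", "TP10"), ("TP7", "TP8"), ("P7", "P8")],
    "linked_earlobes": [("A1", "A2"), ("M1", "M2"), ("P7", "P8")],
}


def resolve_reference(channel_names: list[str], scheme: str) -> tuple[str, ...]:
    """Channel pair implementing a reference scheme on this montage."""
    if scheme not in REFERENCE_CANDIDATES:
        raise ValueError(f"unknown reference scheme {scheme!r}")
    for pair in REFERENCE_CANDIDATES[scheme]:
        if all(c in channel_names for c in pair):
            return pair
    raise KeyError(
        f"no channel pair for scheme {scheme!r} found in montage {channel_names}"
    )


def rereference(
    epochs: EpochsSet,
    scheme: str = "custom",
    ref_channels: list[str] | None = None,
) -> EpochsSet:
    """Subtract the mean of the reference channels from every channel.

    Applying the same reference twice is idempotent (the reference mean of
    already-referenced data is zero).
    """
    if ref_channels is None:
        ref_channels = list(resolve_reference(epochs.channel_names, scheme))
    missing = [c for c in ref_channels if c not in epochs.channel_names]
    if missing:
        raise KeyError(f"reference channel(s) not in recording: {missing}")
    idx = [epochs.channel_index(c) for c in ref_channels]
    ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    out = epochs.copy(data=epochs.data - ref)
    out.meta = {**epochs.meta, "reference": ",".join(ref_channels)}
    return out


def _sos_filtfilt(data: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass(epochs: EpochsSet, lo_hz: float = 0.5, hi_hz: float = 40.0,
             order: int = 4) -> EpochsSet:
    """Zero-phase band-pass as cascaded high-pass + low-pass Butterworth."""
    nyq = epochs.fs_hz / 2.0
    if hi_hz >= nyq:
        raise ValueError(f"hi_hz={hi_hz} must be below Nyquist ({nyq} Hz)")
    hp = signal.butter(order, lo_hz, btype="highpass", fs=epochs.fs_hz, output="sos")
    lp = signal.butter(order, hi_hz, btype="lowpass", fs=epochs.fs_hz, output="sos")
    out = _sos_filtfilt(_sos_filtfilt(epochs.data, hp), lp)
    return epochs.copy(data=out)


def detrend_epochs(epochs: EpochsSet) -> EpochsSet:
    """Per-epoch linear detrend + demean (per channel)."""
    out = signal.detrend(epochs.data, axis=-1, type="linear")
    return epochs.copy(data=out)


def reject_by_std(
    epochs: EpochsSet, threshold_uv: float
) -> tuple[EpochsSet, pd.DataFrame]:
    """Flag trials whose worst channel exceeds a standard-deviation cap.

    A trial is rejected iff ``max over channels of the within-trial
    standard deviation`` exceeds ``threshold_uv`` (absolute µV).  Retained
    data are untouched; only the mask changes.  Also returns a
    per-condition rejection table (condition, n_trials, n_rejected,
    pct_rejected).
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    trial_std = epochs.data.std(axis=-1, ddof=0).max(axis=1)
    rejected = trial_std > threshold_uv
    out = epochs.copy(rejected_mask=epochs.rejected_mask | rejected)
    rows = []
    for c in CONDITIONS:
        sel = epochs.conditions == c
        n = int(sel.sum())
        nrej = int((out.rejected_mask & sel).sum())
        rows.append({
            "condition": c,
            "n_trials": n,
            "n_rejected": nrej,
            "pct_rejected": 100.0 * nrej / n if n else np.nan,
        })
    table = pd.DataFrame(rows)
    if out.rejected_mask.all():
        import warnings

        warnings.warn("all trials rejected; downstream averaging will fail",
                      RuntimeWarning, stacklevel=2)
    return out, table


def zscore_trial_std(epochs: EpochsSet) -> np.ndarray:
    """Per-trial max-channel STD z-scored across trials (alternative
    rejection metric; the absolute-µV metric is the default)."""
    trial_std = epochs.data.std(axis=-1, ddof=0).max(axis=1)
    return (trial_std - trial_std.mean()) / trial_std.std(ddof=0)


def average_erp(
    epochs: EpochsSet,
    condition: str,
    baseline_window_s: tuple[float, float] = (-0.1, 0.0),
    lowpass_hz: float = 12.0,
    order: int = 4,
) -> Erp:
    """Per-condition ERP: average, 12 Hz zero-phase low-pass, baseline.

    The order of operations is fixed: trials are averaged first, the
    average is low-pass filtered, then the per-channel baseline mean is
    subtracted.  The SEM is computed across trials before filtering.
    """
    trials = epochs.condition_data(condition)
    if trials.shape[0] < 2:
        raise ValueError(
            f"need >= 2 usable trials of condition {condition!r}, "
            f"got {trials.shape[0]}"
        )
    mean = trials.mean(axis=0)
    sem = trials.std(axis=0, ddof=1) / np.sqrt(trials.shape[0])
    sos = signal.butter(order, lowpass_hz, btype="lowpass", fs=epochs.fs_hz,
                        output="sos")
    mean = _sos_filtfilt(mean, sos)
    times = epochs.times
    b0, b1 = baseline_window_s
    bsel = (times >= b0) & (times <= b1)
    if not bsel.any():
        raise ValueError(f"baseline window {baseline_window_s} outside epoch")
    mean = mean - mean[:, bsel].mean(axis=1, keepdims=True)
    return Erp(
        mean=mean,
        sem=sem,
        n_trials_used=int(trials.shape[0]),
        condition=condition,
        baseline_window_s=baseline_window_s,
        fs_hz=epochs.fs_hz,
        epoch_start_s=epochs.epoch_start_s,
        channel_names=list(epochs.channel_names),
        subject=str(epochs.meta.get("subject_seed", "")) or None,
    )


def resample_epochs(epochs: EpochsSet, fs_new_hz: float) -> EpochsSet:
    """Polyphase resampling of all trials to a new rate."""
    from fractions import Fraction

    frac = Fraction(int(round(fs_new_hz * 1000)), int(round(epochs.fs_hz * 1000)))
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(epochs.data, up, down, axis=-1)
    return EpochsSet(
        data=data,
        fs_hz=fs_new_hz,
        epoch_start_s=epochs.epoch_start_s,
        conditions=epochs.conditions.copy(),
        channel_names=list(epochs.channel_names),
        rejected_mask=epochs.rejected_mask.copy(),
        meta=dict(epochs.meta),
    )


def read_raw_epochs(
    raw_path: str | Path,
    events_csv: str | Path,
    epoch_window_s: tuple[float, float] = (-0.1, 0.7),
) -> EpochsSet:
    """Optional EDF/BDF ingestion (requires ``mne``).

    ``events_csv`` must have columns ``onset_s`` and ``condition``.  The
    synthetic generator is the primary data source; this entry point exists
    for applying the pipeline to real recordings.
    """
    raw_path = Path(raw_path)
    if not raw_path.exists():
        raise FileNotFoundError(raw_path)
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF/BDF ingestion requires the 'mne' package") from exc
    events = pd.read_csv(events_csv)
    for col in ("onset_s", "condition"):
        if col not in events.columns:
            raise ValueError(f"events table must have a {col!r} column")
    reader = mne.io.read_raw_bdf if raw_path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(raw_path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    sig = raw.get_data() * 1e6  # volts -> µV
    from .containers import epoch_sample_range

    i0, i1 = epoch_sample_range(epoch_window_s, fs)
    n = i1 - i0
    trials, labels = [], []
    for _, row in events.iterrows():
        k = int(round(row["onset_s"] * fs))
        if k + i0 < 0 or k + i1 > sig.shape[1]:
            continue
        trials.append(sig[:, k + i0 : k + i1])
        labels.append(str(row["condition"]))
    if not trials:
        raise ValueError("no event fits inside the recording")
    return EpochsSet(
        data=np.stack(trials),
        fs_hz=fs,
        epoch_start_s=i0 / fs,
        conditions=np.asarray(labels, dtype=object),
        channel_names=list(raw.ch_names),
        meta={"source": str(raw_path)},
    )
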