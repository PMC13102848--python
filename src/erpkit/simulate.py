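"""Synthetic auditory-oddball stimulus sequences and multi-system EEG epochs.

The generator emulates a three-sound oddball session: frequent Standard
tones, rare Target tones (to be detected by button press) and rare Novel
sounds, presented in blocks with a fixed offset-to-onset inter-stimulus
interval.  Evoked responses are modelled as two Gaussian-windowed
deflections — a negative N100 and a positive P300 — with a frontocentral
Gaussian scalp topography, embedded in 1/f (pink) noise.  Four built-in
system profiles reproduce the channel counts, sampling rates, acquisition
lags and noise levels of a wired research-grade recorder and three mobile
headsets.

Subject-level parameters (amplitudes, latencies, topography) are drawn
once per subject and reused across runs, so repeated runs of the same
subject share the signal and differ only in trial noise — the structure a
test-retest reliability analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CONDITIONS, EpochsSet, epoch_sample_range
from .montage import build_layout, standard_positions

DEFAULT_PROPORTIONS = (0.70, 0.15, 0.15)
DEFAULT_DURATIONS_S = {"Standard": 0.05, "Target": 0.05, "Novel": 0.3}
DEFAULT_ISI_S = 1.0
#: Gaussian envelope widths of the two component templates (seconds)
N100_SIGMA_S = 0.015
P300_SIGMA_S = 0.045

_SHUFFLE_RETRY_CAP = 10_000


class SequenceConstraintError(RuntimeError):
    """The ordering constraints cannot be satisfied for these counts."""


# ---------------------------------------------------------------------
# Stimulus sequences
# ---------------------------------------------------------------------

@dataclass
class StimulusSequence:
    """Ordered stimulus labels with onset times and block structure."""

    labels: list[str]
    onsets_s: np.ndarray      # onset from block start, seconds
    block_index: np.ndarray
    durations_s: np.ndarray
    isi_s: float

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.block_index = np.asarray(self.block_index, dtype=int)
        self.durations_s = np.asarray(self.durations_s, dtype=float)

    @property
    def n_stimuli(self) -> int:
        return len(self.labels)

    @property
    def n_blocks(self) -> int:
        return int(self.block_index.max()) + 1

    def counts(self, block: int | None = None) -> dict[str, int]:
        sel = slice(None) if block is None else self.block_index == block
        labels = np.asarray(self.labels, dtype=object)[sel]
        return {c: int(np.sum(labels == c)) for c in CONDITIONS}

    def block_span_s(self, block: int = 0) -> float:
        """Block duration from first onset to the end of the trailing ISI."""
        sel = self.block_index == block
        onsets = self.onsets_s[sel]
        durs = self.durations_s[sel]
        return float(onsets[-1] + durs[-1] + self.isi_s)

    @property
    def onsets_abs_s(self) -> np.ndarray:
        """Onsets on a session-wide clock, blocks laid out back to back."""
        spans = np.array([self.block_span_s(b) for b in range(self.n_blocks)])
        offsets = np.concatenate([[0.0], np.cumsum(spans)[:-1]])
        return self.onsets_s + offsets[self.block_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "block": self.block_index,
            "index": np.arange(self.n_stimuli),
            "condition": self.labels,
            "onset_s": self.onsets_s,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _valid_order(labels: np.ndarray) -> bool:
    """No Target immediately adjacent to a Novel."""
    a, b = labels[:-1], labels[1:]
    bad = ((a == "Target") & (b == "Novel")) | ((a == "Novel") & (b == "Target"))
    return not bool(bad.any())


def make_sequence(
    n_blocks: int,
    n_per_block: int,
    proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS,
    isi_s: float = DEFAULT_ISI_S,
    durations: dict[str, float] | None = None,
    seed: int = 0,
) -> StimulusSequence:
    """Pseudo-randomized oddball sequence under the two ordering constraints.

    Per block: counts are ``round(n_per_block * proportion)`` per condition;
    the first five and last five stimuli are Standards; at least one
    Standard separates every Target from every Novel.  Valid orders are
    drawn by rejection sampling over shuffles of the middle segment, which
    is unbiased among valid orders.  ISI is offset-to-onset.
    """
    if durations is None:
        durations = dict(DEFAULT_DURATIONS_S)
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    counts = {c: round(n_per_block * p) for c, p in zip(CONDITIONS, proportions)}
    if sum(counts.values()) != n_per_block:
        raise SequenceConstraintError(
            f"rounded per-condition counts {counts} do not sum to {n_per_block}"
        )
    if counts["Standard"] < 10:
        raise SequenceConstraintError(
            "need at least 5 Standards at both block start and end "
            f"(got {counts['Standard']} Standards per block)"
        )
    rng = np.random.default_rng(seed)
    middle = np.array(
        ["Standard"] * (counts["Standard"] - 10)
        + ["Target"] * counts["Target"]
        + ["Novel"] * counts["Novel"],
        dtype=object,
    )
    labels: list[str] = []
    blocks: list[int] = []
    for b in range(n_blocks):
        for attempt in range(_SHUFFLE_RETRY_CAP):
            rng.shuffle(middle)
            if _valid_order(middle):
                break
        else:
            raise SequenceConstraintError(
                "could not separate every Target/Novel pair within "
                f"{_SHUFFLE_RETRY_CAP} shuffles (counts per block: {counts})"
            )
        labels += ["Standard"] * 5 + list(middle) + ["Standard"] * 5
        blocks += [b] * n_per_block
    durs = np.array([durations[c] for c in labels])
    onsets = np.empty(len(labels))
    for b in range(n_blocks):
        sel = np.asarray(blocks) == b
        d = durs[sel]
        onsets[sel] = np.concatenate([[0.0], np.cumsum(d[:-1] + isi_s)])
    return StimulusSequence(
        labels=labels,
        onsets_s=onsets,
        block_index=np.asarray(blocks),
        durations_s=durs,
        isi_s=isi_s,
    )


# ---------------------------------------------------------------------
# System profiles
# ---------------------------------------------------------------------

@dataclass
class SystemProfile:
    """Acquisition characteristics of one EEG system."""

    name: str
    channel_names: list[str]
    fs_hz: float
    lag_ms: float
    noise_scale_uv: float
    reference_scheme: str = "linked_mastoids"

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


_BIOSEMI64 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz",
]
_SMARTING24 = [
    "Fp1", "Fp2", "AFz", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "CPz", "P7", "P3", "Pz", "P4", "P8", "POz", "O1", "O2",
    "M1", "M2",
]
_DSI21 = [
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "Cz", "C3", "C4", "T7",
    "T8", "Pz", "P3", "P4", "P7", "P8", "O1", "O2", "A1", "A2",
]
_EPOC14 = [
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1", "O2", "P8", "T8", "FC6",
    "F4", "F8", "AF4",
]


def system_presets() -> dict[str, SystemProfile]:
    """The four built-in system profiles.

    Channel count / sampling rate pairs are (64, 1024), (24, 250),
    (21, 300) and (14, 128); acquisition lags default to 0, +4, -50 and
    +250 ms; the 14-channel headset is the noisiest.
    """
    return {
        "biosemi64": SystemProfile("biosemi64", list(_BIOSEMI64), 1024.0, 0.0, 8.0,
                                   "linked_mastoids"),
        "smarting24": SystemProfile("smarting24", list(_SMARTING24), 250.0, 4.0, 10.0,
                                    "linked_mastoids"),
        "dsi24": SystemProfile("dsi24", list(_DSI21), 300.0, -50.0, 10.0,
                               "linked_earlobes"),
        "epoc14": SystemProfile("epoc14", list(_EPOC14), 128.0, 250.0, 18.0,
                                "linked_mastoids"),
    }


# ---------------------------------------------------------------------
# Subject parameters
# ---------------------------------------------------------------------

@dataclass
class SubjectParams:
    """Per-subject evoked-response parameters (the 'ground truth')."""

    n100_amp_uv: dict[str, float]          # <= 0, per condition
    p300_amp_uv: dict[str, float]          # >= 0, per condition
    n100_lat_ms: float
    p300_lat_ms: float
    p300_lat_offsets_ms: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CONDITIONS})
    topo_center: tuple[float, float] = (0.0, 0.3)   # Fz/FCz midpoint
    topo_width: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v > 0 for v in self.n100_amp_uv.values()):
            raise ValueError("n100_amp_uv must be <= 0 (negative deflection)")
        if any(v < 0 for v in self.p300_amp_uv.values()):
            raise ValueError("p300_amp_uv must be >= 0 (positive deflection)")


#: Between-subject spreads used by :func:`draw_subject_params`; these are
#: the generator's study conditions, not tuning knobs.
DEFAULT_POPULATION = {
    "n100_amp_mean": {"Standard": -4.0, "Target": -4.5, "Novel": -5.5},
    "p300_amp_mean": {"Standard": 0.5, "Target": 1.5, "Novel": 6.0},
    # independent multiplicative spreads per component: subjects differ in
    # their N100:P300 ratio, which is what individuates waveform *shape*
    # (Pearson correlations are insensitive to overall scaling)
    "n100_gain_sd_log": 0.3,
    "p300_gain_sd_log": 0.4,
    "target_p300_gain_range": (0.0, 2.0),  # some subjects lack a target P3b
    "n100_lat_mean_ms": 100.0,
    "n100_lat_sd_ms": 15.0,
    "p300_lat_mean_ms": 300.0,
    "p300_lat_sd_ms": 35.0,
    "target_lat_jitter_ms": 40.0,     # extra Target-only latency spread
    "topo_center_mean": (0.0, 0.3),
    "topo_center_sd": 0.05,
    "topo_width_mean": 0.6,
    "topo_width_sd": 0.05,
}


def draw_subject_params(seed: int, population: dict | None = None) -> SubjectParams:
    """Draw one subject's parameters from the population distribution."""
    pop = dict(DEFAULT_POPULATION)
    if population:
        pop.update(population)
    rng = np.random.default_rng(seed)
    n100_gain = float(np.exp(rng.normal(0.0, pop["n100_gain_sd_log"])))
    p300_gain = float(np.exp(rng.normal(0.0, pop["p300_gain_sd_log"])))
    n100 = {c: v * n100_gain for c, v in pop["n100_amp_mean"].items()}
    p300 = {c: v * p300_gain for c, v in pop["p300_amp_mean"].items()}
    lo, hi = pop["target_p300_gain_range"]
    p300["Target"] *= float(rng.uniform(lo, hi))
    offsets = {c: 0.0 for c in CONDITIONS}
    offsets["Target"] = float(rng.normal(0.0, pop["target_lat_jitter_ms"]))
    cx, cy = pop["topo_center_mean"]
    sd = pop["topo_center_sd"]
    return SubjectParams(
        n100_amp_uv=n100,
        p300_amp_uv=p300,
        n100_lat_ms=float(rng.normal(pop["n100_lat_mean_ms"], pop["n100_lat_sd_ms"])),
        p300_lat_ms=float(rng.normal(pop["p300_lat_mean_ms"], pop["p300_lat_sd_ms"])),
        p300_lat_offsets_ms=offsets,
        topo_center=(float(rng.normal(cx, sd)), float(rng.normal(cy, sd))),
        topo_width=max(0.2, float(rng.normal(pop["topo_width_mean"],
                                             pop["topo_width_sd"]))),
        seed=seed,
    )


# ---------------------------------------------------------------------
# Noise and epochs
# ---------------------------------------------------------------------

def pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs_hz: float) -> np.ndarray:
    """Unit-variance 1/f-shaped noise along the last axis.

    White Gaussian noise is shaped in the frequency domain with a
    1/sqrt(f) amplitude profile (flat below 1 Hz to keep the spectrum
    finite), then rescaled to unit standard deviation.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec *= shaping
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _component_templates(
    profile: SystemProfile,
    params: SubjectParams,
    times: np.ndarray,
) -> dict[str, np.ndarray]:
    """Noise-free (channels x samples) template per condition."""
    table = standard_positions()
    missing = [c for c in profile.channel_names if c not in table]
    if missing:
        raise KeyError(f"unknown channel name(s): {missing}")
    pos = np.array([table[c] for c in profile.channel_names])
    d2 = np.sum((pos - np.asarray(params.topo_center)) ** 2, axis=1)
    gain = np.exp(-d2 / (2.0 * params.topo_width**2))  # (channels,)
    lag_s = profile.lag_ms / 1000.0
    templates = {}
    for c in CONDITIONS:
        t_n100 = params.n100_lat_ms / 1000.0 + lag_s
        t_p300 = (params.p300_lat_ms + params.p300_lat_offsets_ms[c]) / 1000.0 + lag_s
        for lat, label in ((t_n100, "N100"), (t_p300, "P300")):
            if not times[0] <= lat <= times[-1]:
                raise ValueError(
                    f"{label} latency {lat * 1000:.0f} ms (incl. lag) falls outside "
                    f"the epoch window [{times[0] * 1000:.0f}, {times[-1] * 1000:.0f}] ms"
                )
        wave = (
            params.n100_amp_uv[c] * np.exp(-((times - t_n100) ** 2) / (2 * N100_SIGMA_S**2))
            + params.p300_amp_uv[c] * np.exp(-((times - t_p300) ** 2) / (2 * P300_SIGMA_S**2))
        )
        templates[c] = gain[:, None] * wave[None, :]
    return templates


def simulate_subject_epochs(
    profile: SystemProfile,
    params: SubjectParams,
    sequence: StimulusSequence,
    epoch_window_s: tuple[float, float] = (-0.1, 0.7),
    run_id: int = 0,
    artifact_fraction: float = 0.0,
    artifact_scale: float = 10.0,
) -> EpochsSet:
    """Simulate one subject's epoched recording on one system.

    Every trial is the condition template plus fresh pink noise of scale
    ``profile.noise_scale_uv``.  The same ``params.seed`` with a different
    ``run_id`` reuses the subject's evoked parameters with new noise
    (test-retest structure).  A fraction of trials can be corrupted with
    high-variance noise to emulate movement artifacts.
    """
    i0, i1 = epoch_sample_range(epoch_window_s, profile.fs_hz)
    times = np.arange(i0, i1) / profile.fs_hz
    templates = _component_templates(profile, params, times)
    n_trials = sequence.n_stimuli
    n_ch, n_samp = len(profile.channel_names), len(times)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(run_id,))
    )
    data = np.empty((n_trials, n_ch, n_samp))
    labels = np.asarray(sequence.labels, dtype=object)
    noise = pink_noise(rng, (n_trials, n_ch, n_samp), profile.fs_hz)
    noise *= profile.noise_scale_uv
    if artifact_fraction > 0:
        n_bad = int(round(artifact_fraction * n_trials))
        bad = rng.choice(n_trials, size=n_bad, replace=False)
        noise[bad] *= artifact_scale
    for c in CONDITIONS:
        sel = labels == c
        data[sel] = templates[c][None, :, :]
    data += noise
    return EpochsSet(
        data=data,
        fs_hz=profile.fs_hz,
        epoch_start_s=i0 / profile.fs_hz,
        conditions=labels,
        channel_names=list(profile.channel_names),
        meta={"system": profile.name, "subject_seed": params.seed, "run_id": run_id},
    )


def subject_layout(profile: SystemProfile):
    """Channel layout (positions + neighbour graph) for a system profile."""
    return build_layout(profile.channel_names)


# ---------------------------------------------------------------------
# Behavioral responses
# ---------------------------------------------------------------------

def simulate_presses(
    sequence: StimulusSequence,
    p_hit: float = 0.9,
    rt_mean_s: float = 0.45,
    rt_sd_s: float = 0.10,
    fa_per_nontarget: float = 0.005,
    seed: int = 0,
) -> list[float]:
    """Key-press times (session clock) for a simulated participant.

    Hits occur with probability ``p_hit`` per Target, at a truncated-normal
    reaction time inside the scoring window; each non-target draws a false
    alarm with a small probability.
    """
    rng = np.random.default_rng(seed)
    onsets = sequence.onsets_abs_s
    labels = np.asarray(sequence.labels, dtype=object)
    presses: list[float] = []
    for onset, lab in zip(onsets, labels):
        if lab == "Target":
            if rng.random() < p_hit:
                rt = float(np.clip(rng.normal(rt_mean_s, rt_sd_s), 0.21, 1.49))
                presses.append(onset + rt)
        elif rng.random() < fa_per_nontarget:
            presses.append(onset + float(rng.uniform(0.2, 0.9)))
    return sorted(presses)
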