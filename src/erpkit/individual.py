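"""Per-subject analyses: binned significance maps, single-electrode
temporal cluster detection, spatial cluster detection in group-defined
windows, the waveform typicality index, and detection-rate tables.

The typicality score of a participant is the mean Pearson correlation
between their ERP waveform (at one electrode, from stimulus onset to the
end of the epoch) and the waveforms of every other participant recorded
with the same system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CONDITIONS, EpochsSet, Erp
from .cluster import ClusterResult, sign_flip_cluster_test
from .montage import ChannelLayout

#: electrode preference chain for single-electrode analyses ('F4' stands in
#: on montages without 'Fz', e.g. the 14-channel headset)
ELECTRODE_FALLBACK = ("Fz", "F4", "F3", "FCz", "Cz")

COMPONENT_TAILS = {"N100": "negative", "P300": "positive"}


def resolve_electrode(channel_names: list[str],
                      chain: tuple[str, ...] = ELECTRODE_FALLBACK) -> str:
    for name in chain:
        if name in channel_names:
            return name
    raise KeyError(f"none of {chain} present in montage {channel_names}")


# ---------------------------------------------------------------------
# Analysis 1: binned significance maps
# ---------------------------------------------------------------------

@dataclass
class SignificanceMap:
    """Fraction of subjects with a significant t-test per channel and bin."""

    values_negative: np.ndarray   # (channels, bins) in [0, 1]
    values_positive: np.ndarray
    bin_edges_ms: np.ndarray
    alpha: float
    channel_names: list[str]
    n_subjects: int
    tail: str = "negative"

    @property
    def values(self) -> np.ndarray:
        return self.values_negative if self.tail == "negative" else self.values_positive


def _bin_trials(epochs: EpochsSet, bin_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Average trials within fixed-width time bins (edge forced at t=0).

    Returns (trials x channels x bins means, bin edges in seconds).
    """
    n_per_bin = bin_s * epochs.fs_hz
    if abs(n_per_bin - round(n_per_bin)) > 1e-9 or round(n_per_bin) < 1:
        raise ValueError(
            f"bin width {bin_s * 1000:.1f} ms is not a positive multiple of the "
            f"sample period at {epochs.fs_hz} Hz; resample first"
        )
    n_per_bin = int(round(n_per_bin))
    times = epochs.times
    # bin index relative to t=0 so a bin edge falls at stimulus onset
    sample_idx = np.round(times * epochs.fs_hz).astype(int)
    bin_idx = np.floor_divide(sample_idx, n_per_bin)
    bins = np.unique(bin_idx)
    binned = np.stack(
        [epochs.data[:, :, bin_idx == b].mean(axis=-1) for b in bins], axis=-1
    )
    edges = np.append(bins, bins[-1] + 1) * n_per_bin / epochs.fs_hz
    return binned, edges


def binned_significance_map(
    per_subject_epochs: list[EpochsSet],
    condition: str | None = None,
    bin_ms: float = 20.0,
    alpha: float = 0.05,
    tail: str = "negative",
) -> SignificanceMap:
    """Across-subject map of uncorrected one-tailed t-test flags.

    Per subject: trials (optionally of one condition) are averaged within
    ``bin_ms`` bins per channel, a one-tailed one-sample t-test is run per
    (channel, bin), and bins with p < alpha are flagged.  The map value is
    the fraction of subjects flagged.  Both tails are computed and stored;
    ``tail`` selects which one ``.values`` reports.
    """
    if not per_subject_epochs:
        raise ValueError("need at least one subject")
    ref = per_subject_epochs[0]
    flags_neg, flags_pos = [], []
    edges = None
    for ep in per_subject_epochs:
        if ep.channel_names != ref.channel_names or ep.fs_hz != ref.fs_hz:
            raise ValueError("subjects must share channels and sampling rate")
        data = (ep.condition_data(condition) if condition
                else ep.data[~ep.rejected_mask])
        sub = EpochsSet(data=data, fs_hz=ep.fs_hz, epoch_start_s=ep.epoch_start_s,
                        conditions=np.asarray(["x"] * data.shape[0], dtype=object),
                        channel_names=ep.channel_names)
        binned, edges = _bin_trials(sub, bin_ms / 1000.0)
        n = binned.shape[0]
        mean = binned.mean(axis=0)
        sd = binned.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        p_neg = stats.t.cdf(t, df=n - 1)
        p_pos = stats.t.sf(t, df=n - 1)
        flags_neg.append(p_neg < alpha)
        flags_pos.append(p_pos < alpha)
    return SignificanceMap(
        values_negative=np.mean(flags_neg, axis=0),
        values_positive=np.mean(flags_pos, axis=0),
        bin_edges_ms=edges * 1000.0,
        alpha=alpha,
        channel_names=list(ref.channel_names),
        n_subjects=len(per_subject_epochs),
        tail=tail,
    )


# ---------------------------------------------------------------------
# Analysis 2: temporal clustering at one electrode
# ---------------------------------------------------------------------

def individual_temporal_detect(
    epochs: EpochsSet,
    electrode: str | None = None,
    alpha_tail: float = 0.025,
    n_permutations: int = 1000,
    seed: int = 0,
    conditions: tuple[str, ...] = CONDITIONS,
) -> dict[str, ClusterResult]:
    """Per-condition temporal cluster test on one subject, one electrode.

    Both tails are tested at ``alpha_tail`` each.  When the requested
    electrode is absent the standard fallback chain is used and the choice
    recorded in the result metadata.
    """
    requested = electrode
    if electrode is None or electrode not in epochs.channel_names:
        electrode = resolve_electrode(epochs.channel_names)
    ch = epochs.channel_index(electrode)
    out: dict[str, ClusterResult] = {}
    for cond in conditions:
        trials = epochs.condition_data(cond)[:, ch, :]
        if trials.shape[0] < 2:
            raise ValueError(f"need >= 2 usable trials for condition {cond!r}")
        res = sign_flip_cluster_test(
            trials,
            alpha_forming=2 * alpha_tail,
            tail="two_sided",
            n_permutations=n_permutations,
            seed=seed,
            times_s=epochs.times,
        )
        res.times_s = epochs.times
        res.meta = {"electrode": electrode, "requested_electrode": requested,
                    "condition": cond}
        out[cond] = res
    return out


# ---------------------------------------------------------------------
# Analysis 3: spatial clustering in group-defined windows
# ---------------------------------------------------------------------

def individual_spatial_detect(
    epochs: EpochsSet,
    window_ms: tuple[float, float],
    layout: ChannelLayout,
    tail: str,
    alpha_tail: float = 0.025,
    n_permutations: int = 1000,
    seed: int = 0,
    condition: str | None = None,
) -> ClusterResult:
    """Electrode-cluster test of the window-averaged response vs zero.

    Trials are averaged within ``window_ms`` per channel, one-sample
    t-tests are run per channel, and suprathreshold channels are grouped
    into connected components of the layout's neighbour graph; the
    sign-flip max-mass null corrects across electrodes.
    """
    if layout.names != epochs.channel_names:
        raise ValueError("layout does not cover the recording's channels")
    times_ms = epochs.times * 1000.0
    w0, w1 = window_ms
    sel = (times_ms >= w0) & (times_ms <= w1)
    if not sel.any():
        raise ValueError(f"window {window_ms} ms lies outside the epoch")
    data = (epochs.condition_data(condition) if condition
            else epochs.data[~epochs.rejected_mask])
    window_means = data[:, :, sel].mean(axis=-1)  # (trials, channels)
    res = sign_flip_cluster_test(
        window_means,
        alpha_forming=alpha_tail,
        tail=tail,
        n_permutations=n_permutations,
        seed=seed,
        adjacency=layout.neighbor_graph,
    )
    res.meta = {"window_ms": window_ms, "condition": condition, "tail": tail}
    return res


# ---------------------------------------------------------------------
# Typicality
# ---------------------------------------------------------------------

@dataclass
class TypicalityTable:
    """Pairwise waveform correlations and per-subject typicality scores."""

    scores: pd.Series          # index = subject, values in [-1, 1]
    pairwise_r: pd.DataFrame   # symmetric, unit diagonal
    electrode: str
    condition: str


def typicality_scores(
    erps: list[Erp],
    electrode: str | None = None,
    condition: str | None = None,
    subjects: list[str] | None = None,
) -> TypicalityTable:
    """Typicality of each subject's waveform among a cohort.

    Pearson correlations between every pair of subjects' ERP waveforms at
    one electrode, over the post-onset epoch (t >= 0; the pre-stimulus
    baseline is excluded).  A subject's score is the mean of their
    correlations with all others.
    """
    if len(erps) < 3:
        raise ValueError("need at least 3 subjects")
    ref = erps[0]
    if electrode is None or electrode not in ref.channel_names:
        electrode = resolve_electrode(ref.channel_names)
    if condition is None:
        condition = ref.condition
    if subjects is None:
        subjects = [e.subject or f"S{i+1}" for i, e in enumerate(erps)]
    waves = []
    for e, s in zip(erps, subjects):
        if e.condition != condition:
            raise ValueError(f"subject {s}: ERP condition {e.condition!r} != {condition!r}")
        sel = e.times >= 0
        w = e.waveform(electrode)[sel]
        if np.ptp(w) == 0:
            raise ValueError(f"subject {s}: constant waveform, correlation undefined")
        waves.append(w)
    mat = np.corrcoef(np.stack(waves))
    n = len(erps)
    scores = (mat.sum(axis=1) - 1.0) / (n - 1)
    return TypicalityTable(
        scores=pd.Series(scores, index=subjects, name="typicality"),
        pairwise_r=pd.DataFrame(mat, index=subjects, columns=subjects),
        electrode=electrode,
        condition=condition,
    )


def assemble_typicality_long_table(
    tables: dict[str, dict[str, TypicalityTable]] | dict[str, TypicalityTable],
) -> pd.DataFrame:
    """Tidy (subject, system, condition, score) records for model fitting.

    Accepts either ``{system: {condition: table}}`` or ``{system: table}``.
    The mixed-model fit itself is delegated to external statistical
    routines; this only assembles their long-format input.
    """
    records = []
    for system, entry in tables.items():
        conds = entry if isinstance(entry, dict) else {entry.condition: entry}
        for cond, tab in conds.items():
            for subject, score in tab.scores.items():
                records.append({"subject": subject, "system": system,
                                "condition": cond, "score": float(score)})
    df = pd.DataFrame(records)
    if df.duplicated(["subject", "system", "condition"]).any():
        dup = df[df.duplicated(["subject", "system", "condition"])]
        raise ValueError(f"duplicate (subject, system, condition) keys:\n{dup}")
    return df


# ---------------------------------------------------------------------
# Detection tables
# ---------------------------------------------------------------------

def _detected(result: ClusterResult, component: str, alpha: float,
              group_window_ms: tuple[float, float] | None) -> bool:
    sign = 1 if COMPONENT_TAILS[component] == "positive" else -1
    for c in result.significant(alpha):
        if c.sign != sign:
            continue
        if group_window_ms is None:
            return True
        if result.times_s is None:
            raise ValueError("overlap rule needs times_s on the ClusterResult")
        t_ms = result.times_s[c.member_indices] * 1000.0
        if np.any((t_ms >= group_window_ms[0]) & (t_ms <= group_window_ms[1])):
            return True
    return False


def detection_rate(
    results: dict[str, ClusterResult],
    component: str,
    alpha: float = 0.05,
    group_window_ms: tuple[float, float] | None = None,
) -> float:
    """Percent of subjects with >= 1 significant cluster of the component's
    sign (optionally required to intersect the group window), rounded to
    integer percent."""
    if component not in COMPONENT_TAILS:
        raise ValueError(f"component must be one of {sorted(COMPONENT_TAILS)}")
    if not results:
        return 0.0
    hits = sum(_detected(r, component, alpha, group_window_ms)
               for r in results.values())
    return float(round(100.0 * hits / len(results)))


def detection_table(
    per_dataset_results: dict[str, dict[str, dict[str, ClusterResult]]],
    method: str,
    alpha: float = 0.05,
    group_windows_ms: dict[tuple[str, str], tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Detection-rate table: rows = dataset, columns = (component, condition).

    ``per_dataset_results[dataset][condition][subject]`` holds that
    subject's cluster result.  For the temporal method a group window per
    (condition, component) may constrain what counts as detected.
    """
    if method not in ("temporal", "spatial"):
        raise ValueError("method must be 'temporal' or 'spatial'")
    rows = []
    for dataset, by_cond in per_dataset_results.items():
        row: dict[str, object] = {"dataset": dataset, "method": method}
        for cond, per_subject in by_cond.items():
            for component in ("N100", "P300"):
                window = None
                if group_windows_ms is not None:
                    window = group_windows_ms.get((cond, component))
                row[f"{component}_{cond}"] = detection_rate(
                    per_subject, component, alpha=alpha, group_window_ms=window)
        rows.append(row)
    return pd.DataFrame(rows)
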