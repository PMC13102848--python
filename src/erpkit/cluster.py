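"""Group-level statistics: grand averages, one-sample sign-flip
cluster-permutation tests (temporal and spatial), component-window
extraction, and cross-system lag/correlation.

The cluster test thresholds pointwise one-sample t statistics, aggregates
suprathreshold points into clusters (consecutive samples, or connected
electrodes on a neighbour graph), uses the summed t as cluster mass, and
compares each observed mass against the permutation distribution of the
maximal cluster mass under random sign flips of the observations.  With
n observations and 2^n <= 4096 the sign-flip null is enumerated
exhaustively and the resulting p-values are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

EXHAUSTIVE_LIMIT = 4096

TAILS = ("negative", "positive", "two_sided")


@dataclass
class Cluster:
    member_indices: np.ndarray
    mass: float
    p_corrected: float

    @property
    def sign(self) -> int:
        return 1 if self.mass > 0 else -1


@dataclass
class ClusterResult:
    """Clusters with family-wise corrected p-values from a sign-flip null."""

    clusters: list[Cluster]
    tail: str
    alpha_forming: float
    n_permutations: int
    exhaustive: bool
    null_max_mass: np.ndarray
    t_obs: np.ndarray
    n_obs: int
    times_s: np.ndarray | None = None
    mean_obs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < alpha]

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        mask = np.zeros(self.t_obs.shape[0], dtype=bool)
        for c in self.significant(alpha):
            mask[c.member_indices] = True
        return mask


def _pointwise_t(mean: np.ndarray, ss: np.ndarray, n: int) -> np.ndarray:
    """One-sample t from the mean and the (flip-invariant) sum of squares."""
    var = (ss - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    # zero-variance points: t is +/- infinity if the mean is nonzero, 0 otherwise
    degenerate = var == 0
    if np.any(degenerate):
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate, np.sign(mean) * np.inf, t)
        t = np.where(degenerate & (mean == 0), 0.0, t)
    return t


def _contiguous_clusters(mask: np.ndarray) -> list[np.ndarray]:
    """Runs of consecutive True samples."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [np.arange(edges[i], edges[i + 1]) for i in range(0, len(edges), 2)]


def _graph_clusters(mask: np.ndarray, adjacency: dict[int, list[int]]) -> list[np.ndarray]:
    """Connected components of the suprathreshold set on a neighbour graph."""
    active = set(np.flatnonzero(mask).tolist())
    comps: list[np.ndarray] = []
    while active:
        seed = active.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            node = frontier.pop()
            for nb in adjacency[node]:
                if nb in active:
                    active.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(np.array(sorted(comp)))
    return comps


def _find_clusters(
    t: np.ndarray,
    t_crit: float,
    tail: str,
    adjacency: dict[int, list[int]] | None,
) -> list[tuple[np.ndarray, float]]:
    out: list[tuple[np.ndarray, float]] = []
    masks = []
    if tail in ("positive", "two_sided"):
        masks.append(t > t_crit)
    if tail in ("negative", "two_sided"):
        masks.append(t < -t_crit)
    for mask in masks:
        groups = (_graph_clusters(mask, adjacency) if adjacency is not None
                  else _contiguous_clusters(mask))
        for idx in groups:
            out.append((idx, float(t[idx].sum())))
    return out


def _sign_matrix(n: int, n_permutations: int, rng: np.random.Generator,
                 method: str = "auto") -> tuple[np.ndarray, bool]:
    """Sign-flip assignments: exhaustive enumeration when 2^n is small."""
    if method not in ("auto", "exhaustive", "montecarlo"):
        raise ValueError("method must be 'auto', 'exhaustive' or 'montecarlo'")
    exhaust = (method == "exhaustive"
               or (method == "auto" and 2**n <= EXHAUSTIVE_LIMIT))
    if exhaust:
        if 2**n > EXHAUSTIVE_LIMIT:
            raise ValueError(f"2^{n} assignments exceed the exhaustive limit")
        bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        return bits * 2.0 - 1.0, True
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    return signs, False


def sign_flip_cluster_test(
    data: np.ndarray,
    alpha_forming: float = 0.05,
    tail: str = "two_sided",
    n_permutations: int = 1000,
    seed: int | None = 0,
    adjacency: dict[int, list[int]] | None = None,
    times_s: np.ndarray | None = None,
    method: str = "auto",
) -> ClusterResult:
    """One-sample cluster-permutation test of ``data`` (n x points) vs 0.

    ``two_sided`` runs both tails as two one-tailed tests at
    ``alpha_forming / 2`` each; the null distribution is the maximal
    absolute cluster mass per permutation, so the correction controls the
    family-wise error across the tested dimension and both tails.
    Monte-Carlo p-values include the observed permutation
    (``(count + 1) / (n_permutations + 1)``); exhaustive p-values are exact
    counts over all 2^n assignments.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2D (observations x points)")
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not 0 < alpha_forming < 1:
        raise ValueError("alpha_forming must be in (0, 1)")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")

    per_tail_alpha = alpha_forming / 2 if tail == "two_sided" else alpha_forming
    t_crit = float(stats.t.ppf(1 - per_tail_alpha, df=n - 1))

    ss = (data**2).sum(axis=0)  # invariant under sign flips
    mean_obs = data.mean(axis=0)
    t_obs = _pointwise_t(mean_obs, ss, n)
    observed = _find_clusters(t_obs, t_crit, tail, adjacency)

    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n, n_permutations, rng, method)
    means = signs @ data / n  # (n_perm, points)
    null_max = np.zeros(signs.shape[0])
    for p in range(signs.shape[0]):
        t_p = _pointwise_t(means[p], ss, n)
        masses = [abs(m) for _, m in _find_clusters(t_p, t_crit, tail, adjacency)]
        if masses:
            null_max[p] = max(masses)

    clusters = []
    for idx, mass in observed:
        count = int(np.sum(null_max >= abs(mass)))
        if exhaustive:
            p_val = count / signs.shape[0]
        else:
            p_val = (count + 1) / (signs.shape[0] + 1)
        clusters.append(Cluster(member_indices=idx, mass=mass, p_corrected=p_val))
    clusters.sort(key=lambda c: c.member_indices[0])
    return ClusterResult(
        clusters=clusters,
        tail=tail,
        alpha_forming=alpha_forming,
        n_permutations=signs.shape[0],
        exhaustive=exhaustive,
        null_max_mass=null_max,
        t_obs=t_obs,
        n_obs=n,
        times_s=None if times_s is None else np.asarray(times_s, dtype=float),
        mean_obs=mean_obs,
    )


def temporal_cluster_test(
    trials_or_subjects: np.ndarray,
    alpha_forming: float = 0.05,
    tail: str = "two_sided",
    n_permutations: int = 1000,
    seed: int | None = 0,
    times_s: np.ndarray | None = None,
    method: str = "auto",
) -> ClusterResult:
    """Cluster test over consecutive time samples (rows = trials/subjects)."""
    return sign_flip_cluster_test(
        trials_or_subjects,
        alpha_forming=alpha_forming,
        tail=tail,
        n_permutations=n_permutations,
        seed=seed,
        adjacency=None,
        times_s=times_s,
        method=method,
    )


# ---------------------------------------------------------------------
# Grand averages and component windows
# ---------------------------------------------------------------------

def grand_average(erps: list) -> "Erp":
    """Unweighted mean ERP across subjects; SEM across subjects."""
    from .containers import Erp

    if not erps:
        raise ValueError("no ERPs given")
    ref = erps[0]
    for e in erps[1:]:
        if e.channel_names != ref.channel_names:
            raise ValueError("ERPs have mismatched channels")
        if e.mean.shape != ref.mean.shape or e.fs_hz != ref.fs_hz or \
                abs(e.epoch_start_s - ref.epoch_start_s) > 0.5 / ref.fs_hz:
            raise ValueError("ERPs have mismatched time axes")
        if e.condition != ref.condition:
            raise ValueError("ERPs mix conditions")
    stack = np.stack([e.mean for e in erps])
    sem = (stack.std(axis=0, ddof=1) / np.sqrt(len(erps))
           if len(erps) > 1 else np.zeros_like(ref.mean))
    return Erp(
        mean=stack.mean(axis=0),
        sem=sem,
        n_trials_used=len(erps),
        condition=ref.condition,
        baseline_window_s=ref.baseline_window_s,
        fs_hz=ref.fs_hz,
        epoch_start_s=ref.epoch_start_s,
        channel_names=list(ref.channel_names),
        subject="grand_average",
    )


def find_component_windows(
    cluster_result: ClusterResult,
    time_axis_s: np.ndarray,
    waveform: np.ndarray | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """N100/P300 windows from a single-electrode temporal cluster test.

    The earliest significant negative cluster defines the N100 window with
    the latency of its most negative sample; the earliest significant
    positive cluster after it (or anywhere, if no N100) defines the P300
    window with its most positive sample.  Components without a
    significant cluster are reported as not significant (NaN window).
    """
    time_axis_s = np.asarray(time_axis_s, dtype=float)
    values = waveform if waveform is not None else cluster_result.mean_obs
    if values is None:
        values = cluster_result.t_obs
    sig = cluster_result.significant(alpha)
    neg = sorted([c for c in sig if c.sign < 0], key=lambda c: c.member_indices[0])
    pos = sorted([c for c in sig if c.sign > 0], key=lambda c: c.member_indices[0])

    rows = []
    n100 = neg[0] if neg else None
    if n100 is not None:
        idx = n100.member_indices
        peak = idx[np.argmin(values[idx])]
        rows.append({"component": "N100", "significant": True,
                     "window_start_ms": time_axis_s[idx[0]] * 1000,
                     "window_end_ms": time_axis_s[idx[-1]] * 1000,
                     "peak_ms": time_axis_s[peak] * 1000,
                     "p_corrected": n100.p_corrected})
    else:
        rows.append({"component": "N100", "significant": False,
                     "window_start_ms": np.nan, "window_end_ms": np.nan,
                     "peak_ms": np.nan, "p_corrected": np.nan})
    if n100 is not None:
        pos = [c for c in pos if c.member_indices[0] > n100.member_indices[-1]] or pos
    p300 = pos[0] if pos else None
    if p300 is not None:
        idx = p300.member_indices
        peak = idx[np.argmax(values[idx])]
        rows.append({"component": "P300", "significant": True,
                     "window_start_ms": time_axis_s[idx[0]] * 1000,
                     "window_end_ms": time_axis_s[idx[-1]] * 1000,
                     "peak_ms": time_axis_s[peak] * 1000,
                     "p_corrected": p300.p_corrected})
    else:
        rows.append({"component": "P300", "significant": False,
                     "window_start_ms": np.nan, "window_end_ms": np.nan,
                     "peak_ms": np.nan, "p_corrected": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Cross-system lag / correlation
# ---------------------------------------------------------------------

@dataclass
class LagCorrelation:
    lag_ms: float
    r_at_lag: float
    lag_search_ms: tuple[float, float]


def resample_waveform(wave: np.ndarray, fs_old_hz: float, fs_new_hz: float) -> np.ndarray:
    """Polyphase resampling of a 1D waveform."""
    from fractions import Fraction

    frac = Fraction(int(round(fs_new_hz * 1000)), int(round(fs_old_hz * 1000)))
    return signal.resample_poly(np.asarray(wave, dtype=float),
                                frac.numerator, frac.denominator)


def xcorr_lag(
    erp_a: np.ndarray,
    erp_b: np.ndarray,
    fs_common_hz: float,
    max_lag_ms: float = 300.0,
) -> LagCorrelation:
    """Lag of maximal Pearson correlation between two waveforms.

    Both inputs must already share ``fs_common_hz``.  The correlation is
    computed on the overlapping segment at every integer-sample lag within
    ``±max_lag_ms``; a positive lag means ``erp_b`` lags ``erp_a``.  Ties
    are broken toward the smaller absolute lag.
    """
    a = np.asarray(erp_a, dtype=float)
    b = np.asarray(erp_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("waveforms must be 1D")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant waveform")
    max_k = int(round(max_lag_ms / 1000.0 * fs_common_hz))
    if max_k >= min(len(a), len(b)) // 2:
        raise ValueError("max_lag_ms must be below half the waveform duration")
    best = (-np.inf, 0)
    for k in range(-max_k, max_k + 1):
        if k >= 0:
            seg_a, seg_b = a[: len(a) - k or None], b[k:]
        else:
            seg_a, seg_b = a[-k:], b[: len(b) + k]
        m = min(len(seg_a), len(seg_b))
        seg_a, seg_b = seg_a[:m], seg_b[:m]
        if seg_a.std() == 0 or seg_b.std() == 0:
            continue
        r = float(np.corrcoef(seg_a, seg_b)[0, 1])
        if r > best[0] + 1e-12 or (abs(r - best[0]) <= 1e-12 and abs(k) < abs(best[1])):
            best = (r, k)
    if not np.isfinite(best[0]):
        raise ValueError("correlation undefined at every lag")
    return LagCorrelation(
        lag_ms=best[1] / fs_common_hz * 1000.0,
        r_at_lag=best[0],
        lag_search_ms=(-max_lag_ms, max_lag_ms),
    )
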