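"""Test-retest statistics: behavioral scoring (hits/misses/false alarms,
d-prime, reaction time), ICC(3,1) with exact F-based confidence
intervals, Cronbach's alpha, peak extraction, and brain-behavior
correlation.

ICC(3,1) is the single-measure intraclass correlation from a two-way
mixed-effects model with a consistency definition (subjects random, runs
fixed): ``(BMS - EMS) / (BMS + (k - 1) EMS)`` where BMS and EMS are the
between-subject and residual mean squares of the subjects x runs ANOVA
decomposition.  For two runs, Cronbach's alpha equals the Spearman-Brown
step-up ``2r / (1 + r)`` of the between-run Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .individual import TypicalityTable
from .simulate import StimulusSequence


# ---------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------

@dataclass
class BehaviorSummary:
    hits: int
    misses: int
    false_alarms: int
    n_targets: int
    n_nontargets: int
    rts_s: list[float] = field(default_factory=list)

    @property
    def hit_rate(self) -> float:
        return self.hits / self.n_targets if self.n_targets else np.nan

    @property
    def fa_rate(self) -> float:
        return self.false_alarms / self.n_nontargets if self.n_nontargets else np.nan

    @property
    def mean_rt_ms(self) -> float:
        return float(np.mean(self.rts_s) * 1000.0) if self.rts_s else np.nan

    @property
    def dprime(self) -> float:
        return dprime(self.hit_rate, self.fa_rate, self.n_targets, self.n_nontargets)


def classify_responses(
    keypress_times_s: list[float],
    sequence: StimulusSequence,
    window_s: tuple[float, float] = (0.2, 1.5),
) -> BehaviorSummary:
    """Score key presses as hits, misses, or false alarms.

    A press is a hit if it falls within ``window_s`` after the onset of a
    not-yet-answered Target (earliest press wins); Targets without such a
    press are misses; every other press is a false alarm.  Press times are
    on the session clock (blocks laid out back to back).
    """
    presses = sorted(keypress_times_s)
    onsets = sequence.onsets_abs_s
    labels = np.asarray(sequence.labels, dtype=object)
    target_onsets = onsets[labels == "Target"]
    answered = np.zeros(len(target_onsets), dtype=bool)
    hits, fas, rts = 0, 0, []
    lo, hi = window_s
    for press in presses:
        eligible = np.flatnonzero(
            ~answered
            & (press > target_onsets + lo)
            & (press < target_onsets + hi)
        )
        if eligible.size:
            k = eligible[0]
            answered[k] = True
            hits += 1
            rts.append(press - target_onsets[k])
        else:
            fas += 1
    n_targets = len(target_onsets)
    return BehaviorSummary(
        hits=hits,
        misses=n_targets - hits,
        false_alarms=fas,
        n_targets=n_targets,
        n_nontargets=int((labels != "Target").sum()),
        rts_s=rts,
    )


def dprime(hit_rate: float, fa_rate: float, n_targets: int, n_nontargets: int) -> float:
    """Signal-detection sensitivity with 1/(2N) rate clipping.

    Rates are clipped to ``[1/(2N), 1 - 1/(2N)]`` (per respective stimulus
    count) before the inverse-normal transform, so perfect rates stay
    finite.
    """
    if n_targets <= 0 or n_nontargets <= 0:
        raise ValueError("stimulus counts must be positive")
    h = float(np.clip(hit_rate, 1 / (2 * n_targets), 1 - 1 / (2 * n_targets)))
    f = float(np.clip(fa_rate, 1 / (2 * n_nontargets), 1 - 1 / (2 * n_nontargets)))
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


# ---------------------------------------------------------------------
# Run matrices and reliability coefficients
# ---------------------------------------------------------------------

@dataclass
class RunMatrix:
    """Subjects x runs measurements of one measure/component/condition."""

    values: np.ndarray
    measure: str = ""
    component: str = ""
    condition: str = ""
    subjects: list[str] | None = None
    dropped_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError("values must be subjects x runs with >= 2 runs")
        if np.isnan(self.values).any():
            raise ValueError("missing cells; drop incomplete subjects first")


def build_run_matrix(
    per_run: dict[object, dict[str, float]],
    measure: str = "",
    component: str = "",
    condition: str = "",
) -> RunMatrix:
    """Assemble a RunMatrix from per-run {subject: value} mappings.

    Subjects missing from any run are dropped (listwise deletion) and
    recorded in ``dropped_subjects``.
    """
    runs = list(per_run)
    all_subjects = sorted({s for r in runs for s in per_run[r]}, key=str)
    complete = [s for s in all_subjects if all(s in per_run[r] for r in runs)]
    dropped = [str(s) for s in all_subjects if s not in complete]
    values = np.array([[per_run[r][s] for r in runs] for s in complete], dtype=float)
    return RunMatrix(values=values, measure=measure, component=component,
                     condition=condition, subjects=[str(s) for s in complete],
                     dropped_subjects=dropped)


@dataclass
class IccResult:
    icc: float
    ci95: tuple[float, float]
    p: float
    degenerate: bool = False


def icc_3_1(matrix: RunMatrix | np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(3,1): two-way mixed model, consistency definition.

    The confidence interval is the exact F-based interval and the p-value
    comes from ``F = BMS / EMS`` with ``(n-1, (n-1)(k-1))`` degrees of
    freedom.  A zero residual mean square (identical runs up to a constant
    shift) yields ICC = 1 with a degenerate-CI flag.
    """
    x = matrix.values if isinstance(matrix, RunMatrix) else np.asarray(matrix, float)
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 runs")
    grand = x.mean()
    ss_rows = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if ems <= 1e-12 * max(bms, 1.0):
        return IccResult(icc=1.0, ci95=(np.nan, np.nan), p=0.0, degenerate=True)
    icc = (bms - ems) / (bms + (k - 1) * ems)
    f_obs = bms / ems
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(stats.f.sf(f_obs, df1, df2))
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return IccResult(icc=float(icc), ci95=(float(lo), float(hi)), p=p)


def cronbach_alpha(matrix: RunMatrix | np.ndarray) -> float:
    """Cronbach's alpha across runs (runs = items, subjects = cases).

    For two runs with equal variances (e.g. standardized columns) alpha
    equals the Spearman-Brown step-up ``2r / (1 + r)`` of their Pearson
    correlation exactly; with unequal run variances raw alpha is smaller.
    """
    x = matrix.values if isinstance(matrix, RunMatrix) else np.asarray(matrix, float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need >= 2 runs")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total variance is zero; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


# ---------------------------------------------------------------------
# Peak extraction
# ---------------------------------------------------------------------

@dataclass
class PeakMeasure:
    amplitude_uv: float
    latency_ms: float
    at_edge: bool


def peak_measures(
    erp,
    electrode: str,
    window_ms: tuple[float, float],
    polarity: str,
) -> PeakMeasure:
    """Extremum of the stated polarity within a latency window.

    ``polarity`` is 'negative' (minimum) or 'positive' (maximum).  An
    extremum on the window boundary is flagged (``at_edge``): it usually
    indicates a monotone segment rather than a true peak.
    """
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    times_ms = erp.times * 1000.0
    sel = np.flatnonzero((times_ms >= window_ms[0]) & (times_ms <= window_ms[1]))
    if sel.size == 0:
        raise ValueError(f"window {window_ms} ms outside the epoch")
    wave = erp.waveform(electrode)[sel]
    if np.ptp(wave) == 0:
        raise ValueError("flat waveform in window; peak undefined")
    k = int(np.argmin(wave) if polarity == "negative" else np.argmax(wave))
    return PeakMeasure(
        amplitude_uv=float(wave[k]),
        latency_ms=float(times_ms[sel[k]]),
        at_edge=k in (0, sel.size - 1),
    )


# ---------------------------------------------------------------------
# Brain-behavior correlation
# ---------------------------------------------------------------------

def brain_behavior_corr(
    typicality: dict[str, TypicalityTable] | TypicalityTable,
    behavior: dict[str, BehaviorSummary],
) -> pd.DataFrame:
    """Pearson correlation of typicality with d-prime and mean RT.

    One row per (condition, measure).  Subjects without behavioral data
    are excluded listwise; ``n`` reports how many entered each correlation.
    """
    tables = typicality if isinstance(typicality, dict) else \
        {typicality.condition: typicality}
    rows = []
    for cond, tab in tables.items():
        matched = [s for s in tab.scores.index if s in behavior]
        if len(matched) < 4:
            raise ValueError(f"need >= 4 matched subjects (condition {cond!r})")
        scores = tab.scores.loc[matched].to_numpy()
        for measure, getter in (("dprime", lambda b: b.dprime),
                                ("mean_rt_ms", lambda b: b.mean_rt_ms)):
            vals = np.array([getter(behavior[s]) for s in matched])
            ok = ~np.isnan(vals)
            if ok.sum() < 4:
                raise ValueError(f"too few valid {measure} values ({cond})")
            if np.ptp(scores[ok]) == 0 or np.ptp(vals[ok]) == 0:
                raise ValueError(f"degenerate variance for {measure} ({cond})")
            r, p = stats.pearsonr(scores[ok], vals[ok])
            rows.append({"condition": cond, "measure": measure,
                         "r": float(r), "p": float(p), "n": int(ok.sum())})
    return pd.DataFrame(rows)
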