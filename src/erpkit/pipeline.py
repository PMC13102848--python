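"""End-to-end orchestration: configuration, seeded simulate -> preprocess
-> group -> individual (-> reliability) runs, and CSV/JSON emission.

Defaults reproduce the study design: 8 blocks x 80 stimuli at 70/15/15%
Standard/Target/Novel with a 1 s offset-to-onset ISI, four system
profiles, STD rejection thresholds of 25/25/35/40 µV, and a shifted
baseline for the high-lag headset.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster, individual, preprocess, reliability, simulate
from .containers import CONDITIONS, Erp

logger = logging.getLogger("erpkit")

_DEFAULT_N_SUBJECTS = {"biosemi64": 10, "smarting24": 9, "dsi24": 11, "epoc14": 7}
_DEFAULT_STD_THRESHOLDS = {"biosemi64": 25.0, "smarting24": 25.0,
                           "dsi24": 35.0, "epoc14": 40.0}
#: systems whose acquisition lag exceeds this use the shifted baseline
HIGH_LAG_MS = 100.0
HIGH_LAG_BASELINE_S = (0.05, 0.15)


@dataclass
class RunConfig:
    """Validated parameters of one end-to-end run."""

    mode: str = "exp1"
    systems: list[str] = field(
        default_factory=lambda: ["biosemi64", "smarting24", "dsi24", "epoc14"])
    n_subjects: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_N_SUBJECTS))
    n_subjects_exp2: int = 38
    n_runs: int = 2
    n_blocks: int = 8
    n_per_block: int = 80
    proportions: tuple[float, float, float] = simulate.DEFAULT_PROPORTIONS
    isi_s: float = 1.0
    durations: dict[str, float] = field(
        default_factory=lambda: dict(simulate.DEFAULT_DURATIONS_S))
    epoch_window_exp1_s: tuple[float, float] = (-0.1, 0.7)
    epoch_window_exp2_s: tuple[float, float] = (-0.1, 0.4)
    baseline_window_s: tuple[float, float] = (-0.1, 0.0)
    std_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STD_THRESHOLDS))
    artifact_fraction: float = 0.05
    alpha_forming: float = 0.05
    cluster_alpha: float = 0.05
    alpha_tail: float = 0.025
    n_permutations: int = 1000
    bin_ms: float = 20.0
    xcorr_fs_hz: float = 250.0
    xcorr_max_lag_ms: float = 300.0
    seed: int = 0
    out_dir: str = "erpkit_out"

    _RANGES = {
        "alpha_forming": (0.0, 1.0),
        "cluster_alpha": (0.0, 1.0),
        "alpha_tail": (0.0, 0.5),
        "artifact_fraction": (0.0, 0.5),
    }

    def validate(self) -> "RunConfig":
        if self.mode not in ("exp1", "exp2"):
            raise ValueError("mode must be 'exp1' or 'exp2'")
        presets = simulate.system_presets()
        unknown = [s for s in self.systems if s not in presets]
        if unknown:
            raise ValueError(f"unknown system preset(s): {unknown}")
        for key, (lo, hi) in self._RANGES.items():
            v = getattr(self, key)
            if not lo < v < hi:
                raise ValueError(f"{key}={v} outside valid range ({lo}, {hi})")
        for key in ("n_blocks", "n_per_block", "n_permutations", "n_runs"):
            if getattr(self, key) < 1:
                raise ValueError(f"{key} must be >= 1")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        return self

    @property
    def epoch_window_s(self) -> tuple[float, float]:
        return (self.epoch_window_exp1_s if self.mode == "exp1"
                else self.epoch_window_exp2_s)

    def baseline_for(self, profile: simulate.SystemProfile) -> tuple[float, float]:
        if profile.lag_ms > HIGH_LAG_MS:
            return HIGH_LAG_BASELINE_S
        return self.baseline_window_s

    # -- file form ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["proportions"] = list(self.proportions)
        for key in ("epoch_window_exp1_s", "epoch_window_exp2_s", "baseline_window_s"):
            d[key] = list(d[key])
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("proportions", "epoch_window_exp1_s", "epoch_window_exp2_s",
                    "baseline_window_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()


def validate_config(path: str | Path) -> RunConfig:
    """Parse and range-check a YAML config file; empty file -> defaults."""
    text = Path(path).read_text()
    d = yaml.safe_load(text) or {}
    if not isinstance(d, dict):
        raise ValueError("config file must hold a mapping")
    return RunConfig.from_dict(d)


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    out_dir: Path
    log: list[str]
    manifest: dict


# ---------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------

def _subject_seed(base_seed: int, system: str, subject: int) -> int:
    h = hashlib.sha256(f"{base_seed}:{system}:{subject}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def preprocess_subject(
    epochs,
    profile: simulate.SystemProfile,
    config: RunConfig,
    log: list[str],
) -> tuple[dict[str, Erp], object]:
    """Re-reference, band-pass, reject, and average one subject's epochs."""
    subject = epochs.meta.get("subject_seed", "?")
    try:
        refs = preprocess.resolve_reference(epochs.channel_names,
                                            profile.reference_scheme)
        epochs = preprocess.rereference(epochs, ref_channels=list(refs))
        log.append(f"{profile.name}/s{subject}: referenced to {refs}")
    except KeyError as exc:
        log.append(f"{profile.name}/s{subject}: reference skipped ({exc})")
    epochs = preprocess.bandpass(epochs)
    threshold = config.std_thresholds.get(profile.name, 25.0)
    epochs, table = preprocess.reject_by_std(epochs, threshold)
    for _, row in table.iterrows():
        log.append(
            f"{profile.name}/s{subject}: rejected {row.n_rejected}/{row.n_trials} "
            f"{row.condition} trials (threshold {threshold} µV)"
        )
    baseline = config.baseline_for(profile)
    erps = {}
    for cond in CONDITIONS:
        erps[cond] = preprocess.average_erp(epochs, cond,
                                            baseline_window_s=baseline)
        erps[cond].subject = f"{profile.name}_s{subject}"
    return erps, epochs


def group_component_windows(
    erps_by_subject: list[dict[str, Erp]],
    electrode: str,
    config: RunConfig,
    seed: int,
) -> pd.DataFrame:
    """Across-subject temporal cluster test per condition at one electrode."""
    rows = []
    for cond in CONDITIONS:
        waveforms = np.stack([e[cond].waveform(electrode) for e in erps_by_subject])
        times = erps_by_subject[0][cond].times
        res = cluster.temporal_cluster_test(
            waveforms, alpha_forming=config.alpha_forming, tail="two_sided",
            n_permutations=config.n_permutations, seed=seed, times_s=times)
        table = cluster.find_component_windows(
            res, times, waveform=waveforms.mean(axis=0), alpha=config.cluster_alpha)
        table.insert(0, "condition", cond)
        rows.append(table)
    return pd.concat(rows, ignore_index=True)


def _window_lookup(group_windows: pd.DataFrame) -> dict:
    out = {}
    for _, row in group_windows.iterrows():
        if row.significant:
            out[(row.condition, row.component)] = (row.window_start_ms,
                                                   row.window_end_ms)
    return out


# ---------------------------------------------------------------------
# Experiment-1 pipeline
# ---------------------------------------------------------------------

def run_exp1(config: RunConfig) -> ReportBundle:
    presets = simulate.system_presets()
    log: list[str] = []
    sequence = simulate.make_sequence(
        config.n_blocks, config.n_per_block, config.proportions,
        config.isi_s, config.durations, seed=config.seed)
    group_tables, xcorr_rows = [], []
    temporal_results: dict[str, dict[str, dict[str, object]]] = {}
    temporal_unconstrained: dict[str, dict[str, dict[str, object]]] = {}
    spatial_results: dict[str, dict[str, dict[str, object]]] = {}
    typicality_tables: dict[str, dict[str, individual.TypicalityTable]] = {}
    group_windows_by_system: dict[str, pd.DataFrame] = {}
    grand_by_system: dict[str, dict[str, Erp]] = {}

    for system in config.systems:
        profile = presets[system]
        layout = simulate.subject_layout(profile)
        electrode = individual.resolve_electrode(profile.channel_names)
        erps_by_subject, epochs_by_subject = [], []
        for i in range(config.n_subjects.get(system, 8)):
            s_seed = _subject_seed(config.seed, system, i)
            params = simulate.draw_subject_params(s_seed)
            epochs = simulate.simulate_subject_epochs(
                profile, params, sequence, config.epoch_window_s,
                run_id=0, artifact_fraction=config.artifact_fraction)
            erps, clean = preprocess_subject(epochs, profile, config, log)
            erps_by_subject.append(erps)
            epochs_by_subject.append(clean)

        grand_by_system[system] = {
            c: cluster.grand_average([e[c] for e in erps_by_subject])
            for c in CONDITIONS}
        windows = group_component_windows(erps_by_subject, electrode, config,
                                          seed=config.seed + 1)
        windows.insert(0, "system", system)
        group_tables.append(windows)
        group_windows_by_system[system] = windows
        lookup = _window_lookup(windows)

        temporal_results[system] = {c: {} for c in CONDITIONS}
        temporal_unconstrained[system] = {c: {} for c in CONDITIONS}
        spatial_results[system] = {c: {} for c in CONDITIONS}
        for i, epochs in enumerate(epochs_by_subject):
            subj = f"s{i}"
            detections = individual.individual_temporal_detect(
                epochs, electrode, alpha_tail=config.alpha_tail,
                n_permutations=config.n_permutations,
                seed=_subject_seed(config.seed + 2, system, i))
            for cond, res in detections.items():
                temporal_results[system][cond][subj] = res
                temporal_unconstrained[system][cond][subj] = res
            for cond in CONDITIONS:
                for component in ("N100", "P300"):
                    if component == "P300" and cond != "Novel":
                        continue
                    window = lookup.get((cond, component))
                    if window is None:
                        continue
                    tail = individual.COMPONENT_TAILS[component]
                    res = individual.individual_spatial_detect(
                        epochs, window, layout, tail,
                        alpha_tail=config.alpha_tail,
                        n_permutations=config.n_permutations,
                        seed=_subject_seed(config.seed + 3, system, i),
                        condition=cond)
                    spatial_results[system][cond][f"{component}:{subj}"] = res

        typicality_tables[system] = {
            c: individual.typicality_scores(
                [e[c] for e in erps_by_subject], electrode, c)
            for c in CONDITIONS}

    # cross-system lag/correlation against the first (reference) system
    reference = config.systems[0]
    for system in config.systems[1:]:
        for cond in CONDITIONS:
            ref_erp = grand_by_system[reference][cond]
            sys_erp = grand_by_system[system][cond]
            a = cluster.resample_waveform(
                ref_erp.waveform(individual.resolve_electrode(ref_erp.channel_names)),
                ref_erp.fs_hz, config.xcorr_fs_hz)
            b = cluster.resample_waveform(
                sys_erp.waveform(individual.resolve_electrode(sys_erp.channel_names)),
                sys_erp.fs_hz, config.xcorr_fs_hz)
            lc = cluster.xcorr_lag(a, b, config.xcorr_fs_hz,
                                   config.xcorr_max_lag_ms)
            xcorr_rows.append({"reference": reference, "system": system,
                               "condition": cond, "r": lc.r_at_lag,
                               "lag_ms": lc.lag_ms})

    # detection tables (temporal: with and without the group-window rule)
    def spatial_by_component(system, cond, component):
        return {k.split(":", 1)[1]: v
                for k, v in spatial_results[system][cond].items()
                if k.startswith(f"{component}:")}

    temp_rows, spat_rows = [], []
    for system in config.systems:
        lookup = _window_lookup(group_windows_by_system[system])
        row_c = {"dataset": system, "method": "temporal", "constrained": True}
        row_u = {"dataset": system, "method": "temporal", "constrained": False}
        row_s = {"dataset": system, "method": "spatial"}
        for cond in CONDITIONS:
            for component in ("N100", "P300"):
                if component == "P300" and cond != "Novel":
                    continue
                col = f"{component}_{cond}"
                window = lookup.get((cond, component))
                per_subj = temporal_results[system][cond]
                row_c[col] = (individual.detection_rate(
                    per_subj, component, alpha=config.cluster_alpha,
                    group_window_ms=window) if window else np.nan)
                row_u[col] = individual.detection_rate(
                    per_subj, component, alpha=config.cluster_alpha)
                spat = spatial_by_component(system, cond, component)
                row_s[col] = (individual.detection_rate(
                    spat, component, alpha=config.cluster_alpha)
                    if spat else np.nan)
        temp_rows += [row_c, row_u]
        spat_rows.append(row_s)

    tables = {
        "group_windows": pd.concat(group_tables, ignore_index=True),
        "xcorr": pd.DataFrame(xcorr_rows),
        "temporal_detection": pd.DataFrame(temp_rows),
        "spatial_detection": pd.DataFrame(spat_rows),
        "typicality_long": individual.assemble_typicality_long_table(
            typicality_tables),
    }
    return _emit(config, tables, log)


# ---------------------------------------------------------------------
# Experiment-2 pipeline
# ---------------------------------------------------------------------

def run_exp2(config: RunConfig) -> ReportBundle:
    presets = simulate.system_presets()
    profile = presets[config.systems[0]]
    electrode = individual.resolve_electrode(profile.channel_names)
    log: list[str] = []
    n_subj = config.n_subjects_exp2

    erps_by_run: list[list[dict[str, Erp]]] = []
    sequences = [simulate.make_sequence(
        config.n_blocks, config.n_per_block, config.proportions,
        config.isi_s, config.durations, seed=config.seed + 10 + r)
        for r in range(config.n_runs)]
    subject_params = [
        simulate.draw_subject_params(_subject_seed(config.seed, "exp2", i))
        for i in range(n_subj)]
    for r in range(config.n_runs):
        run_erps = []
        for i, params in enumerate(subject_params):
            epochs = simulate.simulate_subject_epochs(
                profile, params, sequences[r], config.epoch_window_s,
                run_id=r, artifact_fraction=config.artifact_fraction)
            erps, _ = preprocess_subject(epochs, profile, config, log)
            for e in erps.values():
                e.subject = f"s{i}"
            run_erps.append(erps)
        erps_by_run.append(run_erps)

    # group windows per run (Table-7 format) and peak windows from run 1
    run_windows = []
    for r in range(config.n_runs):
        w = group_component_windows(erps_by_run[r], electrode, config,
                                    seed=config.seed + 20 + r)
        w.insert(0, "run", r + 1)
        run_windows.append(w)
    windows_table = pd.concat(run_windows, ignore_index=True)
    lookup = _window_lookup(run_windows[0].assign(system="exp2"))

    # peak measures -> ICC per (measure, component, condition)
    icc_rows = []
    peak_plan = [("N100", c, "negative") for c in CONDITIONS] + \
                [("P300", "Novel", "positive")]
    for component, cond, polarity in peak_plan:
        window = lookup.get((cond, component))
        if window is None:
            log.append(f"exp2: no group window for {component}/{cond}; ICC skipped")
            continue
        for measure in ("amplitude_uv", "latency_ms"):
            per_run = {}
            for r in range(config.n_runs):
                per_run[r] = {}
                for i in range(n_subj):
                    pk = reliability.peak_measures(
                        erps_by_run[r][i][cond], electrode, window, polarity)
                    per_run[r][f"s{i}"] = getattr(pk, measure)
            matrix = reliability.build_run_matrix(
                per_run, measure=measure, component=component, condition=cond)
            res = reliability.icc_3_1(matrix)
            icc_rows.append({
                "measure": measure, "component": component, "condition": cond,
                "icc": res.icc, "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                "p": res.p, "n": matrix.values.shape[0]})

    # typicality per run -> Cronbach's alpha per condition
    typ_by_run = [
        {c: individual.typicality_scores([e[c] for e in erps_by_run[r]],
                                         electrode, c)
         for c in CONDITIONS}
        for r in range(config.n_runs)]
    alpha_rows = []
    for cond in CONDITIONS:
        per_run = {r: typ_by_run[r][cond].scores.to_dict()
                   for r in range(config.n_runs)}
        matrix = reliability.build_run_matrix(per_run, measure="typicality",
                                              condition=cond)
        alpha_rows.append({"condition": cond,
                           "cronbach_alpha": reliability.cronbach_alpha(matrix),
                           "n": matrix.values.shape[0]})

    # behavior on the first run -> brain-behavior correlations
    behavior = {}
    for i in range(n_subj):
        rng = np.random.default_rng(_subject_seed(config.seed + 30, "beh", i))
        presses = simulate.simulate_presses(
            sequences[0], p_hit=float(np.clip(rng.beta(9, 1), 0.5, 1.0)),
            rt_mean_s=float(rng.normal(0.45, 0.08)),
            seed=_subject_seed(config.seed + 31, "beh", i))
        behavior[f"s{i}"] = reliability.classify_responses(presses, sequences[0])
    behavior_table = pd.DataFrame([
        {"subject": s, "hits": b.hits, "misses": b.misses,
         "false_alarms": b.false_alarms, "hit_rate": b.hit_rate,
         "mean_rt_ms": b.mean_rt_ms, "dprime": b.dprime}
        for s, b in behavior.items()])
    bb = reliability.brain_behavior_corr(typ_by_run[0], behavior)

    typ_long = []
    for r in range(config.n_runs):
        for cond in CONDITIONS:
            for subject, score in typ_by_run[r][cond].scores.items():
                typ_long.append({"subject": subject, "run": r + 1,
                                 "condition": cond, "score": float(score)})

    tables = {
        "group_windows_by_run": windows_table,
        "icc": pd.DataFrame(icc_rows),
        "cronbach_alpha": pd.DataFrame(alpha_rows),
        "behavior": behavior_table,
        "brain_behavior": bb,
        "typicality_long": pd.DataFrame(typ_long),
    }
    return _emit(config, tables, log)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full seeded pipeline for the configured experiment mode."""
    config.validate()
    return run_exp1(config) if config.mode == "exp1" else run_exp2(config)


def _emit(config: RunConfig, tables: dict[str, pd.DataFrame],
          log: list[str]) -> ReportBundle:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.csv", index=False)
    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "tables": sorted(tables),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    for line in log:
        logger.info(line)
    return ReportBundle(tables=tables, out_dir=out_dir, log=log,
                        manifest=manifest)
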