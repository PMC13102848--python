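"""Binned significance maps, per-subject detection, typicality scores."""

import numpy as np
import pandas as pd
import pytest

from erpkit import (
    Erp,
    assemble_typicality_long_table,
    binned_significance_map,
    build_layout,
    detection_rate,
    detection_table,
    individual_spatial_detect,
    individual_temporal_detect,
    typicality_scores,
)
from erpkit.cluster import Cluster, ClusterResult
from conftest import flat_params, make_epochs_array


# -- binned significance maps ------------------------------------------

def test_null_map_rejects_at_about_alpha():
    rng = np.random.default_rng(0)
    subjects = [make_epochs_array(rng.standard_normal((40, 2, 100)))
                for _ in range(30)]
    m = binned_significance_map(subjects, bin_ms=20.0, alpha=0.05)
    for values in (m.values_negative, m.values_positive):
        se = np.sqrt(0.05 * 0.95 / 30)  # per (channel, bin) cell
        assert abs(values.mean() - 0.05) < 3 * se / np.sqrt(values.size) + 0.01


def test_shared_noise_free_component_flags_every_subject():
    t = np.arange(-25, 175) / 250.0
    wave = -5.0 * np.exp(-((t - 0.1) ** 2) / (2 * 0.015**2))
    data = np.tile(wave, (20, 1, 1))  # trials x 1 channel x samples
    # tiny trial jitter so the per-subject t-test is defined
    rng = np.random.default_rng(1)
    subjects = [make_epochs_array(data + 0.01 * rng.standard_normal(data.shape))
                for _ in range(5)]
    m = binned_significance_map(subjects, bin_ms=20.0, alpha=0.05)
    bins = (m.bin_edges_ms[:-1] >= 80) & (m.bin_edges_ms[1:] <= 120)
    assert np.all(m.values_negative[0, bins] == 1.0)
    assert np.all(m.values_positive[0, bins] == 0.0)


def test_single_subject_map_is_binary():
    rng = np.random.default_rng(2)
    m = binned_significance_map(
        [make_epochs_array(rng.standard_normal((30, 3, 100)))], bin_ms=20.0)
    assert set(np.unique(m.values_negative)) <= {0.0, 1.0}


def test_bin_width_must_match_sample_grid():
    rng = np.random.default_rng(3)
    ep = make_epochs_array(rng.standard_normal((10, 1, 100)), fs_hz=128.0,
                           epoch_start_s=-0.125)
    with pytest.raises(ValueError, match="resample"):
        binned_significance_map([ep], bin_ms=20.0)  # 2.56 samples per bin


def test_bin_edges_aligned_at_zero():
    rng = np.random.default_rng(4)
    ep = make_epochs_array(rng.standard_normal((10, 1, 100)))
    m = binned_significance_map([ep], bin_ms=20.0)
    assert 0.0 in m.bin_edges_ms


# -- temporal detection ------------------------------------------------

def test_strong_component_detected_reliably(mini_profile, short_sequence):
    """N100 at 5x the noise scale is detected in (nearly) every seed."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        params = flat_params(n100_uv=-50.0, p300_uv=0.0, seed=seed)
        from erpkit import simulate_subject_epochs

        ep = simulate_subject_epochs(mini_profile, params, short_sequence)
        res = individual_temporal_detect(ep, "Fz", n_permutations=300,
                                         seed=seed, conditions=("Standard",))
        sig = res["Standard"].significant()
        ok = any(c.mass < 0 and
                 np.any(np.abs(res["Standard"].times_s[c.member_indices] - 0.1)
                        < 0.05)
                 for c in sig)
        hits += ok
    assert hits >= int(0.95 * n_seeds)


def test_zero_amplitude_rarely_detected(mini_profile, short_sequence):
    from erpkit import simulate_subject_epochs

    false_pos = 0
    n_seeds = 20
    for seed in range(n_seeds):
        params = flat_params(n100_uv=0.0, p300_uv=0.0, seed=100 + seed)
        ep = simulate_subject_epochs(mini_profile, params, short_sequence)
        res = individual_temporal_detect(ep, "Fz", n_permutations=300,
                                         seed=seed, conditions=("Standard",))
        false_pos += bool(res["Standard"].significant())
    assert false_pos <= 0.1 * n_seeds + 2


def test_noise_free_cluster_matches_template_support(noiseless_epochs):
    res = individual_temporal_detect(noiseless_epochs, "Fz",
                                     n_permutations=200, seed=0,
                                     conditions=("Standard",))["Standard"]
    sig = res.significant()
    assert sig
    neg = [c for c in sig if c.mass < 0]
    times = res.times_s[neg[0].member_indices] * 1000
    # window brackets the injected 100 ms component
    assert times[0] < 100.0 < times[-1]


def test_electrode_fallback_recorded():
    rng = np.random.default_rng(5)
    ep = make_epochs_array(rng.standard_normal((10, 2, 100)),
                           channel_names=["F4", "T8"])
    res = individual_temporal_detect(ep, "Fz", n_permutations=50, seed=0,
                                     conditions=("Standard",))["Standard"]
    assert res.meta["electrode"] == "F4"


# -- spatial detection -------------------------------------------------

#: injected activation covers samples 40:60 -> 60-136 ms on this grid
_PATCH_WINDOW_MS = (60.0, 136.0)


def _spatial_epochs(active, channels, amp=-10.0, n_trials=20):
    rng = np.random.default_rng(6)
    data = 0.5 * rng.standard_normal((n_trials, len(channels), 100))
    for ch in active:
        data[:, channels.index(ch), 40:60] += amp
    return make_epochs_array(data, channel_names=channels)


def test_focal_source_yields_single_cluster_of_neighbours():
    channels = ["Fz", "FCz", "Cz", "F3", "F4", "Pz", "Oz"]
    layout = build_layout(channels)
    active = ["Fz", "FCz", "F3"]
    ep = _spatial_epochs(active, channels)
    # strict forming threshold: the injected channels have |t| >> 10 while
    # noise channels cross it only with probability ~alpha_tail
    res = individual_spatial_detect(ep, _PATCH_WINDOW_MS, layout, "negative",
                                    alpha_tail=0.001, n_permutations=300,
                                    seed=0)
    sig = res.significant()
    assert len(sig) == 1
    members = {channels[i] for i in sig[0].member_indices}
    assert members == set(active)


def test_two_disjoint_patches_give_two_clusters():
    channels = ["Fz", "FCz", "F3", "F4", "Pz", "POz", "Oz"]
    layout = build_layout(channels)
    ep = _spatial_epochs(["Fz", "FCz"], channels)
    # add a second, spatially separate patch
    for ch in ("Pz", "POz", "Oz"):
        ep.data[:, channels.index(ch), 40:60] += -10.0
    res = individual_spatial_detect(ep, _PATCH_WINDOW_MS, layout, "negative",
                                    n_permutations=300, seed=0)
    sig = res.significant()
    assert len(sig) == 2


def test_all_zero_spatial_data_gives_nothing():
    channels = ["Fz", "Cz", "Pz"]
    layout = build_layout(channels)
    ep = make_epochs_array(np.zeros((10, 3, 100)), channel_names=channels)
    res = individual_spatial_detect(ep, (100.0, 200.0), layout, "negative",
                                    n_permutations=100, seed=0)
    assert res.clusters == []


def test_spatial_clusters_equal_graph_components():
    """Reported clusters are exactly the connected components of the
    suprathreshold channel set (independent scipy.sparse.csgraph oracle)."""
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy import stats as sps

    channels = ["Fp1", "Fp2", "Fz", "F3", "F4", "Cz", "C3", "C4", "Pz",
                "P3", "P4", "Oz"]
    layout = build_layout(channels)
    rng = np.random.default_rng(7)
    data = rng.standard_normal((15, len(channels), 50))
    data[:, :, 20:30] += rng.normal(0, 1.2, size=(len(channels)))[None, :, None]
    ep = make_epochs_array(data, channel_names=channels)
    res = individual_spatial_detect(ep, (0.0, 150.0), layout, "positive",
                                    alpha_tail=0.05, n_permutations=100, seed=0)
    # oracle: per-channel t on window means, threshold, graph components
    wm = data[:, :, 25:].mean(axis=-1)  # matches window (0,150) ms at 250 Hz
    sel = (ep.times >= 0) & (ep.times <= 0.150)
    wm = data[:, :, sel].mean(axis=-1)
    t, p = sps.ttest_1samp(wm, 0.0, axis=0)
    mask = (p / 2 < 0.05) & (t > 0)
    adj = lil_matrix((len(channels), len(channels)))
    for i, nbrs in layout.neighbor_graph.items():
        for j in nbrs:
            adj[i, j] = 1
    n_comp, labels = connected_components(adj.tocsr(), directed=False)
    expected = {}
    for i in np.flatnonzero(mask):
        expected.setdefault(labels[i], set()).add(i)
    got = [set(c.member_indices.tolist()) for c in res.clusters]
    # every suprathreshold channel appears in exactly one reported cluster,
    # grouped by its graph component restricted to the suprathreshold set
    reported = set().union(*got) if got else set()
    assert reported == set(np.flatnonzero(mask).tolist())
    for comp in got:
        # all members of one reported cluster share a graph component
        assert len({labels[i] for i in comp}) == 1


# -- typicality --------------------------------------------------------

def _erp(wave, subject, condition="Standard", epoch_start_s=-0.1):
    mean = np.tile(wave, (1, 1))
    return Erp(mean=mean, sem=np.zeros_like(mean), n_trials_used=10,
               condition=condition, baseline_window_s=(-0.1, 0.0), fs_hz=250.0,
               epoch_start_s=epoch_start_s, channel_names=["Fz"],
               subject=subject)


def test_identical_cohort_scores_one():
    rng = np.random.default_rng(8)
    w = rng.standard_normal(100)
    tab = typicality_scores([_erp(w, f"s{i}") for i in range(5)], "Fz")
    assert np.allclose(tab.scores.to_numpy(), 1.0)
    assert np.allclose(tab.pairwise_r.to_numpy(), 1.0)


def test_worked_three_subject_example():
    """Pairwise r (AB, AC, BC) = (0.5, 0.3, 0.1) -> scores (0.40, 0.30, 0.20)."""
    n = 400
    rng = np.random.default_rng(9)
    raw = rng.standard_normal((3, n))
    raw -= raw.mean(axis=1, keepdims=True)
    u, _ = np.linalg.qr(raw.T)  # zero-mean orthonormal columns
    target = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.1], [0.3, 0.1, 1.0]])
    waves = np.linalg.cholesky(target) @ u.T
    # time axis starts at 0 so the full constructed waveform enters the score
    tab = typicality_scores([_erp(waves[i], s, epoch_start_s=0.0)
                             for i, s in enumerate("ABC")], "Fz")
    assert tab.scores["A"] == pytest.approx(0.40, abs=1e-9)
    assert tab.scores["B"] == pytest.approx(0.30, abs=1e-9)
    assert tab.scores["C"] == pytest.approx(0.20, abs=1e-9)


def test_independent_noise_cohort_scores_near_zero():
    means = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        erps = [_erp(rng.standard_normal(100), f"s{i}") for i in range(10)]
        means.append(typicality_scores(erps, "Fz").scores.mean())
    assert abs(np.mean(means)) < 0.05


def test_matrix_symmetry_and_unit_diagonal():
    rng = np.random.default_rng(10)
    tab = typicality_scores([_erp(rng.standard_normal(80), f"s{i}")
                             for i in range(6)], "Fz")
    m = tab.pairwise_r.to_numpy()
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 1.0)
    assert np.allclose(tab.scores.to_numpy(),
                       (m.sum(axis=1) - 1) / (m.shape[0] - 1))


def test_label_equivariance_under_subject_permutation():
    rng = np.random.default_rng(11)
    waves = [rng.standard_normal(80) for _ in range(5)]
    a = typicality_scores([_erp(w, f"s{i}") for i, w in enumerate(waves)], "Fz")
    order = [3, 1, 4, 0, 2]
    b = typicality_scores([_erp(waves[j], f"s{j}") for j in order], "Fz")
    for j in order:
        assert b.scores[f"s{j}"] == pytest.approx(a.scores[f"s{j}"])


def test_constant_waveform_error_names_subject():
    rng = np.random.default_rng(12)
    erps = [_erp(rng.standard_normal(80), "s0"), _erp(np.zeros(80), "bad"),
            _erp(rng.standard_normal(80), "s2")]
    with pytest.raises(ValueError, match="bad"):
        typicality_scores(erps, "Fz")


def test_baseline_excluded_from_typicality_window():
    rng = np.random.default_rng(13)
    w1, w2, w3 = (rng.standard_normal(100) for _ in range(3))
    erps = [_erp(w, s) for w, s in ((w1, "a"), (w2, "b"), (w3, "c"))]
    # corrupt only the pre-stimulus segment; scores must be unaffected
    corrupted = [e.mean.copy() for e in erps]
    before = typicality_scores(erps, "Fz").scores
    for e in erps:
        e.mean[:, :25] = 99.0
    after = typicality_scores(erps, "Fz").scores
    assert np.allclose(before.to_numpy(), after.to_numpy())


# -- detection tables --------------------------------------------------

def _result(p, sign, idx=(10, 11, 12), times=None):
    t = np.zeros(50)
    c = Cluster(member_indices=np.array(idx), mass=sign * 30.0, p_corrected=p)
    return ClusterResult(clusters=[c], tail="two_sided", alpha_forming=0.05,
                         n_permutations=100, exhaustive=False,
                         null_max_mass=np.zeros(100), t_obs=t, n_obs=10,
                         times_s=times if times is not None
                         else np.arange(50) / 250.0)


def test_seven_of_ten_is_seventy_percent():
    results = {f"s{i}": _result(0.01 if i < 7 else 0.5, -1) for i in range(10)}
    assert detection_rate(results, "N100") == 70.0


def test_zero_detections():
    results = {f"s{i}": _result(0.5, -1) for i in range(4)}
    assert detection_rate(results, "N100") == 0.0


def test_sign_rule_and_window_overlap():
    results = {
        "hit": _result(0.01, -1, idx=(20, 21)),       # -> 80-84 ms
        "wrong_sign": _result(0.01, +1, idx=(20, 21)),
        "outside": _result(0.01, -1, idx=(45, 46)),   # -> 180-184 ms
        "ns": _result(0.3, -1, idx=(20, 21)),
    }
    assert detection_rate(results, "N100") == 50.0  # hit + outside
    assert detection_rate(results, "N100", group_window_ms=(60, 120)) == 25.0
    assert detection_rate(results, "P300") == 25.0  # only wrong_sign is +


def test_hand_counted_five_subject_fixture():
    ps = [0.01, 0.04, 0.06, 0.20, 0.049]
    results = {f"s{i}": _result(p, -1) for i, p in enumerate(ps)}
    assert detection_rate(results, "N100", alpha=0.05) == 60.0


def test_detection_table_layout():
    per_dataset = {
        "sysA": {"Standard": {f"s{i}": _result(0.01, -1) for i in range(4)}},
        "sysB": {"Standard": {f"s{i}": _result(0.50, -1) for i in range(4)}},
    }
    table = detection_table(per_dataset, method="temporal")
    assert list(table["dataset"]) == ["sysA", "sysB"]
    assert table.loc[0, "N100_Standard"] == 100.0
    assert table.loc[1, "N100_Standard"] == 0.0


# -- long-format table -------------------------------------------------

def _typ_table(subjects, condition):
    import pandas as pd

    n = len(subjects)
    r = pd.DataFrame(np.eye(n), index=subjects, columns=subjects)
    scores = pd.Series(np.linspace(0.2, 0.8, n), index=subjects)
    from erpkit import TypicalityTable

    return TypicalityTable(scores=scores, pairwise_r=r, electrode="Fz",
                           condition=condition)


def test_long_table_record_count():
    tables = {
        sys: {c: _typ_table(["s1", "s2"], c)
              for c in ("Standard", "Target", "Novel")}
        for sys in ("sysA", "sysB")}
    df = assemble_typicality_long_table(tables)
    assert len(df) == 2 * 3 * 2
    assert set(df.columns) == {"subject", "system", "condition", "score"}


def test_long_table_round_trips_through_csv(tmp_path):
    tables = {"sysA": {"Standard": _typ_table(["s1", "s2", "s3"], "Standard")}}
    df = assemble_typicality_long_table(tables)
    path = tmp_path / "long.csv"
    df.to_csv(path, index=False)
    back = pd.read_csv(path)
    assert np.allclose(back["score"], df["score"])


def test_duplicate_keys_rejected():
    t = _typ_table(["s1", "s1"], "Standard")
    with pytest.raises(ValueError, match="duplicate"):
        assemble_typicality_long_table({"sysA": {"Standard": t}})
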