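"""Network cohesion: windowed t over Fisher-Z edges, group tests, BY-FDR,
spatial specificity and rating epochs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurosync import (
    Epoch,
    NCISeries,
    NetworkDefinition,
    RatingCurve,
    SubjectTimeSeries,
    fdr_by,
    inter_nci,
    intra_nci,
    n_windows,
    rating_epochs,
    significant_runs,
    sliding_nci,
    spatial_specificity,
    window_group_test,
)
from neurosync.nci import ranksum_z

from oracles import by_stepup_o, intra_nci_o, inter_nci_o, ranksum_z_p_o


def test_intra_three_node_sign_pattern_matches_oracle():
    """Nodes a, a, -a give edge z (+Z0, -Z0, -Z0); t matches a hand oracle."""
    a = np.random.default_rng(0).normal(size=20)
    window = np.vstack([a, a, -a])
    z0 = np.arctanh(1 - 1e-7)
    zs = np.array([z0, -z0, -z0])
    t_expected = zs.mean() / (zs.std(ddof=1) / np.sqrt(3))
    assert intra_nci(window) == pytest.approx(t_expected, rel=1e-12)
    assert intra_nci(window) == pytest.approx(intra_nci_o(window), rel=1e-10)


def test_intra_matches_oracle_random():
    rng = np.random.default_rng(1)
    for _ in range(25):
        w = rng.normal(size=(rng.integers(3, 6), rng.integers(5, 15)))
        assert intra_nci(w) == pytest.approx(intra_nci_o(w), rel=1e-10)


def test_intra_node_permutation_invariance():
    rng = np.random.default_rng(2)
    w = rng.normal(size=(5, 12))
    t0 = intra_nci(w)
    assert intra_nci(w[rng.permutation(5)]) == pytest.approx(t0, rel=1e-12)


def test_intra_null_mean_near_zero():
    """Independent white-noise nodes: mean t over 200 seeds within 0.1 of 0."""
    vals = [
        intra_nci(np.random.default_rng(s).normal(size=(3, 500)))
        for s in range(200)
    ]
    assert abs(np.mean(vals)) < 0.1


def test_intra_errors_and_degenerate():
    with pytest.raises(ValueError, match="insufficient edges"):
        intra_nci(np.random.default_rng(0).normal(size=(2, 10)))
    w = np.random.default_rng(1).normal(size=(3, 10))
    w[0] = 4.2  # constant node -> flagged, not inflated
    assert np.isnan(intra_nci(w))


def test_inter_symmetry_and_oracle():
    rng = np.random.default_rng(3)
    w = rng.normal(size=(6, 15))
    a, b = np.array([0, 1, 2]), np.array([3, 4, 5])
    assert inter_nci(w, a, b) == inter_nci(w, b, a)
    assert inter_nci(w, a, b) == pytest.approx(
        inter_nci_o(w, a, b), rel=1e-10
    )


def test_inter_rejects_overlap_and_tiny():
    w = np.random.default_rng(4).normal(size=(4, 10))
    with pytest.raises(ValueError, match="disjoint"):
        inter_nci(w, [0, 1], [1, 2])
    with pytest.raises(ValueError, match="edges"):
        inter_nci(w, [0], [1])


def test_inter_monotone_in_shared_latent():
    """A latent injected into one node of each network raises mean inter-NCI."""
    means = []
    for beta in (0.0, 0.5, 1.0):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            w = rng.normal(size=(6, 60))
            u = rng.normal(size=60)
            w[0] += beta * u
            w[3] += beta * u
            vals.append(inter_nci(w, [0, 1, 2], [3, 4, 5]))
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


# --- sliding windows -----------------------------------------------------


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n_tr=st.integers(10, 300),
    w=st.integers(3, 40),
    step=st.integers(1, 7),
)
def test_window_count_identity(n_tr, w, step):
    if w > n_tr:
        with pytest.raises(ValueError):
            n_windows(n_tr, w, step)
    else:
        count = n_windows(n_tr, w, step)
        starts = np.arange(count) * step
        assert count == (n_tr - w) // step + 1
        assert starts[-1] + w <= n_tr
        assert starts[-1] + step + w > n_tr


def test_study_scale_window_count():
    assert n_windows(169, 10, 1) == 160


def test_sliding_matches_per_window_computation():
    rng = np.random.default_rng(5)
    sub = SubjectTimeSeries("s", "pmdd", rng.normal(size=(8, 40)))
    net = NetworkDefinition("n", np.array([1, 3, 5, 7]))
    series = sliding_nci(sub, net, window_length=12, step=3)
    assert series.values.size == n_windows(40, 12, 3)
    for k, s in enumerate(series.window_starts):
        direct = intra_nci(sub.data[net.indices, s : s + 12])
        assert series.values[k] == pytest.approx(direct, rel=1e-10)


def test_full_length_window_equals_whole_series():
    rng = np.random.default_rng(6)
    sub = SubjectTimeSeries("s", "pmdd", rng.normal(size=(5, 30)))
    net = NetworkDefinition("n", np.arange(4))
    series = sliding_nci(sub, net, window_length=30)
    assert series.values.size == 1
    assert series.values[0] == pytest.approx(
        intra_nci(sub.data[:4]), rel=1e-12
    )


def test_sliding_window_too_long_raises():
    sub = SubjectTimeSeries("s", "pmdd", np.zeros((4, 9)) + np.arange(9))
    with pytest.raises(ValueError):
        sliding_nci(sub, NetworkDefinition("n", np.arange(3)), window_length=10)


def test_stationary_structure_has_no_trend():
    """Constant-in-time structure: regression slope of NCI on window ~ 0."""
    from scipy import stats as sps

    slopes = []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        shared = rng.normal(size=60)
        data = 0.8 * shared + rng.normal(size=(4, 60))
        sub = SubjectTimeSeries("s", "pmdd", data)
        series = sliding_nci(sub, NetworkDefinition("n", np.arange(4)), 10)
        ok = ~np.isnan(series.values)
        slopes.append(
            sps.linregress(series.window_starts[ok], series.values[ok]).slope
        )
    t = np.mean(slopes) / (np.std(slopes, ddof=1) / np.sqrt(len(slopes)))
    assert abs(t) < 3.5  # slope CI covers zero


# --- window group test ---------------------------------------------------


def _series(values, sid="s", nets="tom", w=10, step=1):
    values = np.asarray(values, float)
    return NCISeries(
        subject_id=sid,
        networks=nets,
        window_length=w,
        step=step,
        values=values,
        window_starts=np.arange(values.size) * step,
    )


def test_identical_distributions_z_zero_p_one():
    vals = np.array([[1.0, 2.0], [3.0, 1.5], [2.5, 0.5]])
    a = [_series(v, sid=f"a{i}") for i, v in enumerate(vals)]
    b = [_series(v, sid=f"b{i}") for i, v in enumerate(vals)]
    out = window_group_test(a, b)
    assert np.allclose(out["z"], 0.0)
    assert np.allclose(out["p"], 1.0)
    assert np.all(out["q"] >= out["p"] - 1e-15)


def test_ranksum_matches_exact_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(10):
        a, b = rng.normal(size=5), rng.normal(size=5)
        z_exp, _ = ranksum_z_p_o(list(a), list(b))
        assert ranksum_z(a, b) == pytest.approx(z_exp, rel=1e-10)
    # with ties, via midranks
    a = np.array([1.0, 1.0, 2.0, 3.0, 3.0])
    b = np.array([1.0, 2.0, 2.0, 4.0, 4.0])
    z_exp, _ = ranksum_z_p_o(list(a), list(b))
    assert ranksum_z(a, b) == pytest.approx(z_exp, rel=1e-10)


def test_complete_separation_hits_enumeration_maximum():
    a = [_series([v]) for v in (10.0, 11.0, 12.0, 13.0, 14.0)]
    b = [_series([v]) for v in (1.0, 2.0, 3.0, 4.0, 5.0)]
    out = window_group_test(a, b, method="perm")
    from oracles import ranksum_enumeration_o

    _, ws = ranksum_enumeration_o([10, 11, 12, 13, 14], [1, 2, 3, 4, 5])
    z_max = (max(ws) - np.mean(ws)) / np.std(ws)
    assert out.loc[0, "z"] == pytest.approx(z_max, rel=1e-10)
    assert out.loc[0, "p"] == pytest.approx(2 / 252, rel=1e-10)


def test_group_too_small_raises():
    a = [_series([1.0]) for _ in range(2)]
    b = [_series([2.0]) for _ in range(5)]
    with pytest.raises(ValueError, match="3 subjects"):
        window_group_test(a, b)


def test_degenerate_values_dropped_per_window():
    rng = np.random.default_rng(8)
    a = [_series(rng.normal(size=3), sid=f"a{i}") for i in range(4)]
    b = [_series(rng.normal(size=3), sid=f"b{i}") for i in range(4)]
    a[0].values[1] = np.nan
    out = window_group_test(a, b)
    assert out.loc[1, "n_a"] == 3 and out.loc[0, "n_a"] == 4
    assert np.isfinite(out.loc[1, "z"])


# --- BY FDR --------------------------------------------------------------


def test_by_worked_example():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    assert fdr_by(p) == pytest.approx(by_stepup_o(list(p)), abs=1e-12)


def test_by_single_test_identity():
    assert fdr_by(np.array([0.037]))[0] == pytest.approx(0.037)


def test_by_permutation_equivariance():
    rng = np.random.default_rng(9)
    p = rng.uniform(size=20)
    q = fdr_by(p)
    perm = rng.permutation(20)
    assert fdr_by(p[perm]) == pytest.approx(q[perm], abs=1e-15)


def test_by_never_below_p_and_validates():
    rng = np.random.default_rng(10)
    p = rng.uniform(size=30)
    assert np.all(fdr_by(p) >= p)
    with pytest.raises(ValueError):
        fdr_by(np.array([0.1, 1.2]))
    with pytest.raises(ValueError):
        fdr_by(np.array([-0.1, 0.5]))


def test_significant_runs_counts_consecutive_windows():
    table = pd.DataFrame(
        {
            "z": [3.0, 2.8, 2.6, 0.1, 2.9, 3.1],
            "q": [0.01, 0.02, 0.04, 0.9, 0.03, 0.01],
        }
    )
    runs = significant_runs(table, 0.05)
    assert runs["length"].tolist() == [3, 2]
    assert runs.loc[0, "z_min"] == 2.6 and runs.loc[0, "z_max"] == 3.0


# --- spatial specificity -------------------------------------------------


def _two_group_white(seed, n_units=20, n_tr=40, n_per=5, target_gain=0.0):
    rng = np.random.default_rng(seed)
    subs = []
    for g, tag in (("pmdd", "p"), ("control", "c")):
        for i in range(n_per):
            x = rng.normal(size=(n_units, n_tr))
            if g == "pmdd" and target_gain:
                x[:4] += target_gain * rng.normal(size=n_tr)
            subs.append(SubjectTimeSeries(f"{tag}{i}", g, x))
    return subs


def test_specificity_validation():
    subs = _two_group_white(0)
    net = NetworkDefinition("t", np.arange(4))
    with pytest.raises(ValueError, match="n_random"):
        spatial_specificity(subs, "pmdd", "control", 0, 10, net,
                            np.arange(4, 20), n_random=10)
    with pytest.raises(ValueError, match="pool"):
        spatial_specificity(subs, "pmdd", "control", 0, 10, net,
                            np.arange(4, 6), n_random=100)


def test_planted_target_effect_scores_near_100():
    subs = _two_group_white(1, target_gain=2.5)
    net = NetworkDefinition("t", np.arange(4))
    s = spatial_specificity(
        subs, "pmdd", "control", 5, 20, net, np.arange(4, 20),
        n_random=100, seed=2,
    )
    assert s > 95.0


def test_rating_epochs_cases():
    n = 60
    flat = RatingCurve(np.full(n, 1.0), np.full(n, 0.2), scale_max=6)
    assert rating_epochs(flat, 3.0, 10) == []  # threshold above the range
    allhigh = RatingCurve(np.full(n, 5.0), np.full(n, 0.2), scale_max=6)
    eps = rating_epochs(allhigh, 5.0, 10)
    assert len(eps) == 1 and eps[0].tr_start == 0 and eps[0].tr_stop == n
    assert eps[0].windows.size == n_windows(n, 10, 1)
    # bimodal: two supra-threshold runs with constructed boundaries
    med = np.full(n, 1.0)
    med[10:25] = 5.0
    med[40:55] = 5.0
    bim = RatingCurve(med, np.full(n, 0.2), scale_max=6)
    eps = rating_epochs(bim, 3.0, 10)
    assert [(e.tr_start, e.tr_stop) for e in eps] == [(10, 25), (40, 55)]
    assert list(eps[0].windows) == [10, 11, 12, 13, 14, 15]


def test_epoch_windows_fully_inside_run():
    med = np.zeros(50)
    med[20:33] = 4.0
    r = RatingCurve(med, np.full(50, 0.1), scale_max=6)
    (ep,) = rating_epochs(r, 2.0, window_length=10, step=2)
    assert all(s >= 20 and s + 10 <= 33 for s in ep.windows * 2)
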