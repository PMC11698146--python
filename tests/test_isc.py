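"""Leave-one-out ISC, phase-randomization surrogates, max-statistic null,
group thresholding and contrast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurosync import (
    NullDistribution,
    SubjectTimeSeries,
    compare_groups,
    group_isc,
    loo_isc,
    max_stat_null,
    phase_randomize,
    threshold_groups,
)
from neurosync.simulate import NetworkSpec, SimulationConfig, gen_dataset

from conftest import make_subjects
from oracles import loo_isc_o, welch_t_o


def test_identical_subjects_give_unit_correlation():
    base = np.random.default_rng(0).normal(size=(3, 30))
    subs = make_subjects([base.copy() for _ in range(4)])
    assert np.allclose(loo_isc(subs, "s00"), 1.0)


def test_orthogonal_series_give_zero():
    t = np.arange(24)
    cos = np.cos(2 * np.pi * t / 24)[None, :]
    sin = np.sin(2 * np.pi * t / 24)[None, :]
    subs = make_subjects([cos, sin, sin])
    assert loo_isc(subs, "s00")[0] == pytest.approx(0.0, abs=1e-12)


def test_loo_matches_brute_force_oracle():
    data = [
        np.array([[1, 2, 3, 4, 5, 6.0]]),
        np.array([[2, 1, 4, 3, 6, 5.0]]),
        np.array([[1, 3, 2, 5, 4, 6.0]]),
    ]
    subs = make_subjects(data)
    for i in range(3):
        expected = loo_isc_o(data, i)
        got = loo_isc(subs, f"s{i:02d}")
        assert got == pytest.approx(expected, rel=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    a=st.floats(min_value=0.1, max_value=50),
    b=st.floats(min_value=-100, max_value=100),
)
def test_positive_affine_invariance(a, b):
    rng = np.random.default_rng(7)
    data = [rng.normal(size=(2, 25)) for _ in range(4)]
    subs = make_subjects([d.copy() for d in data])
    r0 = loo_isc(subs, "s01")
    data[1] = a * data[1] + b
    subs2 = make_subjects(data)
    assert loo_isc(subs2, "s01") == pytest.approx(r0, rel=1e-9)


def test_constant_series_flagged_nan():
    rng = np.random.default_rng(1)
    data = [rng.normal(size=(2, 20)) for _ in range(3)]
    data[0][1] = 5.0  # constant unit in the left-out subject
    subs = make_subjects(data)
    r = loo_isc(subs, "s00")
    assert np.isnan(r[1]) and not np.isnan(r[0])


def test_too_few_subjects_raises():
    rng = np.random.default_rng(2)
    subs = make_subjects([rng.normal(size=(2, 20)) for _ in range(2)])
    with pytest.raises(ValueError, match="at least 3"):
        loo_isc(subs, "s00")


def test_group_isc_row_order_invariance():
    rng = np.random.default_rng(3)
    data = [rng.normal(size=(3, 30)) for _ in range(4)]
    subs = make_subjects(data)
    res = group_isc(subs, "pmdd")
    perm = [subs[2], subs[0], subs[3], subs[1]]
    res_p = group_isc(perm, "pmdd")
    for i, s in enumerate(perm):
        j = res.subject_ids.index(s.subject_id)
        assert np.allclose(res_p.r[i], res.r[j])


def test_unknown_group_raises():
    rng = np.random.default_rng(4)
    subs = make_subjects([rng.normal(size=(2, 20)) for _ in range(3)])
    with pytest.raises(ValueError, match="unknown group"):
        group_isc(subs, "nogroup")


# --- phase randomization -------------------------------------------------


def test_constant_series_unchanged():
    x = np.full(17, 3.5)
    assert np.allclose(phase_randomize(x, seed=0), x)


@pytest.mark.parametrize("n", [16, 17, 64, 101])
def test_amplitude_spectrum_and_mean_preserved(n):
    x = np.random.default_rng(n).normal(size=n)
    y = phase_randomize(x, seed=1)
    assert np.isrealobj(y)
    np.testing.assert_allclose(
        np.abs(np.fft.rfft(y)), np.abs(np.fft.rfft(x)), rtol=1e-10, atol=1e-10
    )
    assert y.mean() == pytest.approx(x.mean(), abs=1e-12)


def test_single_bin_cosine_stays_single_sinusoid():
    n = 64
    t = np.arange(n)
    x = 2.0 * np.cos(2 * np.pi * 5 * t / n)
    y = phase_randomize(x, seed=2)
    F = np.fft.rfft(y) / n * 2
    mags = np.abs(F)
    assert mags[5] == pytest.approx(2.0, rel=1e-10)
    assert np.all(np.delete(mags, 5) < 1e-10)


def test_autocorrelation_preserved():
    """Wiener-Khinchin: the surrogate's circular ACF equals the original's."""
    x = np.random.default_rng(9).normal(size=80).cumsum()  # strongly smooth
    y = phase_randomize(x, seed=3)

    def acf(v):
        f = np.fft.rfft(v - v.mean())
        return np.fft.irfft(f * np.conj(f), n=v.size)

    np.testing.assert_allclose(acf(y), acf(x), rtol=1e-8, atol=1e-8)


def test_rejects_complex_and_short_input():
    with pytest.raises(TypeError):
        phase_randomize(np.array([1 + 1j, 2 + 0j]))
    with pytest.raises(ValueError):
        phase_randomize(np.array([1.0]))
    with pytest.raises(ValueError):
        phase_randomize(np.array([1.0, np.nan, 2.0]))


# --- max-statistic null and thresholding ---------------------------------


def _null_cfg(seed, alpha=0.0):
    return SimulationConfig(
        n_per_group=3, n_units=8, n_tr=60, alpha_load=alpha,
        ar_phi=0.0, subject_gain_sd=0.0, seed=seed,
    )


def test_null_values_bounded_and_sized():
    ds = gen_dataset(_null_cfg(0))
    null = max_stat_null(ds.subjects, "pmdd", n_iter=120, seed=1)
    assert null.values.size == 120
    assert np.all(null.values >= -1) and np.all(null.values <= 1)


def test_null_requires_min_iterations():
    ds = gen_dataset(_null_cfg(1))
    with pytest.raises(ValueError, match="n_iter"):
        max_stat_null(ds.subjects, "pmdd", n_iter=50, seed=0)


def test_planted_signal_exceeds_null():
    """A strongly loaded unit beats the top of the null (power spot-check)."""
    alpha = np.zeros(8)
    alpha[3] = 1.5
    ds = gen_dataset(_null_cfg(2, alpha=alpha))
    res = group_isc(ds.subjects, "pmdd")
    null = max_stat_null(ds.subjects, "pmdd", n_iter=1000, seed=3)
    top = np.sort(null.values)[-1]  # 100*(1 - 1/n_iter) percentile
    assert res.stat[3] > top


def test_threshold_monotone_in_alpha():
    null = NullDistribution(values=np.linspace(-0.2, 0.9, 500), n_iter=500)
    thresholds = [null.threshold(a) for a in (0.2, 0.1, 0.05, 0.01)]
    assert all(t2 >= t1 for t1, t2 in zip(thresholds, thresholds[1:]))
    assert null.threshold(1e-6) == np.inf  # below 1/(n_iter+1) resolution


def test_threshold_groups_union_and_validation():
    rng = np.random.default_rng(5)
    r = rng.uniform(-0.2, 0.2, size=(3, 6))
    from neurosync import ISCResult

    res_a = ISCResult("pmdd", ["a", "b", "c"], r.copy())
    res_b = ISCResult("control", ["d", "e", "f"], r.copy())
    res_a.r[:, 0] = 0.9  # significant in A only
    res_b.r[:, 5] = 0.9  # significant in B only
    res_a = ISCResult("pmdd", ["a", "b", "c"], res_a.r)
    res_b = ISCResult("control", ["d", "e", "f"], res_b.r)
    null = NullDistribution(values=np.linspace(0, 0.5, 500), n_iter=500)
    mask = threshold_groups(res_a, res_b, null, null, alpha=0.05)
    assert mask[0] and mask[5]
    assert mask.sum() == res_a.sig_mask.sum() + res_b.sig_mask.sum()
    with pytest.raises(ValueError, match="alpha"):
        threshold_groups(res_a, res_b, null, null, alpha=1.5)


# --- group contrast ------------------------------------------------------


def _result_from_r(group, r):
    from neurosync import ISCResult

    return ISCResult(group, [f"{group}{i}" for i in range(r.shape[0])], r)


def test_identical_groups_t_zero_p_one():
    r = np.random.default_rng(6).uniform(-0.5, 0.5, size=(4, 5))
    res_a, res_b = _result_from_r("pmdd", r), _result_from_r("control", r)
    unit_table, roi = compare_groups(res_a, res_b, np.ones(5, bool))
    assert np.allclose(unit_table["t"], 0.0)
    assert np.allclose(unit_table["p"], 1.0)
    assert roi.empty


def test_welch_t_matches_textbook_oracle():
    za = np.array([0.5, 0.6, 0.7])
    zb = np.array([0.1, 0.2, 0.3])
    res_a = _result_from_r("pmdd", np.tanh(za)[:, None])
    res_b = _result_from_r("control", np.tanh(zb)[:, None])
    unit_table, roi = compare_groups(res_a, res_b, np.ones(1, bool))
    t_exp, p_exp = welch_t_o(list(za), list(zb))
    assert unit_table.loc[0, "t"] == pytest.approx(t_exp, rel=1e-9)
    assert unit_table.loc[0, "p"] == pytest.approx(p_exp, rel=1e-9)
    assert roi.loc[0, "direction"] == 1


def test_empty_mask_gives_empty_table():
    r = np.random.default_rng(8).uniform(-0.5, 0.5, size=(3, 4))
    res_a, res_b = _result_from_r("pmdd", r), _result_from_r("control", -r)
    unit_table, roi = compare_groups(res_a, res_b, np.zeros(4, bool))
    assert unit_table.empty and roi.empty


def test_roi_clustering_contiguity_and_coords():
    rng = np.random.default_rng(10)
    r_a = rng.uniform(-0.1, 0.1, size=(5, 8))
    r_b = r_a.copy()
    r_a[:, [1, 2, 6]] += 0.8  # two separated clusters of difference
    res_a, res_b = _result_from_r("pmdd", r_a), _result_from_r("control", r_b)
    coords = np.arange(24, dtype=float).reshape(8, 3)
    unit_table, roi = compare_groups(
        res_a, res_b, np.ones(8, bool), coords=coords
    )
    assert len(roi) == 2
    assert roi.loc[0, "units"] == [1, 2] and roi.loc[1, "units"] == [6]
    assert roi.loc[1, "peak_x"] == coords[6, 0]
    assert set(roi["direction"]) == {1}
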