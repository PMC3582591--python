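import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcfseg import (
    WinsorParams,
    estimate_residual_sd,
    impute_missing,
    mad_scale,
    median_filter_trend,
    psi_clip,
    winsorize,
)
from pcfseg.preprocess import winsorize_values


@pytest.mark.parametrize(
    "x,theta,expected",
    [(2.7, 1.5, 1.5), (-0.4, 1.5, -0.4), (-9.0, 2.0, -2.0), (0.0, 0.1, 0.0)],
)
def test_psi_clip_cases(x, theta, expected):
    assert psi_clip(x, theta) == expected


def test_psi_clip_rejects_nonpositive_threshold():
    with pytest.raises(ValueError):
        psi_clip(1.0, 0.0)


@given(st.floats(-50, 50), st.floats(0.01, 10))
def test_psi_clip_bounded_and_identity_inside(x, theta):
    y = psi_clip(x, theta)
    assert abs(y) <= theta
    if abs(x) <= theta:
        assert y == x


def test_median_trend_constant_sequence_unchanged():
    y = np.full(30, 3.25)
    for k in (1, 5, 25):
        np.testing.assert_array_equal(median_filter_trend(y, k), y)


def test_median_trend_suppresses_single_outlier():
    y = np.array([0, 0, 0, 10, 0, 0, 0], dtype=float)
    assert median_filter_trend(y, 2)[3] == 0


def test_median_trend_shrinking_windows_and_even_midpoint():
    np.testing.assert_allclose(median_filter_trend([1, 5, 2], 1), [3.0, 2.0, 3.5])


def test_median_trend_rejects_bad_input():
    with pytest.raises(ValueError):
        median_filter_trend([], 1)
    with pytest.raises(ValueError):
        median_filter_trend([1.0, 2.0], 0)


def test_mad_scale_hand_value_and_constant():
    assert mad_scale([1, 2, 3, 4, 100]).s == pytest.approx(1.4826)
    assert mad_scale([5.0] * 10).s == 0.0


def test_mad_scale_estimates_gaussian_sd(rng):
    x = rng.standard_normal(200_000)
    assert mad_scale(x).s == pytest.approx(1.0, abs=0.01)


def test_winsorize_clips_spike_to_tau_s_above_trend():
    # flat-trend sequence: trend is the global median 0.1, residual MAD 0.15
    y = np.array([0.1, -0.2, 0.1, -0.1, 10, 0.2, -0.1, 0.1, -0.2, 0.1])
    s = 1.4826 * 0.15
    w = winsorize_values(y, WinsorParams(tau=2.5, k_trend=25))
    assert s == pytest.approx(0.22239)
    assert w[4] == pytest.approx(0.1 + 2.5 * s)
    np.testing.assert_allclose(w[:4], y[:4])


def test_winsorize_identity_when_no_outliers(rng):
    y = 0.05 * np.sin(np.arange(100) / 30)  # smooth, residuals tiny & uniform
    y += rng.normal(0, 0.01, 100)
    w = winsorize_values(y, WinsorParams(tau=3.0))
    trend = median_filter_trend(y, 25)
    s = mad_scale(y - trend).s
    if np.all(np.abs(y - trend) <= 3 * s):
        np.testing.assert_allclose(w, y, atol=1e-12)


def test_winsorize_degenerate_scale_floors_with_warning():
    y = np.concatenate([np.zeros(20), [5.0], np.zeros(20)])
    with pytest.warns(UserWarning, match="degenerate"):
        w = winsorize_values(y, WinsorParams(tau=2.5, k_trend=5))
    assert abs(w[20]) < 1e-9  # spike pulled to the constant level


def test_winsorize_table_preserves_grid_missing_and_bound(small_table):
    params = WinsorParams(tau=2.0, k_trend=1)
    out = winsorize(small_table, params)
    assert list(out.pos) == list(small_table.pos)
    assert list(out.chrom) == list(small_table.chrom)
    assert np.isnan(out.values[0, 2])  # missing stays missing


def test_winsorize_idempotent_on_clean_gaussian(rng):
    y = rng.standard_normal(500)
    params = WinsorParams(tau=2.5)
    once = winsorize_values(y, params)
    twice = winsorize_values(once, params)
    # after clipping, the re-estimated threshold retains all residuals
    assert np.max(np.abs(twice - once)) < 0.05
    assert np.mean(twice != once) < 0.05


def test_winsorize_alters_more_values_on_contaminated_data(rng):
    from pcfseg import ContaminationSpec

    clean = rng.standard_normal(5000)
    cont = ContaminationSpec(alpha=0.05, d=3.0).draw(rng, 5000)
    params = WinsorParams(tau=2.5)
    frac_clean = np.mean(winsorize_values(clean, params) != clean)
    frac_cont = np.mean(winsorize_values(cont, params) != cont)
    assert frac_cont > frac_clean


def test_residual_sd_on_iid_gaussian(rng):
    y = rng.standard_normal(100_000)
    assert estimate_residual_sd(y).s == pytest.approx(1.0, abs=0.02)


def test_residual_sd_ignores_level_shifts_and_scales():
    y = np.repeat([0.0, 2.0, -1.0], 200)
    assert estimate_residual_sd(y).s == pytest.approx(0.0, abs=1e-12)
    z = np.tile([0.1, -0.1, 0.2, -0.3], 100)
    assert estimate_residual_sd(2 * z).s == pytest.approx(2 * estimate_residual_sd(z).s)


def test_residual_sd_aggregates_arms_by_median(rng):
    arms = [rng.standard_normal(5001) * s for s in (0.5, 1.0, 2.0)]
    est = estimate_residual_sd(arms)
    assert est.s == pytest.approx(np.median([estimate_residual_sd(a).s for a in arms]))
    assert est.s == pytest.approx(1.0, abs=0.05)


def test_impute_midpoint_edge_and_identity(small_table):
    from pcfseg import CopyNumberTable

    t = CopyNumberTable(
        chrom=np.array(["1"] * 3), pos=np.array([1, 2, 3]),
        sample_ids=["a", "b"],
        values=np.array([[1.0, np.nan, 3.0], [np.nan, 5.0, 5.0]]),
    )
    out = impute_missing(t)
    assert out.values[0, 1] == 2.0  # mean of the two neighbours
    assert out.values[1, 0] == 5.0  # one-sided at the edge
    full = impute_missing(out)
    np.testing.assert_array_equal(full.values, out.values)


def test_impute_rejects_fully_missing_arm():
    from pcfseg import CopyNumberTable

    t = CopyNumberTable(
        chrom=np.array(["1", "1"]), pos=np.array([1, 2]),
        sample_ids=["a"], values=np.array([[np.nan, np.nan]]),
    )
    with pytest.raises(ValueError, match="missing"):
        impute_missing(t)
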