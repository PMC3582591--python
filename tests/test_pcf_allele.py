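import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcfseg import (
    PenaltySpec,
    aspcf,
    filter_homozygous,
    mirror_baf,
    multipcf,
    pair_logr_to_baf,
)
from pcfseg.simulate import simulate_snp_tracks


@pytest.mark.parametrize("b,expected", [(0.7, 0.3), (0.5, 0.5), (0.2, 0.2)])
def test_mirror_reflects_above_half(b, expected):
    assert mirror_baf(b) == pytest.approx(expected)


def test_mirror_passes_missing_and_rejects_out_of_range():
    assert np.isnan(mirror_baf(np.array([np.nan, 0.6]))[0])
    with pytest.raises(ValueError):
        mirror_baf([1.2])


@given(st.floats(0, 1))
def test_mirroring_is_idempotent_and_at_most_half(b):
    m = mirror_baf(b)
    assert 0 <= m <= 0.5
    assert mirror_baf(m) == m


def test_homozygote_filter_threshold_and_na():
    mask = filter_homozygous(np.array([0.05, 0.3, np.nan]), 0.1)
    assert list(mask) == [False, True, False]
    mask0 = filter_homozygous(np.array([0.05, 0.3, np.nan]), 0.0)
    assert list(mask0) == [True, True, False]
    assert filter_homozygous(np.array([0.1, 0.49]), 0.1).all()
    with pytest.raises(ValueError):
        filter_homozygous(np.array([0.3]), 0.6)


def test_pairing_assigns_nearest_and_averages():
    r, assign = pair_logr_to_baf(
        np.array([1.0, 2.0, 3.0]), np.array([10, 20, 30]), np.array([12, 29])
    )
    np.testing.assert_allclose(r, [1.5, 3.0])  # |20-12| = 8 < |29-20| = 9
    assert list(assign) == [0, 0, 1]


def test_pairing_single_baf_probe_gets_global_mean():
    r, _ = pair_logr_to_baf(np.array([1.0, 3.0, 5.0]), np.array([1, 2, 3]), np.array([2]))
    np.testing.assert_allclose(r, [3.0])


def test_pairing_identity_when_grids_coincide(rng):
    pos = np.arange(1, 11) * 100
    logr = rng.standard_normal(10)
    r, assign = pair_logr_to_baf(logr, pos, pos)
    np.testing.assert_array_equal(r, logr)
    assert list(assign) == list(range(10))


def test_pairing_tie_goes_to_leftward_probe():
    _, assign = pair_logr_to_baf(np.array([1.0]), np.array([20]), np.array([10, 30]))
    assert assign[0] == 0


def test_balanced_diploid_track_gives_single_segment():
    prof = simulate_snp_tracks([(300, "balanced")], seed=11)
    res = aspcf(prof.values, prof.baf, penalty=PenaltySpec(gamma=40, kmin=5))
    assert res.segmentation.n_segments == 1


def test_baf_only_event_is_detected_with_flat_logr():
    # copy-neutral LOH: logR level unchanged, mirrored BAF drops below 0.5
    prof = simulate_snp_tracks([(200, "balanced"), (200, "cnloh")], seed=5)
    res = aspcf(prof.values, prof.baf, penalty=PenaltySpec(gamma=20, kmin=5))
    assert res.segmentation.n_segments == 2
    assert abs(res.orig_start_indices[1] - 201) <= 3
    assert abs(res.logr_means[1] - res.logr_means[0]) < 0.15
    assert res.baf_means[1] < res.baf_means[0] - 0.1


def test_track_pair_and_boundaries_share_one_index_set(rng):
    prof = simulate_snp_tracks(
        [(150, "balanced"), (150, "hemizygous_loss"), (150, "gain")], seed=9
    )
    res = aspcf(prof.values, prof.baf, penalty=PenaltySpec(gamma=20, kmin=5))
    assert np.all((res.pair.y1 >= 0) & (res.pair.y1 <= 0.5))
    assert res.segmentation.means.shape == (res.segmentation.n_segments, 2)
    assert res.orig_start_indices.size == res.segmentation.n_segments


def test_duplicated_track_equals_two_sample_multipcf(rng):
    # feeding a pre-mirrored synthetic "BAF" identical to a logR track with
    # theta=0 reduces the allele-specific fit to plain two-track PCF
    y = np.clip(0.2 + 0.04 * rng.standard_normal(100), 0.0, 0.35)
    y[50:] += 0.1  # stays within [0, 0.5], so mirroring leaves it unchanged
    pen = PenaltySpec(gamma=10, kmin=5, normalize=False)
    res = aspcf(y, y, penalty=pen, theta_baf=0.0)
    ref = multipcf(np.vstack([y, y]), pen)
    np.testing.assert_array_equal(res.segmentation.start_indices, ref.start_indices)
    np.testing.assert_allclose(res.segmentation.means, ref.means, atol=1e-12)


def test_matches_brute_force_two_track_oracle(rng):
    from pcfseg.simulate import brute_force_pcf

    for _ in range(30):
        p = int(rng.integers(3, 11))
        y1 = np.round(rng.uniform(0.1, 0.5, p), 2)
        y2 = np.round(rng.standard_normal(p), 1)
        gamma = float(rng.uniform(0.5, 6))
        res = aspcf(y2, y1, penalty=PenaltySpec(gamma=gamma, kmin=1, normalize=False),
                    theta_baf=0.0)
        _, cost = brute_force_pcf(np.vstack([y1, y2]), gamma)
        assert res.segmentation.total_cost == pytest.approx(cost, abs=1e-9)


def test_rejects_mismatched_tracks():
    with pytest.raises(ValueError):
        aspcf(np.zeros(5), np.full(4, 0.5))
    with pytest.raises(ValueError, match="impute"):
        aspcf(np.array([np.nan, 0.0]), np.array([0.5, 0.5]))
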