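import numpy as np
import pytest

from pcfseg import (
    CandidateSet,
    FilterBank,
    PenaltySpec,
    highpass_scores,
    pcf_exact,
    pcf_fast,
    pcf_on_candidates,
    select_candidates,
)
from pcfseg.simulate import ContaminationSpec, simulate_profile

STEP = np.array([0.0, 0.0, 0.0, 4.0, 4.0, 4.0])


def test_highpass_zero_on_constant_input():
    np.testing.assert_array_equal(highpass_scores(np.full(50, 2.5), 12), np.zeros(50))


def test_highpass_unit_step_peak_value_and_location():
    y = np.zeros(40)
    y[19:] = 1.0  # step at 1-based position 20
    sc = highpass_scores(y, 3)
    # weights [1, 1, 0.5] inner->outer: full right window sums to 2.5
    assert sc[18] == pytest.approx(2.5)
    assert np.argmax(np.abs(sc)) == 18


def test_highpass_is_linear_in_sign():
    rng = np.random.default_rng(3)
    y = rng.standard_normal(100)
    np.testing.assert_allclose(highpass_scores(-y, 12), -highpass_scores(y, 12))


def test_highpass_rejects_bad_width_and_short_input():
    with pytest.raises(ValueError):
        highpass_scores(np.zeros(10), 0)
    np.testing.assert_array_equal(highpass_scores(np.zeros(5), 12), np.zeros(5))


def test_filter_bank_adds_kmin_matched_width():
    assert FilterBank().with_kmin(5).widths == (3, 5, 12)
    assert FilterBank().with_kmin(3).widths == (3, 12)


def test_candidates_full_fraction_admits_every_position(rng):
    y = rng.standard_normal(50)
    cs = select_candidates(y, target_fraction=1.0)
    np.testing.assert_array_equal(cs.starts, np.arange(1, 52))  # every start + sentinel


def test_candidate_fraction_close_to_target_on_noise(rng):
    y = rng.standard_normal(5000)
    cs = select_candidates(y, FilterBank().with_kmin(5), 0.15)
    frac = (cs.starts.size - 2) / 5000
    assert 0.10 <= frac <= 0.20


def test_large_step_always_among_candidates():
    # noise can shift the filter-response peak by one probe, so exact-position
    # recall is allowed a few near-misses but +-1-probe recall must be perfect
    exact = within_one = 0
    for r in range(100):
        rng = np.random.default_rng(7000 + r)
        y = rng.standard_normal(500)
        y[250:] += 5.0  # 5-sigma step, segment start at 1-based 251
        cs = select_candidates(y, FilterBank().with_kmin(5), 0.15)
        exact += 251 in cs.starts
        within_one += bool(np.any(np.abs(cs.starts - 251) <= 1))
    assert within_one == 100
    assert exact >= 95


def test_candidate_set_validation():
    with pytest.raises(ValueError, match="sentinel"):
        CandidateSet(starts=np.array([2, 7]), n_probes=6)
    with pytest.raises(ValueError, match="increasing"):
        CandidateSet(starts=np.array([1, 4, 4, 7]), n_probes=6)


def test_restriction_vacuous_with_full_candidate_set():
    full = CandidateSet(starts=np.arange(1, 8), n_probes=6)
    pen = PenaltySpec(gamma=1, kmin=1, normalize=False)
    a = pcf_on_candidates(STEP, full, pen)
    b = pcf_exact(STEP, pen)
    np.testing.assert_array_equal(a.start_indices, b.start_indices)
    assert a.total_cost == pytest.approx(b.total_cost, abs=1e-12)


def test_restricted_candidates_examples():
    pen = PenaltySpec(gamma=1, kmin=1, normalize=False)
    mid = pcf_on_candidates(STEP, CandidateSet(starts=np.array([1, 4, 7]), n_probes=6), pen)
    assert list(mid.start_indices) == [1, 4]
    np.testing.assert_allclose(mid.means, [0.0, 4.0])
    forced = pcf_on_candidates(STEP, CandidateSet(starts=np.array([1, 7]), n_probes=6), pen)
    assert forced.n_segments == 1 and forced.means[0] == pytest.approx(2.0)


def test_full_candidates_match_exact_on_random_instances(rng):
    pen = PenaltySpec(gamma=4, kmin=1, normalize=False)
    for _ in range(30):
        p = int(rng.integers(10, 201))
        y = rng.standard_normal(p)
        full = CandidateSet(starts=np.arange(1, p + 2), n_probes=p)
        a = pcf_on_candidates(y, full, pen)
        b = pcf_exact(y, pen)
        assert a.total_cost == pytest.approx(b.total_cost, abs=1e-9)


def test_fast_finds_exact_breakpoint_on_clear_step():
    prof = simulate_profile(
        [(50, 0.0), (50, 2.0)], ContaminationSpec(alpha=0, sigma=0.5), seed=3
    )
    pen = PenaltySpec(gamma=40, kmin=5)
    np.testing.assert_array_equal(
        pcf_fast(prof.values, pen).start_indices,
        pcf_exact(prof.values, pen).start_indices,
    )


def test_fast_cost_never_beats_exact(rng):
    pen = PenaltySpec(gamma=15, kmin=5, normalize=False)
    for seed in range(5):
        prof = simulate_profile(
            [(200, 0.0), (100, 1.0), (200, -0.5)],
            ContaminationSpec(alpha=0, sigma=0.8),
            seed=seed,
        )
        fe = pcf_exact(prof.values, pen)
        ff = pcf_fast(prof.values, pen)
        assert ff.total_cost >= fe.total_cost - 1e-9


def test_constant_sequence_single_segment_any_length():
    fit = pcf_fast(np.full(2000, 0.3), PenaltySpec(gamma=40, kmin=5, normalize=False))
    assert fit.n_segments == 1 and fit.means[0] == pytest.approx(0.3)


def test_subsequence_mode_recovers_strong_breakpoints(rng):
    # force the overlapping-subsequence path with a small max_arm
    spec = [(700, 0.0), (700, 2.0), (700, -1.0), (700, 1.0)]
    prof = simulate_profile(spec, ContaminationSpec(alpha=0, sigma=0.5), seed=21)
    pen = PenaltySpec(gamma=40, kmin=5)
    fit = pcf_fast(prof.values, pen, max_arm=1500, sub_len=1000, overlap=200)
    exact = pcf_exact(prof.values, pen)
    np.testing.assert_array_equal(fit.start_indices, exact.start_indices)
    np.testing.assert_allclose(fit.means, exact.means, atol=1e-12)


def test_fast_rejects_bad_inputs():
    with pytest.raises(ValueError):
        pcf_fast([], PenaltySpec())
    with pytest.raises(ValueError, match="overlap"):
        pcf_fast(np.zeros(10), PenaltySpec(), sub_len=100, overlap=100)
    with pytest.raises(ValueError):
        select_candidates(np.zeros(10), target_fraction=0.0)
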