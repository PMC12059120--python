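"""Shuffle-null classification, rank tests, and cross-validated selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from calseq.core import DffTensor, ValidationError, WindowSpec
from calseq.preprocess import align_trials, compute_dff
from calseq.responsiveness import (
    build_null,
    build_null_matrix,
    categorize,
    classify_neuron_session,
    classify_recording,
    crossval_select,
    rank_sum_test,
    single_trial_responses,
)
from calseq.simulate import CalciumKernel, SimConfig, simulate_experiment

from conftest import SMALL_SESSIONS


def _noise_dff(n_neurons=1, n_trials=20, n_frames=120, sd=0.05, seed=0, t0=60):
    rng = np.random.default_rng(seed)
    return DffTensor(
        dff=rng.normal(0.0, sd, (n_neurons, n_trials, n_frames)),
        t0_frame=t0,
        frame_rate=30.0,
        trial_ids=np.arange(n_trials),
    )


# ---------------------------------------------------------------------------
# single-trial response statistic
# ---------------------------------------------------------------------------


def test_flat_trial_response_is_zero():
    dff = DffTensor(np.zeros((1, 4, 120)), 60, 30.0, np.arange(4))
    np.testing.assert_allclose(single_trial_responses(dff), 0.0)


def test_response_is_post_minus_pre_mean():
    dff = DffTensor(np.zeros((1, 1, 120)), 60, 30.0, [0])
    dff.dff[0, 0, 60:90] = 0.4
    assert np.isclose(single_trial_responses(dff)[0, 0], 0.4)


def test_baseline_gap_uses_earlier_window():
    dff = DffTensor(np.zeros((1, 1, 150)), 90, 30.0, [0])
    dff.dff[0, 0, 60:90] = 0.5  # delay period, skipped by the gap
    assert np.isclose(single_trial_responses(dff)[0, 0], -0.5)
    assert np.isclose(single_trial_responses(dff, baseline_gap=30)[0, 0], 0.0)


def test_planted_kernel_response_matches_quadrature_oracle():
    """Noise-free planted transient vs numerical integration of the kernel."""
    amp = 0.5
    kernel = CalciumKernel(0.05, 1.0)
    expected = amp * integrate.quad(kernel, 0.0, 1.0)[0] / 1.0
    cfg = SimConfig(
        n_neurons=1,
        session_sizes=dict(SMALL_SESSIONS),
        category_fractions={"whisker": 1.0},
        reliability=1.0,
        amplitude_mu=float(np.log(amp)),
        amplitude_sigma=0.0,
        noise_sd=0.0,
        drift_amplitude=0.0,
    )
    rec, trials, _ = simulate_experiment(cfg, 2)
    sub = trials.select(session="whisker")
    dff = compute_dff(align_trials(rec, sub, "stim_onset"), sub)
    values = single_trial_responses(dff)
    np.testing.assert_allclose(values, expected, rtol=0.02)  # 30 Hz sampling


def test_window_overflow_is_error():
    dff = DffTensor(np.zeros((1, 2, 40)), 20, 30.0, [0, 1])
    with pytest.raises(ValidationError, match="overflow"):
        single_trial_responses(dff)


# ---------------------------------------------------------------------------
# null distribution
# ---------------------------------------------------------------------------


def test_null_of_constant_session_is_identically_zero():
    null = build_null(
        np.full((10, 120), 0.0), 1000, np.random.default_rng(0), 30.0, 60
    )
    np.testing.assert_array_equal(null.values, 0.0)
    assert null.n_draws == 1000


def test_null_is_reproducible_given_seed():
    dff = np.random.default_rng(3).normal(0, 1, (10, 120))
    a = build_null(dff, 1000, np.random.default_rng(9), 30.0, 60)
    b = build_null(dff, 1000, np.random.default_rng(9), 30.0, 60)
    np.testing.assert_array_equal(a.values, b.values)


def test_null_mean_on_white_noise_matches_analytic_se():
    """Draw = difference of two 30-frame means of iid noise.

    Each draw has sd sigma*sqrt(2/30); draws reuse overlapping windows of
    the same finite session, so the effective sample size for the mean is
    the number of non-overlapping window pairs, not the draw count.
    """
    sd = 0.3
    rng = np.random.default_rng(5)
    dff = rng.normal(0, sd, (40, 210))
    null = build_null(dff, 1000, rng, 30.0, 120)
    draw_sd = sd * np.sqrt(2.0 / 30.0)
    n_indep = 40 * (210 // 60)
    assert abs(null.values.mean()) < 3 * draw_sd / np.sqrt(n_indep)
    assert np.isclose(null.values.std(), draw_sd, rtol=0.15)


def test_null_too_short_session_is_error():
    with pytest.raises(ValidationError, match="short"):
        build_null(np.zeros((3, 50)), 100, np.random.default_rng(0), 30.0, 25)


def test_null_stimulus_window_exclusion_shifts_anchor_support():
    dff = DffTensor(np.zeros((1, 5, 300)), 150, 30.0, np.arange(5))
    dff.dff[:, :, 150:180] = 1.0  # stimulus response window
    incl = build_null_matrix(dff, 2000, np.random.default_rng(1))
    excl = build_null_matrix(
        dff, 2000, np.random.default_rng(1), exclude_stimulus_windows=True
    )
    assert np.any(incl != 0.0)
    np.testing.assert_array_equal(excl, 0.0)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------


def brute_force_rank_sum(x, y):
    """Exact two-sided p by enumerating all label assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    total = list(ranks.values())
    stats_all = [sum(c) for c in itertools.combinations(total, n)]
    mean = np.mean(stats_all)
    extreme = sum(1 for s in stats_all if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(stats_all)


def test_rank_sum_canonical_examples():
    assert np.isclose(rank_sum_test([1, 2, 3], [4, 5, 6]), 0.1)
    assert rank_sum_test([1.0, 2.0, 2.0], [2.0, 1.0, 2.0]) == 1.0
    with pytest.raises(ValidationError):
        rank_sum_test([], [1.0])


def test_rank_sum_matches_enumeration_on_random_small_samples():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = int(rng.integers(2, 5))
        m = int(rng.integers(2, 7 - min(n, 4)) + 2)
        vals = rng.permutation(np.arange(1.0, n + m + 1.0))
        x, y = vals[:n], vals[n:]
        assert np.isclose(rank_sum_test(x, y), brute_force_rank_sum(x, y))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def test_planted_responses_are_classified_responsive():
    rng = np.random.default_rng(0)
    responses = rng.normal(0.5, 0.05, 24)
    null = rng.normal(0.0, 0.05, 1000)
    rec = classify_neuron_session(responses, null)
    assert rec["responsive"] and rec["selected"] and rec["p_value"] < 1e-6
    assert rec["n_trials"] == 24


def test_insufficient_trials_are_flagged_not_tested():
    rec = classify_neuron_session(np.array([0.1, 0.2, 0.3]), np.zeros(1000))
    assert rec["insufficient"] and not rec["responsive"] and np.isnan(rec["p_value"])


def test_null_drawn_responses_are_rarely_significant():
    rng = np.random.default_rng(11)
    hits = 0
    n_rep = 400
    for _ in range(n_rep):
        null = rng.normal(0.0, 1.0, 1000)
        responses = rng.normal(0.0, 1.0, 20)
        if classify_neuron_session(responses, null)["responsive"]:
            hits += 1
    rate = hits / n_rep
    band = 2.58 * np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) < band


def test_detection_monotone_in_amplitude_and_trial_count():
    """Detection rate grows with planted effect size and with trials."""
    rng = np.random.default_rng(21)

    def rate(amp, n_trials, reps=150):
        hits = 0
        for _ in range(reps):
            null = rng.normal(0.0, 0.05, 1000)
            responses = rng.normal(amp, 0.05, n_trials)
            hits += classify_neuron_session(responses, null)["responsive"]
        return hits / reps

    by_amp = [rate(a, 20) for a in (0.005, 0.02, 0.2)]
    assert by_amp[0] <= by_amp[1] <= by_amp[2]
    assert by_amp[2] > 0.9
    by_n = [rate(0.02, n) for n in (6, 12, 40)]
    assert by_n[0] <= by_n[1] <= by_n[2]


def test_classification_is_deterministic_given_seed(small_experiment):
    _, rec, trials, _ = small_experiment
    a = classify_recording(rec, trials, rng=np.random.default_rng(3))
    b = classify_recording(rec, trials, rng=np.random.default_rng(3))
    pd.testing.assert_frame_equal(a, b)


def test_classification_covers_every_window_and_neuron(small_experiment):
    _, rec, trials, _ = small_experiment
    records = classify_recording(rec, trials, rng=np.random.default_rng(3))
    assert set(records["window"]) == {
        "looming", "nonlooming", "looming_offset", "nonlooming_offset",
        "whisker", "pairing", "matched", "mismatch",
    }
    assert len(records) == 8 * rec.n_neurons
    assert records["p_value"].between(0, 1).all()


# ---------------------------------------------------------------------------
# selection and categorisation
# ---------------------------------------------------------------------------


def _record(nid, window, responsive, odd, even, session="whisker"):
    return {
        "neuron_id": nid,
        "session": session,
        "window": window,
        "n_trials": 20,
        "p_value": 0.01 if responsive else 0.5,
        "responsive": responsive,
        "odd_mean": odd,
        "even_mean": even,
        "all_mean": (odd + even) / 2,
        "selected": bool(responsive and odd > 0),
        "insufficient": False,
    }


def test_crossval_selection_rules():
    records = pd.DataFrame(
        [
            _record(0, "whisker", True, 0.2, 0.15),
            _record(1, "whisker", True, -0.1, 0.2),
            _record(2, "whisker", False, 0.3, 0.3),
        ]
    )
    sel = crossval_select(records)
    assert list(sel["neuron_id"]) == [0]
    assert np.isclose(sel["even_mean"].iloc[0], 0.15)


def test_categorize_preserves_overlaps_and_drops_unselected():
    records = pd.DataFrame(
        [
            _record(0, "whisker", True, 0.2, 0.1),
            _record(0, "matched", True, 0.1, 0.1, session="interleaved"),
            _record(0, "mismatch", True, 0.3, 0.2, session="interleaved"),
            _record(1, "pairing", True, -0.2, 0.1, session="pairing"),
            _record(2, "whisker", False, 0.5, 0.4),
        ]
    )
    cats = categorize(records)
    assert cats[0] == {"whisker", "matched", "mismatch"}
    assert cats[1] == frozenset()
    assert cats[2] == frozenset()
    loose = categorize(records, require_positive=False)
    assert loose[1] == {"pairing"}
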