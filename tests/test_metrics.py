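"""Response probability, population averages, window statistics, overlaps."""

import itertools

import numpy as np
import pytest
from scipy import integrate, stats

from calseq.core import DffTensor, GroundTruth, ValidationError
from calseq.metrics import (
    category_jaccard,
    compare_groups,
    mean_stimulus_response,
    overlap_counts,
    per_neuron_jaccard,
    population_average,
    prestimulus_response,
    response_probability,
    signed_rank_test,
)
from calseq.preprocess import align_trials, compute_dff, sg_smooth
from calseq.responsiveness import rank_sum_test
from calseq.simulate import CalciumKernel, SimConfig, simulate_experiment

from conftest import SMALL_SESSIONS


def _noise_dff(n_neurons, n_trials, n_frames=120, sd=0.05, seed=0, t0=60):
    rng = np.random.default_rng(seed)
    return DffTensor(
        dff=rng.normal(0.0, sd, (n_neurons, n_trials, n_frames)),
        t0_frame=t0,
        frame_rate=30.0,
        trial_ids=np.arange(n_trials),
    )


# ---------------------------------------------------------------------------
# response probability
# ---------------------------------------------------------------------------


def test_response_probability_is_one_at_extreme_snr():
    cfg = SimConfig(
        n_neurons=4,
        session_sizes={**SMALL_SESSIONS, "whisker": 20},
        category_fractions={"whisker": 1.0},
        reliability=1.0,
        amplitude_mu=float(np.log(0.5)),
        amplitude_sigma=0.0,
        noise_sd=0.01,
        drift_amplitude=0.0,
    )
    rec, trials, _ = simulate_experiment(cfg, 6)
    sub = trials.select(session="whisker")
    dff = compute_dff(align_trials(rec, sub, "stim_onset"), sub)
    rp = response_probability(dff, session="whisker")
    assert (rp["probability"] == 1.0).all()
    assert (rp["n_trials"] == 20).all()


def test_response_probability_matches_frame_test_oracle():
    """Dual route: package path vs direct smoothing + rank-sum per trial."""
    dff = _noise_dff(6, 15, seed=3)
    rp = response_probability(dff)
    hits = np.zeros((6, 15), dtype=bool)
    for i, t in itertools.product(range(6), range(15)):
        sm = sg_smooth(dff.dff[i, t], 30.0)
        post, pre = sm[60:90], sm[30:60]
        p = stats.mannwhitneyu(post, pre, alternative="two-sided",
                               method="asymptotic").pvalue
        hits[i, t] = p < 0.05 and np.median(post) > np.median(pre)
    np.testing.assert_array_equal(
        rp["n_responsive_trials"].to_numpy(), hits.sum(axis=1)
    )


def test_response_probability_on_noise_shows_smoothing_anticonservatism():
    """Smoothing correlates adjacent frames, so the per-trial frame test
    fires far above the nominal alpha/2 on pure noise (a property of the
    procedure itself, quantified here)."""
    dff = _noise_dff(40, 50, seed=4)
    rp = response_probability(dff)
    rate = rp["probability"].mean()
    assert 0.08 < rate < 0.35
    assert rp["probability"].between(0, 1).all()


def test_response_probability_recovers_reliability_without_noise():
    """Binomial oracle at reliability 0.35, noise-free transients."""
    reliability = 0.35
    n_neurons, n_trials = 10, 150
    cfg = SimConfig(
        n_neurons=n_neurons,
        session_sizes={**SMALL_SESSIONS, "whisker": n_trials},
        category_fractions={"whisker": 1.0},
        reliability=reliability,
        amplitude_sigma=0.0,
        noise_sd=0.0,
        drift_amplitude=0.0,
    )
    rec, trials, _ = simulate_experiment(cfg, 8)
    sub = trials.select(session="whisker")
    dff = compute_dff(align_trials(rec, sub, "stim_onset"), sub)
    est = response_probability(dff)["probability"].mean()
    se = np.sqrt(reliability * (1 - reliability) / (n_neurons * n_trials))
    assert abs(est - reliability) < 3 * se


def test_response_probability_needs_full_windows():
    with pytest.raises(ValidationError, match="frames"):
        response_probability(_noise_dff(1, 5, n_frames=50, t0=20))


# ---------------------------------------------------------------------------
# population averages
# ---------------------------------------------------------------------------


def test_population_average_sem_zero_for_identical_neurons():
    dff = DffTensor(np.tile(np.linspace(0, 1, 120), (3, 4, 1)), 60, 30.0, np.arange(4))
    pop = population_average(dff, np.arange(3), np.arange(4))
    np.testing.assert_allclose(pop.sem_trace, 0.0, atol=1e-12)


def test_population_average_baseline_mean_is_exactly_zero():
    dff = _noise_dff(20, 10, seed=5)
    pop = population_average(dff, np.arange(20), np.arange(1, 10, 2))
    b0, b1 = pop.baseline
    assert (b0, b1) == (30, 60)
    assert abs(pop.mean_trace[b0:b1].mean()) < 1e-12


def test_population_average_empty_cohort_flagged():
    pop = population_average(_noise_dff(4, 6), np.array([]), np.arange(6))
    assert pop.n_neurons == 0 and np.isnan(pop.mean_trace).all()


def test_population_peak_recovers_planted_amplitude():
    """100 planted responders at amplitude 0.3, default noise: peak within
    10% of the planted value."""
    cfg = SimConfig(
        n_neurons=100,
        session_sizes={**SMALL_SESSIONS, "whisker": 40},
        category_fractions={"whisker": 1.0},
        reliability=1.0,
        amplitude_sigma=0.0,
        drift_amplitude=0.0,
    )
    rec, trials, _ = simulate_experiment(cfg, 9)
    sub = trials.select(session="whisker")
    dff = compute_dff(align_trials(rec, sub, "stim_onset"), sub)
    even = np.arange(1, dff.n_trials, 2)
    pop = population_average(dff, np.arange(100), even)
    assert abs(pop.mean_trace.max() - 0.3) < 0.03


# ---------------------------------------------------------------------------
# mean stimulus response
# ---------------------------------------------------------------------------


def test_mean_stimulus_response_shift_is_noop_for_nonnegative_traces():
    trace = np.zeros(120)
    trace[60:90] = 0.4
    assert np.isclose(mean_stimulus_response(trace, 60, 30.0), 0.4)


def test_mean_stimulus_response_invariant_to_added_constant():
    rng = np.random.default_rng(0)
    trace = rng.normal(0, 0.1, 120)
    a = mean_stimulus_response(trace, 60, 30.0)
    b = mean_stimulus_response(trace - 5.0, 60, 30.0)
    assert np.isclose(a, b)


def test_mean_stimulus_response_exclude_policy():
    trace = np.zeros(120)
    trace[10] = -0.2
    assert np.isnan(mean_stimulus_response(trace, 60, 30.0, min_policy="exclude"))


def test_mean_stimulus_response_matches_kernel_quadrature():
    kernel = CalciumKernel(0.05, 1.0)
    amp = 0.4
    t = (np.arange(240) - 120) / 30.0
    trace = amp * kernel(t)
    expected = amp * integrate.quad(kernel, 0, 1.0)[0]
    assert np.isclose(mean_stimulus_response(trace, 120, 30.0), expected, rtol=0.02)


# ---------------------------------------------------------------------------
# pre-stimulus window
# ---------------------------------------------------------------------------


def test_prestimulus_ramp_value_and_delay_enhancement():
    """Planted 0.2 ramp: 0.05 corrected pre-stimulus mean without delay,
    0.125 with a 1 s delay (ramp spans the delay period)."""
    for delay, expected in ((0.0, 0.05), (1.0, 0.125)):
        cfg = SimConfig(
            n_neurons=2,
            delay=delay,
            session_sizes=dict(SMALL_SESSIONS),
            category_fractions={"ramp": 1.0},
            reliability=0.0,
            noise_sd=0.0,
            drift_amplitude=0.0,
        )
        rec, trials, _ = simulate_experiment(cfg, 3)
        sub = trials.select(trial_type="matched")
        dff = compute_dff(align_trials(rec, sub, "stim_onset"), sub)
        vals = prestimulus_response(dff, sub, np.arange(2))
        np.testing.assert_allclose(vals, expected, atol=0.01)


def test_prestimulus_centred_on_zero_without_ramp():
    cfg = SimConfig(
        n_neurons=30,
        session_sizes=dict(SMALL_SESSIONS),
        category_fractions={},
    )
    rec, trials, _ = simulate_experiment(cfg, 3)
    sub = trials.select(trial_type="matched")
    dff = compute_dff(align_trials(rec, sub, "stim_onset"), sub)
    vals = prestimulus_response(dff, sub, np.arange(30))
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean()) < 4 * se + 1e-4


# ---------------------------------------------------------------------------
# overlaps
# ---------------------------------------------------------------------------


def test_overlap_counts_set_arithmetic():
    out = overlap_counts({"a": {"x", "y"}, "b": {"y", "z"}})
    assert out["categories"] == {"x": 1, "y": 2, "z": 1}
    assert out["pairs"]["x&y"] == 1
    assert out["pairs"]["x&z"] == 0
    assert out["triples"]["x&y&z"] == 0


def test_overlap_counts_disjoint_categories():
    out = overlap_counts({0: {"a"}, 1: {"b"}, 2: {"c"}})
    assert all(v == 0 for v in out["pairs"].values())


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def brute_force_signed_rank(d):
    """Exact two-sided p over all 2^n sign assignments of |d|."""
    d = np.asarray(d, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    n = len(d)
    total = ranks.sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    mean = total / 2
    extreme = sum(1 for w in ws if abs(w - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(ws)


def test_compare_groups_paired_identical_is_one():
    res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
    assert res.p_value == 1.0 and res.test == "signed_rank_paired"


def test_compare_groups_all_positive_differences_exact():
    a = np.arange(1.0, 7.0)
    res = compare_groups(a + 1.0, a, paired=True)
    assert np.isclose(res.p_value, 2 / 2**6)


def test_compare_groups_unpaired_delegates_to_rank_sum():
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
    assert compare_groups(x, y).p_value == rank_sum_test(x, y)


def test_compare_groups_paired_length_mismatch_is_error():
    with pytest.raises(ValidationError, match="equal lengths"):
        compare_groups([1.0], [1.0, 2.0], paired=True)


def test_signed_rank_matches_enumeration_on_random_samples():
    rng = np.random.default_rng(9)
    for n in (4, 5, 6, 7):
        d = rng.permutation(np.arange(1.0, n + 1)) * rng.choice([-1, 1], n)
        assert np.isclose(signed_rank_test(d), brute_force_signed_rank(d))


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def _truth():
    return GroundTruth(
        neuron_ids=np.arange(4),
        categories=[{"whisker"}, {"matched", "ramp"}, set(), {"mismatch"}],
        amplitude=np.array([0.3, 0.4, 0.0, 0.2]),
        reliability=np.array([0.35, 0.35, 0.0, 0.35]),
    )


def test_category_jaccard_scores_detected_membership():
    assignments = {
        0: frozenset({"whisker"}),
        1: frozenset({"matched"}),
        2: frozenset(),
        3: frozenset({"matched", "mismatch"}),
    }
    j = category_jaccard(assignments, _truth())
    assert j["whisker"] == 1.0 and j["mismatch"] == 1.0
    assert np.isclose(j["matched"], 0.5)  # one planted, one spurious
    assert "ramp" not in j  # not a detectable window


def test_per_neuron_jaccard_counts_empty_sets_as_match():
    assignments = {
        0: frozenset({"whisker"}),
        1: frozenset({"matched"}),
        2: frozenset(),
        3: frozenset(),
    }
    assert np.isclose(per_neuron_jaccard(assignments, _truth()), 0.75)
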