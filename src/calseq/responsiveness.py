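"""Shuffle-null responsiveness classification and cross-validated selection.

A neuron's responsiveness to a stimulus window is decided by comparing its
single-trial responses (mean ΔF/F in a 1 s window from stimulus onset
minus the mean in the 1 s baseline window before it) against a null
distribution of 1000 identically computed values at randomly placed
anchors within the same session's trials.  This controls for each neuron's
own noise statistics.  Significance uses a two-sided Mann-Whitney U test
at p < 0.05 with no multiple-testing correction.

Selection is cross-validated: a responsive neuron enters downstream
analyses only if its mean response on odd trials (1st, 3rd, ... in
presentation order) is positive, and all reported statistics then use the
even trials, removing the selection bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DffTensor,
    Recording,
    TrialTable,
    ValidationError,
    WindowSpec,
    frames_for,
    validate_classification,
    window_definitions,
)
from .preprocess import align_trials, compute_dff

__all__ = [
    "NullDistribution",
    "single_trial_responses",
    "build_null",
    "build_null_matrix",
    "rank_sum_test",
    "classify_neuron_session",
    "classify_recording",
    "crossval_select",
    "categorize",
    "MIN_TRIALS",
]

#: fewer trials than this are flagged insufficient rather than tested
MIN_TRIALS = 5

#: primary alignment anchor per session (used for null-window placement)
_SESSION_ANCHOR = {
    "sound": "sound_onset",
    "whisker": "stim_onset",
    "pairing": "stim_onset",
    "interleaved": "stim_onset",
}


@dataclass
class NullDistribution:
    """Baseline-corrected mean ΔF/F at randomly placed windows.

    One null per neuron per session, shared across that session's stimulus
    windows.
    """

    values: np.ndarray
    n_draws: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_draws,):
            raise ValidationError("null length must equal n_draws")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("null contains non-finite values")


def single_trial_responses(
    dff: DffTensor,
    window: WindowSpec = WindowSpec(),
    anchor_frame: int | None = None,
    baseline_gap: int = 0,
) -> np.ndarray:
    """Per-trial response: mean ΔF/F over the 1 s window from the anchor
    minus the mean over the 1 s baseline window before it.

    ``baseline_gap`` shifts the baseline window earlier by that many
    frames.  It is 0 by default (baseline immediately precedes the
    anchor); for sessions with a delay between sound offset and stimulus
    onset the gap equals the delay, so the baseline is the
    sound-presentation window rather than the expectation-contaminated
    delay period.

    Returns an array of shape (neurons, trials).
    """
    rate = dff.frame_rate
    resp_f = window.response_frames(rate)
    base_f = window.baseline_frames(rate)
    a = dff.t0_frame if anchor_frame is None else anchor_frame
    if a - base_f - baseline_gap < 0 or a + resp_f > dff.n_frames:
        raise ValidationError(
            f"response/baseline windows around frame {a} overflow the "
            f"{dff.n_frames}-frame snippet"
        )
    post = dff.dff[:, :, a : a + resp_f].mean(axis=2)
    pre = dff.dff[:, :, a - baseline_gap - base_f : a - baseline_gap].mean(axis=2)
    return post - pre


def build_null_matrix(
    dff: DffTensor,
    n_draws: int,
    rng: np.random.Generator,
    window: WindowSpec = WindowSpec(),
    exclude_stimulus_windows: bool = False,
    baseline_gap: int = 0,
) -> np.ndarray:
    """Null distributions for every neuron of one session at once.

    Each draw picks a uniformly random (trial, anchor frame) pair from the
    session's aligned ΔF/F snippets, with the anchor constrained so both
    the baseline and response windows fit; draws are independent across
    neurons (each neuron gets its own 1000 events, with replacement).
    ``baseline_gap`` mirrors :func:`single_trial_responses` so null events
    use the same window geometry as the statistic they calibrate.

    When ``exclude_stimulus_windows`` is set, anchors whose response or
    baseline window would overlap the true stimulus-response window are
    excluded (sensitivity analysis; the default keeps the literal "random
    events from the same session", which is conservative because planted
    responses inflate the null).

    Returns an array of shape (neurons, n_draws).
    """
    rate = dff.frame_rate
    resp_f = window.response_frames(rate)
    base_f = window.baseline_frames(rate)
    lo, hi = base_f + baseline_gap, dff.n_frames - resp_f  # valid anchors
    if hi < lo:
        raise ValidationError(
            "session snippets too short to place baseline + response windows"
        )
    n, t = dff.n_neurons, dff.n_trials
    if exclude_stimulus_windows:
        t0 = dff.t0_frame
        cand = np.arange(lo, hi + 1)
        # a window pair anchored at a overlaps [t0, t0 + resp_f) iff
        # a - gap - base_f < t0 + resp_f and a + resp_f > t0
        keep = ~((cand - baseline_gap - base_f < t0 + resp_f) & (cand + resp_f > t0))
        cand = cand[keep]
        if len(cand) == 0:
            raise ValidationError("no valid null anchors after exclusion")
        anchors = cand[rng.integers(0, len(cand), size=(n, n_draws))]
    else:
        anchors = rng.integers(lo, hi + 1, size=(n, n_draws))
    trial = rng.integers(0, t, size=(n, n_draws))

    cs = np.cumsum(dff.dff, axis=2)
    cs = np.concatenate([np.zeros((n, t, 1)), cs], axis=2)
    ni = np.arange(n)[:, None]
    post = (cs[ni, trial, anchors + resp_f] - cs[ni, trial, anchors]) / resp_f
    b1 = anchors - baseline_gap
    pre = (cs[ni, trial, b1] - cs[ni, trial, b1 - base_f]) / base_f
    return post - pre


def build_null(
    dff_neuron: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
    frame_rate: float,
    t0_frame: int,
    window: WindowSpec = WindowSpec(),
    exclude_stimulus_windows: bool = False,
    baseline_gap: int = 0,
) -> NullDistribution:
    """Null distribution for a single neuron's session ΔF/F (trials x frames)."""
    dff_neuron = np.asarray(dff_neuron, dtype=float)
    if dff_neuron.ndim != 2:
        raise ValidationError("expected a trials x frames matrix for one neuron")
    tensor = DffTensor(
        dff=dff_neuron[None, :, :],
        t0_frame=t0_frame,
        frame_rate=frame_rate,
        trial_ids=np.arange(dff_neuron.shape[0]),
    )
    values = build_null_matrix(
        tensor, n_draws, rng, window, exclude_stimulus_windows, baseline_gap
    )[0]
    return NullDistribution(values=values, n_draws=n_draws)


def rank_sum_test(x, y) -> float:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) p-value.

    Exact enumeration when the smaller sample has at most 8 values and
    there are no ties; tie-corrected normal approximation otherwise.
    Degenerate input where every value is identical returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test requires non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def classify_neuron_session(
    responses: np.ndarray,
    null: NullDistribution | np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Classify one neuron for one stimulus window.

    Returns a record with the two-sided rank-sum p-value against the null,
    the responsive flag at ``alpha``, odd/even/all-trial mean responses,
    and the cross-validated ``selected`` flag (responsive and positively
    modulated on odd trials).  Fewer than ``MIN_TRIALS`` trials yields an
    insufficient-data flag instead of a test.
    """
    responses = np.asarray(responses, dtype=float)
    null_values = null.values if isinstance(null, NullDistribution) else np.asarray(null)
    n = responses.size
    odd = responses[0::2]  # 1st, 3rd, ... in presentation order
    even = responses[1::2]
    rec = {
        "n_trials": int(n),
        "odd_mean": float(odd.mean()) if odd.size else np.nan,
        "even_mean": float(even.mean()) if even.size else np.nan,
        "all_mean": float(responses.mean()) if n else np.nan,
    }
    if n < MIN_TRIALS:
        rec.update(p_value=np.nan, responsive=False, selected=False, insufficient=True)
        return rec
    p = rank_sum_test(responses, null_values)
    responsive = bool(p < alpha)
    rec.update(
        p_value=p,
        responsive=responsive,
        selected=bool(responsive and rec["odd_mean"] > 0),
        insufficient=False,
    )
    return rec


def classify_recording(
    rec: Recording,
    trials: TrialTable,
    *,
    alpha: float = 0.05,
    n_draws: int = 1000,
    window: WindowSpec = WindowSpec(),
    rng: np.random.Generator | None = None,
    align_pre: float = 4.0,
    align_post: float = 3.0,
    exclude_stimulus_windows: bool = False,
) -> pd.DataFrame:
    """Classify every neuron in every stimulus window of the recording.

    For each session present in the trial table, one null distribution per
    neuron is built from that session's trials and shared across the
    session's stimulus windows (sound onset and offset for the sound
    session; whisker-stimulus onset for whisker, pairing, matched and
    mismatch windows, the mismatch anchor being the scheduled onset of the
    omitted or deviant stimulus).  In sessions with a delay between sound
    offset and stimulus onset, the baseline window of the response
    statistic is the sound-presentation window (shifted back by the
    delay), both for the trials and for the null events.

    Returns a classification table with one row per neuron x window.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    present = trials.sessions_present()
    for session in present:
        sess_trials = trials.select(session=session)
        if len(sess_trials) == 0:
            continue
        delay = float(np.nan_to_num(sess_trials.df["delay_s"].max()))
        gap = frames_for(delay, rec.frame_rate) if delay > 0 else 0
        aligned = align_trials(
            rec, sess_trials, _SESSION_ANCHOR[session], align_pre, align_post
        )
        sess_dff = compute_dff(aligned, sess_trials)
        null = build_null_matrix(
            sess_dff, n_draws, rng, window, exclude_stimulus_windows, gap
        )
        for label, w_session, w_types, w_anchor in window_definitions():
            if w_session != session:
                continue
            sub = sess_trials.select(trial_type=w_types)
            if len(sub) == 0:
                continue
            sub_aligned = align_trials(
                rec, sub, w_anchor.removesuffix("_s"), align_pre, align_post
            )
            sub_dff = compute_dff(sub_aligned, sub)
            responses = single_trial_responses(sub_dff, window, baseline_gap=gap)
            for i in range(rec.n_neurons):
                r = classify_neuron_session(responses[i], null[i], alpha)
                r.update(
                    neuron_id=rec.neuron_ids[i], session=session, window=label
                )
                rows.append(r)
    records = pd.DataFrame(rows)
    cols = [
        "neuron_id",
        "session",
        "window",
        "n_trials",
        "p_value",
        "responsive",
        "odd_mean",
        "even_mean",
        "all_mean",
        "selected",
        "insufficient",
    ]
    records = records[cols]
    return validate_classification(records)


def crossval_select(records: pd.DataFrame) -> pd.DataFrame:
    """Cross-validated selection report: the selected records with their
    even-trial means.

    A record is selected when the neuron is responsive and its odd-trial
    mean response is positive; all downstream metrics then use the
    even-trial means reported here.
    """
    validate_classification(records)
    return records.loc[records["selected"], ["neuron_id", "session", "window", "even_mean"]]


def categorize(records: pd.DataFrame, require_positive: bool = True) -> dict:
    """Per-neuron stimulus-category labels from the classification table.

    Labels are the windows in which the neuron was significantly
    responsive; with ``require_positive`` (default) the label additionally
    requires positive modulation on odd trials, matching the cohorts the
    downstream analyses use.  Labels are not mutually exclusive.
    """
    validate_classification(records)
    flag = "selected" if require_positive else "responsive"
    out: dict = {nid: set() for nid in records["neuron_id"].unique()}
    for _, row in records.loc[records[flag]].iterrows():
        out[row["neuron_id"]].add(row["window"])
    return {k: frozenset(v) for k, v in out.items()}
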