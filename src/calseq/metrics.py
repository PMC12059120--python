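"""Derived response metrics and group statistics.

Response probability counts, per neuron, the fraction of trials (odd and
even) in which the smoothed ΔF/F trace in the 1 s window from stimulus
onset is significantly larger than the 1 s baseline before it (rank-sum
over 30 frames each side at 30 Hz, p < 0.05, post median above pre
median).  Population averages are built from per-neuron even-trial mean
traces, baseline-corrected by the 1 s window before stimulus onset — for
delay sessions, the sound-presentation window.  Group comparisons use the
two-sided Wilcoxon-Mann-Whitney test (unpaired) and Wilcoxon signed-rank
test (paired).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DffTensor,
    GroundTruth,
    TrialTable,
    ValidationError,
    WindowSpec,
    frames_for,
)
from .preprocess import sg_smooth
from .responsiveness import rank_sum_test

__all__ = [
    "ResponseProbabilityRecord",
    "PopulationAverage",
    "StatResult",
    "response_probability",
    "population_average",
    "mean_stimulus_response",
    "prestimulus_response",
    "prestimulus_comparison",
    "overlap_counts",
    "signed_rank_test",
    "compare_groups",
    "category_jaccard",
    "per_neuron_jaccard",
]


@dataclass
class ResponseProbabilityRecord:
    neuron_id: object
    session: str
    n_responsive_trials: int
    n_trials: int

    @property
    def probability(self) -> float:
        return self.n_responsive_trials / self.n_trials


@dataclass
class PopulationAverage:
    """Across-neuron average of per-neuron mean ΔF/F traces.

    Each neuron's mean trace is baseline-corrected (its mean over the
    baseline window subtracted from the entire trace) before averaging, so
    the population mean is exactly zero over the baseline window.
    """

    mean_trace: np.ndarray
    sem_trace: np.ndarray
    n_neurons: int
    baseline: tuple

    def __post_init__(self) -> None:
        if self.n_neurons and np.any(self.sem_trace < 0):
            raise ValidationError("sem must be non-negative")


@dataclass
class StatResult:
    test: str
    p_value: float
    n1: int
    n2: int
    median1: float
    median2: float


def response_probability(
    dff: DffTensor,
    alpha: float = 0.05,
    window: WindowSpec = WindowSpec(),
    sg_window_s: float = 0.150,
    session: str = "",
    neuron_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-neuron response probability over all trials of one stimulus.

    Single-trial traces are Savitzky-Golay smoothed first; a trial counts
    as responsive when the rank-sum comparison of the 30 post-stimulus
    frames against the 30 pre-stimulus frames gives p < ``alpha`` and the
    post-window median exceeds the pre-window median (the directional
    reading of "significantly larger").

    Note: on temporally correlated noise this frame-level test is
    anti-conservative (smoothing alone raises its false-positive rate well
    above alpha); the calibration experiment quantifies this.
    """
    rate = dff.frame_rate
    resp_f = window.response_frames(rate)
    base_f = window.baseline_frames(rate)
    a = dff.t0_frame
    if a - base_f < 0 or a + resp_f > dff.n_frames:
        raise ValidationError(
            f"need {base_f} frames before and {resp_f} after the stimulus"
        )
    sm = sg_smooth(dff.dff, rate, sg_window_s)
    post = sm[:, :, a : a + resp_f]
    pre = sm[:, :, a - base_f : a]
    with warnings.catch_warnings():
        # constant snippets (noise-free simulations) make the tie-corrected
        # variance zero; the median condition already rejects those trials
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.mannwhitneyu(
            post, pre, alternative="two-sided", method="asymptotic", axis=2
        ).pvalue
    hit = (p < alpha) & (np.median(post, axis=2) > np.median(pre, axis=2))
    n_hit = hit.sum(axis=1)
    ids = neuron_ids if neuron_ids is not None else np.arange(dff.n_neurons)
    return pd.DataFrame(
        {
            "neuron_id": ids,
            "session": session,
            "n_responsive_trials": n_hit,
            "n_trials": dff.n_trials,
            "probability": n_hit / dff.n_trials,
        }
    )


def population_average(
    dff: DffTensor,
    neuron_idx: np.ndarray,
    trial_idx: np.ndarray,
    baseline: tuple[int, int] | None = None,
) -> PopulationAverage:
    """Population average of per-neuron mean traces, baseline-corrected.

    ``neuron_idx`` is typically the cross-validation-selected cohort and
    ``trial_idx`` the even trials of the condition.  ``baseline`` is a
    half-open frame interval; by default the 1 s before the alignment
    anchor.
    """
    neuron_idx = np.asarray(neuron_idx, dtype=int)
    trial_idx = np.asarray(trial_idx, dtype=int)
    rate = dff.frame_rate
    if baseline is None:
        baseline = (dff.t0_frame - frames_for(1.0, rate), dff.t0_frame)
    b0, b1 = baseline
    if not (0 <= b0 < b1 <= dff.n_frames):
        raise ValidationError(f"baseline window {baseline} outside snippet")
    if neuron_idx.size == 0:
        empty = np.full(dff.n_frames, np.nan)
        return PopulationAverage(empty, empty, 0, (b0, b1))
    per_neuron = dff.dff[np.ix_(neuron_idx, trial_idx)].mean(axis=1)
    per_neuron = per_neuron - per_neuron[:, b0:b1].mean(axis=1, keepdims=True)
    mean = per_neuron.mean(axis=0)
    if len(neuron_idx) > 1:
        sem = per_neuron.std(axis=0, ddof=1) / np.sqrt(len(neuron_idx))
    else:
        sem = np.zeros(dff.n_frames)
    return PopulationAverage(mean, sem, int(len(neuron_idx)), (b0, b1))


def mean_stimulus_response(
    trace: np.ndarray,
    t0_frame: int,
    frame_rate: float,
    window: WindowSpec = WindowSpec(),
    min_policy: str = "shift",
) -> float:
    """Mean stimulus response of a single-neuron average trace.

    The trace is first raised above zero for its minimum (shifted by
    ``-min`` when the minimum is negative); the response is then the mean
    over the 1 s window from the anchor minus the mean over the 1 s window
    before it.  ``min_policy='exclude'`` instead returns NaN for traces
    with a negative minimum.
    """
    trace = np.asarray(trace, dtype=float)
    if min_policy not in ("shift", "exclude"):
        raise ValidationError(f"unknown min_policy {min_policy!r}")
    m = trace.min()
    if m < 0:
        if min_policy == "exclude":
            return float("nan")
        trace = trace - m
    resp_f = window.response_frames(frame_rate)
    base_f = window.baseline_frames(frame_rate)
    if t0_frame - base_f < 0 or t0_frame + resp_f > trace.size:
        raise ValidationError("response/baseline windows overflow the trace")
    return float(
        trace[t0_frame : t0_frame + resp_f].mean()
        - trace[t0_frame - base_f : t0_frame].mean()
    )


def prestimulus_response(
    dff: DffTensor,
    trials: TrialTable,
    neuron_idx: np.ndarray,
    trial_idx: np.ndarray | None = None,
    window: WindowSpec = WindowSpec(),
) -> np.ndarray:
    """Mean ΔF/F in the 0.5 s window before stimulus onset, per neuron.

    Values are corrected by each trial's sound-presentation window (the
    1 s before stimulus onset when no sound was played, e.g. whisker-only
    trials), which is also the baseline used for delay sessions where the
    sound window no longer abuts the stimulus.
    """
    neuron_idx = np.asarray(neuron_idx, dtype=int)
    df = trials.df
    if trial_idx is None:
        trial_idx = np.arange(len(df))
    trial_idx = np.asarray(trial_idx, dtype=int)
    rate = dff.frame_rate
    pre_f = window.prestim_frames(rate)
    t0 = dff.t0_frame

    vals = np.zeros((len(neuron_idx), len(trial_idx)))
    for j, t in enumerate(trial_idx):
        row = df.iloc[t]
        stim = row["stim_onset_s"]
        if np.isnan(stim):
            raise ValidationError(
                f"trial {row['trial_id']}: no stimulus onset for the "
                "pre-stimulus window"
            )
        if np.isnan(row["sound_onset_s"]):
            b0 = t0 - frames_for(1.0, rate)
            b1 = t0
        else:
            b0 = t0 + int(np.round((row["sound_onset_s"] - stim) * rate))
            b1 = t0 + int(np.round((row["sound_offset_s"] - stim) * rate))
        if b0 < 0 or t0 - pre_f < 0:
            raise ValidationError("baseline window outside snippet")
        base = dff.dff[neuron_idx, t, b0:b1].mean(axis=1)
        pre = dff.dff[neuron_idx, t, t0 - pre_f : t0].mean(axis=1)
        vals[:, j] = pre - base
    return vals.mean(axis=1)


def prestimulus_comparison(
    values_a: dict,
    values_b: dict,
) -> StatResult:
    """Paired comparison of per-neuron pre-stimulus responses between two
    sessions; neurons missing from either side are dropped (logged by the
    caller)."""
    common = sorted(set(values_a) & set(values_b))
    if not common:
        raise ValidationError("no neurons present in both sessions")
    a = np.array([values_a[k] for k in common])
    b = np.array([values_b[k] for k in common])
    return compare_groups(a, b, paired=True)


def overlap_counts(assignments: dict, categories=None) -> dict:
    """Per-category, pairwise and triple overlap counts of label sets."""
    if categories is None:
        categories = sorted({c for s in assignments.values() for c in s})
    out = {
        "categories": {c: 0 for c in categories},
        "pairs": {},
        "triples": {},
    }
    for cats in assignments.values():
        for c in cats:
            if c in out["categories"]:
                out["categories"][c] += 1
    for i, a in enumerate(categories):
        for b in categories[i + 1 :]:
            key = f"{a}&{b}"
            out["pairs"][key] = sum(
                1 for s in assignments.values() if a in s and b in s
            )
            for c in categories[categories.index(b) + 1 :]:
                key3 = f"{a}&{b}&{c}"
                out["triples"][key3] = sum(
                    1 for s in assignments.values() if a in s and b in s and c in s
                )
    return out


def signed_rank_test(x, y=None) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Exact enumeration over sign patterns for small tie-free samples,
    normal approximation otherwise; identical pairs give p = 1.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.size == 0:
        raise ValidationError("signed-rank test requires non-empty samples")
    if np.all(d == 0):
        return 1.0
    nz = d[d != 0]  # zero differences dropped, as in the classic test
    if len(nz) == 1:
        return 1.0  # both sign assignments are equally extreme
    if len(nz) <= 13:
        # exact enumeration of all 2^n sign assignments (valid under ties)
        method = stats.PermutationMethod(n_resamples=2 ** len(nz))
    else:
        method = "approx"
    return float(stats.wilcoxon(nz, alternative="two-sided", method=method).pvalue)


def compare_groups(a, b, paired: bool = False) -> StatResult:
    """Two-sided group comparison.

    Paired data use the Wilcoxon signed-rank test (requires equal
    lengths); unpaired data use the Wilcoxon-Mann-Whitney rank-sum test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValidationError("paired comparison requires equal lengths")
        p = signed_rank_test(a, b)
        test = "signed_rank_paired"
    else:
        p = rank_sum_test(a, b)
        test = "ranksum_unpaired"
    return StatResult(
        test=test,
        p_value=p,
        n1=int(a.size),
        n2=int(b.size),
        median1=float(np.median(a)),
        median2=float(np.median(b)),
    )


# ---------------------------------------------------------------------------
# recovery against planted truth
# ---------------------------------------------------------------------------

#: detected window label -> ground-truth category
_LABEL_TO_TRUTH = {
    "looming": "sound",
    "nonlooming": "sound",
    "looming_offset": "sound_offset",
    "nonlooming_offset": "sound_offset",
    "whisker": "whisker",
    "pairing": "pairing",
    "matched": "matched",
    "mismatch": "mismatch",
}


def _mapped(assignment: frozenset) -> frozenset:
    return frozenset(_LABEL_TO_TRUTH[lab] for lab in assignment)


def category_jaccard(assignments: dict, truth: GroundTruth) -> dict:
    """Jaccard index between detected and planted membership per category.

    Only categories with at least one planted neuron are reported.
    """
    id_to_idx = {nid: i for i, nid in enumerate(truth.neuron_ids)}
    out = {}
    truth_sets = {i: truth.detection_categories(i) for i in range(truth.n_neurons)}
    cats = sorted({c for s in truth_sets.values() for c in s})
    for cat in cats:
        planted = {i for i, s in truth_sets.items() if cat in s}
        detected = {
            id_to_idx[nid]
            for nid, labels in assignments.items()
            if cat in _mapped(labels) and nid in id_to_idx
        }
        union = planted | detected
        out[cat] = len(planted & detected) / len(union) if union else 1.0
    return out


def per_neuron_jaccard(assignments: dict, truth: GroundTruth) -> float:
    """Mean per-neuron Jaccard between detected and planted category sets.

    Neurons with empty sets on both sides count as a perfect match.
    """
    id_to_idx = {nid: i for i, nid in enumerate(truth.neuron_ids)}
    scores = []
    for nid, labels in assignments.items():
        i = id_to_idx[nid]
        det = _mapped(labels)
        tru = truth.detection_categories(i)
        union = det | tru
        scores.append(len(det & tru) / len(union) if union else 1.0)
    return float(np.mean(scores))
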