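"""Trial alignment, per-trial ΔF/F normalisation, and trace smoothing.

ΔF/F is computed per trial as (F - F0)/F0 with F0 the mean fluorescence in
the 1 s window before the trial-start cue, making the measure invariant to
multiplicative rescaling of the raw traces.  Smoothing is a 1st-order
Savitzky-Golay filter over a 150 ms window; it is applied only inside the
per-trial response-probability test and display paths, never before the
shuffle-null classification.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .core import (
    AlignedTensor,
    DffTensor,
    Recording,
    TrialTable,
    ValidationError,
    frames_for,
)

__all__ = ["align_trials", "compute_dff", "sg_smooth", "sg_window_frames"]


def align_trials(
    rec: Recording,
    trials: TrialTable,
    anchor: str = "stim_onset",
    pre: float = 4.0,
    post: float = 3.0,
) -> AlignedTensor:
    """Cut raw-fluorescence snippets around a per-trial anchor event.

    Each snippet covers frames ``[anchor - pre, anchor + post)``; lengths
    convert to frames by round-half-up, so all snippets are equally long
    and the anchor sits at the same index ``t0_frame`` in every one.

    Parameters
    ----------
    anchor
        One of ``stim_onset``, ``sound_onset``, ``sound_offset``,
        ``cue_onset``; every selected trial must carry that event.
    pre, post
        Seconds before/after the anchor.  The default 4 s pre-window
        reaches back past the trial-start cue so the ΔF/F baseline window
        is always inside the snippet.
    """
    col = f"{anchor}_s" if not anchor.endswith("_s") else anchor
    if col not in trials.df.columns:
        raise ValidationError(f"unknown anchor {anchor!r}")
    times = trials.df[col].to_numpy(dtype=float)
    ids = trials.trial_ids
    if np.isnan(times).any():
        bad = ids[np.isnan(times)][0]
        raise ValidationError(f"trial {bad}: anchor {anchor!r} not present")

    rate = rec.frame_rate
    pre_f = frames_for(pre, rate)
    post_f = frames_for(post, rate)
    anchor_frames = np.round(times * rate).astype(int)
    starts = anchor_frames - pre_f
    stops = anchor_frames + post_f
    if (starts < 0).any():
        bad = ids[starts < 0][0]
        raise ValidationError(f"trial {bad}: window starts before the recording")
    if (stops > rec.n_frames).any():
        bad = ids[stops > rec.n_frames][0]
        raise ValidationError(f"trial {bad}: window ends after the recording")

    idx = starts[:, None] + np.arange(pre_f + post_f)[None, :]
    values = rec.fluorescence[:, idx]  # (neurons, trials, frames)
    return AlignedTensor(
        values=values,
        t0_frame=pre_f,
        frame_rate=rate,
        trial_ids=ids,
        anchor=anchor,
        anchor_times_s=times,
    )


def compute_dff(
    aligned: AlignedTensor,
    trials: TrialTable,
    f0_len: float = 1.0,
    eps_scale: float = 1e-6,
) -> DffTensor:
    """Per-trial ΔF/F with F0 = mean F in the 1 s window before the cue.

    Raises a degenerate-baseline error naming the neuron and trial if any
    F0 is at or below ``eps_scale`` times the median fluorescence.
    """
    df = trials.df
    if len(df) != aligned.n_trials:
        raise ValidationError("trial table does not match aligned tensor")
    rate = aligned.frame_rate
    f0_frames = frames_for(f0_len, rate)
    cue = df["cue_onset_s"].to_numpy(dtype=float)
    offsets = aligned.t0_frame + np.round(
        (cue - aligned.anchor_times_s) * rate
    ).astype(int)
    starts = offsets - f0_frames
    if (starts < 0).any() or (offsets > aligned.n_frames).any():
        bad = aligned.trial_ids[(starts < 0) | (offsets > aligned.n_frames)][0]
        raise ValidationError(
            f"trial {bad}: pre-cue baseline window not inside the snippet"
        )

    idx = starts[:, None] + np.arange(f0_frames)[None, :]
    f0 = aligned.values[:, np.arange(aligned.n_trials)[:, None], idx].mean(axis=2)
    eps = eps_scale * np.median(aligned.values)
    bad = f0 <= eps
    if bad.any():
        n, t = np.argwhere(bad)[0]
        raise ValidationError(
            f"degenerate baseline: F0 <= {eps:.3g} for neuron {n}, trial "
            f"{aligned.trial_ids[t]}"
        )
    dff = aligned.values / f0[:, :, None] - 1.0
    return DffTensor(
        dff=dff,
        t0_frame=aligned.t0_frame,
        frame_rate=rate,
        trial_ids=aligned.trial_ids,
    )


def sg_window_frames(window_s: float, frame_rate: float) -> int:
    """Odd frame count for a Savitzky-Golay window of ``window_s`` seconds.

    The exact span rarely lands on an odd frame count (150 ms at 30 Hz is
    4.5 frames), so it is rounded up to the next odd integer (here 5).
    """
    w = int(np.ceil(window_s * frame_rate))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def sg_smooth(
    trace: np.ndarray,
    frame_rate: float,
    window_s: float = 0.150,
    order: int = 1,
) -> np.ndarray:
    """Savitzky-Golay (local least-squares polynomial) smoothing.

    Operates along the last axis.  Edges are handled by fitting the local
    polynomial to the terminal window (``mode="interp"``), which keeps the
    filter exact on polynomial inputs up to ``order`` over the whole
    series and avoids edge transients that would bias window statistics
    near snippet boundaries.  An order-1 filter on a symmetric interior
    window equals a moving average, so linear ramps pass through
    unchanged.
    """
    trace = np.asarray(trace, dtype=float)
    w = sg_window_frames(window_s, frame_rate)
    if trace.shape[-1] <= w:
        raise ValidationError(
            f"series of {trace.shape[-1]} frames shorter than the "
            f"{w}-frame smoothing window"
        )
    return savgol_filter(trace, w, order, axis=-1, mode="interp")
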