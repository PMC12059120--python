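"""Shared data model for trial-based calcium-imaging analysis.

The experiment this package analyses is an auditory-tactile stimulus
sequence: head-fixed animals hear a trial-start cue, then (depending on the
session) a 1 s predictive sound and/or a brief whisker deflection.  Four
session types are presented sequentially within one continuous imaging
block:

* ``sound``       — looming / non-looming sounds alone,
* ``whisker``     — whisker stimulus alone,
* ``pairing``     — looming sound immediately followed by the whisker
                    stimulus,
* ``interleaved`` — matched trials (sound then whisker stimulus) randomly
                    interleaved with mismatch trials where the whisker
                    stimulus is omitted or its intensity deviates.

All timestamps are stored in seconds from recording start and converted to
0-based frame indices exactly once; windows are half-open frame intervals
``[start, end)`` and a window of length ``L`` seconds at rate ``r`` spans
``round(L * r)`` frames (1 s at 30 Hz = 30 frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SESSIONS",
    "TRIAL_TYPES",
    "MISMATCH_TYPES",
    "WINDOW_LABELS",
    "CATEGORIES",
    "TRIAL_COLUMNS",
    "ValidationError",
    "FormatError",
    "frames_for",
    "Recording",
    "TrialTable",
    "WindowSpec",
    "AlignedTensor",
    "DffTensor",
    "GroundTruth",
    "validate_classification",
    "window_definitions",
]

SESSIONS = ("sound", "whisker", "pairing", "interleaved")

MISMATCH_TYPES = ("mismatch_omission", "mismatch_decreased", "mismatch_increased")

TRIAL_TYPES = (
    "sound_looming",
    "sound_nonlooming",
    "whisker_only",
    "paired",
    "matched",
) + MISMATCH_TYPES

#: session each trial type belongs to
_TYPE_SESSION = {
    "sound_looming": "sound",
    "sound_nonlooming": "sound",
    "whisker_only": "whisker",
    "paired": "pairing",
    "matched": "interleaved",
    "mismatch_omission": "interleaved",
    "mismatch_decreased": "interleaved",
    "mismatch_increased": "interleaved",
}

#: stimulus windows tested for responsiveness: label -> (session, trial
#: types, anchor column).  The mismatch anchor is the *scheduled* whisker
#: stimulus onset, which the trial table carries even for omission trials.
_WINDOWS = (
    ("looming", "sound", ("sound_looming",), "sound_onset_s"),
    ("nonlooming", "sound", ("sound_nonlooming",), "sound_onset_s"),
    ("looming_offset", "sound", ("sound_looming",), "sound_offset_s"),
    ("nonlooming_offset", "sound", ("sound_nonlooming",), "sound_offset_s"),
    ("whisker", "whisker", ("whisker_only",), "stim_onset_s"),
    ("pairing", "pairing", ("paired",), "stim_onset_s"),
    ("matched", "interleaved", ("matched",), "stim_onset_s"),
    ("mismatch", "interleaved", MISMATCH_TYPES, "stim_onset_s"),
)

WINDOW_LABELS = tuple(w[0] for w in _WINDOWS)

#: ground-truth categories a simulated neuron may carry.  ``ramp`` marks the
#: pre-stimulus expectation ramp carried by a subset of matched responders.
CATEGORIES = (
    "sound",
    "sound_offset",
    "whisker",
    "pairing",
    "matched",
    "mismatch",
    "ramp",
)

TRIAL_COLUMNS = (
    "trial_id",
    "session",
    "trial_type",
    "cue_onset_s",
    "sound_onset_s",
    "sound_offset_s",
    "stim_onset_s",
    "intensity_pct",
    "delay_s",
)


class ValidationError(ValueError):
    """Input data violates a structural or semantic invariant."""


class FormatError(ValueError):
    """On-disk artifact does not conform to the expected format."""


def frames_for(seconds: float, frame_rate: float) -> int:
    """Number of frames spanned by ``seconds`` at ``frame_rate``.

    Round-half-up, so 1 s at 30 Hz is exactly 30 frames and the rounding of
    half-frame windows does not depend on parity.
    """
    return int(np.floor(seconds * frame_rate + 0.5))


def window_definitions():
    """Stimulus-window table: (label, session, trial_types, anchor column)."""
    return _WINDOWS


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous raw fluorescence for one imaging block.

    ``fluorescence`` holds raw trace values F (arbitrary units), one row per
    neuron.  ``block_id`` labels the block/condition (e.g. ``control`` or
    ``hM4Di+CNO``); the pipeline treats it as an opaque label.
    """

    fluorescence: np.ndarray
    frame_rate: float
    neuron_ids: np.ndarray
    block_id: str = "block0"

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids)
        if self.fluorescence.ndim != 2:
            raise ValidationError("fluorescence must be 2-D (neurons x frames)")
        if not self.frame_rate > 0:
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        if len(self.neuron_ids) != self.fluorescence.shape[0]:
            raise ValidationError(
                f"{len(self.neuron_ids)} neuron_ids for "
                f"{self.fluorescence.shape[0]} trace rows"
            )
        if len(np.unique(self.neuron_ids)) != len(self.neuron_ids):
            raise ValidationError("neuron_ids must be unique")
        bad = ~np.isfinite(self.fluorescence)
        if bad.any():
            n, f = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite fluorescence at neuron {self.neuron_ids[n]}, "
                f"frame {f}"
            )

    @property
    def n_neurons(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


class TrialTable:
    """Validated per-trial annotations.

    Wraps a :class:`pandas.DataFrame` with columns :data:`TRIAL_COLUMNS`.
    Event times are seconds from recording start; absent events (e.g. the
    sound onset of a whisker-only trial) are NaN.  Omission trials carry the
    *scheduled* whisker-stimulus onset with intensity 0.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"trial table missing columns: {missing}")
        df = df[list(TRIAL_COLUMNS)]
        df["trial_id"] = df["trial_id"].astype(int)

        unknown = set(df["session"]) - set(SESSIONS)
        if unknown:
            raise ValidationError(f"unknown session labels: {sorted(unknown)}")
        unknown = set(df["trial_type"]) - set(TRIAL_TYPES)
        if unknown:
            raise ValidationError(f"unknown trial types: {sorted(unknown)}")

        for _, row in df.iterrows():
            expected = _TYPE_SESSION[row["trial_type"]]
            if row["session"] != expected:
                raise ValidationError(
                    f"trial {row['trial_id']}: type {row['trial_type']!r} "
                    f"belongs to session {expected!r}, not {row['session']!r}"
                )

        tid = df["trial_id"].to_numpy()
        if len(np.unique(tid)) != len(tid):
            raise ValidationError("trial_ids must be unique")
        if not np.all(np.diff(tid) > 0):
            raise ValidationError("trial_ids must be strictly increasing")
        cue = df["cue_onset_s"].to_numpy(dtype=float)
        if np.any(~np.isfinite(cue)):
            raise ValidationError("cue_onset_s must be finite for every trial")
        if not np.all(np.diff(cue) > 0):
            raise ValidationError("trials must be strictly increasing in time")

        so = df["sound_onset_s"].to_numpy(dtype=float)
        sf = df["sound_offset_s"].to_numpy(dtype=float)
        st = df["stim_onset_s"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((~np.isnan(so)) & ~(cue < so)):
                raise ValidationError("cue_onset must precede sound_onset")
            if np.any((~np.isnan(so)) & (~np.isnan(sf)) & ~(so < sf)):
                raise ValidationError("sound_onset must precede sound_offset")
            if np.any((~np.isnan(so)) & (~np.isnan(st)) & ~(so < st)):
                raise ValidationError("sound_onset must precede stim_onset")
            if np.any((~np.isnan(st)) & ~(cue < st)):
                raise ValidationError("cue_onset must precede stim_onset")

        omission = df["trial_type"] == "mismatch_omission"
        if omission.any():
            om = df.loc[omission]
            if om["stim_onset_s"].isna().any():
                raise ValidationError(
                    "omission trials must carry the scheduled stim_onset"
                )
            if (om["intensity_pct"] != 0).any():
                bad_id = om.loc[om["intensity_pct"] != 0, "trial_id"].iloc[0]
                raise ValidationError(
                    f"trial {bad_id}: omission trials must have intensity 0"
                )

        # sessions, where present, must form contiguous blocks in the
        # canonical order sound -> whisker -> pairing -> interleaved
        order = {s: i for i, s in enumerate(SESSIONS)}
        ranks = df["session"].map(order).to_numpy()
        if np.any(np.diff(ranks) < 0):
            raise ValidationError(
                "sessions must appear contiguously in the order "
                + " -> ".join(SESSIONS)
            )

        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_trials(self) -> int:
        return len(self.df)

    @property
    def trial_ids(self) -> np.ndarray:
        return self.df["trial_id"].to_numpy()

    def select(
        self,
        session: str | None = None,
        trial_type: str | Sequence[str] | None = None,
    ) -> "TrialTable":
        """Sub-table restricted to a session and/or trial type(s)."""
        mask = np.ones(len(self.df), dtype=bool)
        if session is not None:
            mask &= (self.df["session"] == session).to_numpy()
        if trial_type is not None:
            if isinstance(trial_type, str):
                trial_type = (trial_type,)
            mask &= self.df["trial_type"].isin(trial_type).to_numpy()
        return TrialTable(self.df.loc[mask])

    def sessions_present(self) -> tuple[str, ...]:
        return tuple(s for s in SESSIONS if (self.df["session"] == s).any())

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, TrialTable) and self.df.equals(other.df)


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window lengths (seconds) and the event they anchor to.

    ``response_len``/``baseline_len`` are the 1 s post/pre windows of the
    single-trial response statistic; ``prestim_len`` is the 0.5 s window
    used for the expectation correlate.
    """

    response_len: float = 1.0
    baseline_len: float = 1.0
    prestim_len: float = 0.5
    anchor: str = "stim_onset"

    def __post_init__(self) -> None:
        for name in ("response_len", "baseline_len", "prestim_len"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.anchor not in ("stim_onset", "sound_onset", "sound_offset", "cue_onset"):
            raise ValidationError(f"unknown anchor {self.anchor!r}")

    def response_frames(self, frame_rate: float) -> int:
        return frames_for(self.response_len, frame_rate)

    def baseline_frames(self, frame_rate: float) -> int:
        return frames_for(self.baseline_len, frame_rate)

    def prestim_frames(self, frame_rate: float) -> int:
        return frames_for(self.prestim_len, frame_rate)


@dataclass
class AlignedTensor:
    """Raw fluorescence snippets aligned to a per-trial anchor event.

    ``values`` is neurons x trials x frames; ``t0_frame`` is the index of
    the anchor within every snippet; ``anchor_times_s`` keeps the absolute
    anchor time of each trial so later stages can locate other trial events
    inside the snippet.
    """

    values: np.ndarray
    t0_frame: int
    frame_rate: float
    trial_ids: np.ndarray
    anchor: str
    anchor_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("aligned values must be 3-D")
        if not 0 <= self.t0_frame <= self.values.shape[2]:
            raise ValidationError("t0_frame outside snippet")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]


@dataclass
class DffTensor:
    """Trial-aligned ΔF/F = (F - F0)/F0, neurons x trials x frames.

    F0 is computed per trial as the mean fluorescence in the 1 s window
    before the trial-start cue, so every trial is normalised by its own
    local baseline.
    """

    dff: np.ndarray
    t0_frame: int
    frame_rate: float
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 3:
            raise ValidationError("dff must be 3-D (neurons x trials x frames)")
        if not np.all(np.isfinite(self.dff)):
            raise ValidationError("dff contains non-finite values")
        if len(self.trial_ids) != self.dff.shape[1]:
            raise ValidationError("trial_ids length mismatch")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_trials(self) -> int:
        return self.dff.shape[1]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[2]


@dataclass
class GroundTruth:
    """Planted simulator truth used for recovery benchmarking.

    ``categories`` holds, per neuron, the set of stimulus categories the
    neuron was built to respond to (empty set = non-responder).
    """

    neuron_ids: np.ndarray
    categories: list
    amplitude: np.ndarray
    reliability: np.ndarray

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.reliability = np.asarray(self.reliability, dtype=float)
        self.categories = [frozenset(c) for c in self.categories]
        n = len(self.neuron_ids)
        if not (len(self.categories) == len(self.amplitude) == len(self.reliability) == n):
            raise ValidationError("ground-truth field lengths disagree")
        for cats in self.categories:
            unknown = cats - set(CATEGORIES)
            if unknown:
                raise ValidationError(f"unknown truth categories: {sorted(unknown)}")
        if np.any((self.reliability < 0) | (self.reliability > 1)):
            raise ValidationError("reliability must lie in [0, 1]")
        if np.any(self.amplitude < 0):
            raise ValidationError("amplitude must be >= 0")
        for cats, amp in zip(self.categories, self.amplitude):
            if not cats and amp != 0:
                raise ValidationError("non-responders must have amplitude 0")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    def detection_categories(self, index: int) -> frozenset:
        """Truth categories in the space the classifier can detect.

        ``ramp`` is an expectation signature riding on matched responders,
        not a stimulus window of its own, so it is dropped here.
        """
        return self.categories[index] - {"ramp"}


_CLASSIFICATION_COLUMNS = (
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
)


def validate_classification(records: pd.DataFrame) -> pd.DataFrame:
    """Check a classification table against its structural invariants."""
    missing = [c for c in _CLASSIFICATION_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"classification table missing columns: {missing}")
    p = records["p_value"].to_numpy(dtype=float)
    ok = np.isnan(p) | ((p >= 0) & (p <= 1))
    if not ok.all():
        raise ValidationError("p_value outside [0, 1]")
    if np.isnan(p[~records["insufficient"].to_numpy(bool)]).any():
        raise ValidationError("p_value missing for a tested record")
    sel = records["selected"].to_numpy(bool)
    if np.any(sel & ~records["responsive"].to_numpy(bool)):
        raise ValidationError("selected implies responsive")
    if np.any(sel & ~(records["odd_mean"].to_numpy(float) > 0)):
        raise ValidationError("selected implies odd_mean > 0")
    unknown = set(records["window"]) - set(WINDOW_LABELS)
    if unknown:
        raise ValidationError(f"unknown window labels: {sorted(unknown)}")
    return records
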