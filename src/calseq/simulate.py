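"""Synthetic trial-structured fluorescence recordings with known truth.

The generator emulates the audio-tactile sequence experiment: a sound
session (~25 looming + ~25 non-looming trials), a whisker session (~50
trials), a pairing session (~20 trials of looming sound followed
immediately by the whisker stimulus), and an interleaved session (~120
matched trials randomly interleaved with ~30 mismatch trials).  Each trial
begins with a 2 s baseline followed by a brief trial-start cue; in pairing
and interleaved trials the 1 s predictive sound starts 1 s after the cue
and the whisker stimulus follows at sound offset plus an optional delay.
Trials are 8-9 s long with an irregular 2-5 s inter-trial interval.

The forward model is multiplicative in the baseline fluorescence,

    F(t) = baseline_f * (1 + drift(t)) * (1 + sum of responses) + noise,

so that downstream per-trial ΔF/F normalisation recovers the planted
response exactly in the noise-free case.  Responses are
difference-of-exponential calcium-indicator transients triggered, with
per-trial Bernoulli reliability, at the anchor event of each neuron's
planted category; mismatch responders fire at the *scheduled* whisker
onset of mismatch trials only, and ramp neurons additionally carry a
linear pre-stimulus expectation ramp on matched trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    CATEGORIES,
    GroundTruth,
    MISMATCH_TYPES,
    Recording,
    TrialTable,
    ValidationError,
    _TYPE_SESSION,
)

__all__ = [
    "SimConfig",
    "CalciumKernel",
    "make_trial_schedule",
    "assign_ground_truth",
    "synthesize_traces",
    "simulate_experiment",
]


@dataclass(frozen=True)
class CalciumKernel:
    """Difference-of-exponentials transient, normalised to unit peak.

    k(t) = A * (exp(-t / tau_decay) - exp(-t / tau_rise)) for t >= 0, with
    A chosen so that max_t k(t) = 1.  k(0) = 0 and k decays to 0.  Defaults
    are generic red-indicator kinetics (fast rise, ~1 s decay).
    """

    tau_rise: float = 0.05
    tau_decay: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValidationError("kernel requires tau_decay > tau_rise > 0")

    @property
    def peak_time(self) -> float:
        r, d = self.tau_rise, self.tau_decay
        return r * d / (d - r) * np.log(d / r)

    @property
    def _norm(self) -> float:
        tp = self.peak_time
        return 1.0 / (np.exp(-tp / self.tau_decay) - np.exp(-tp / self.tau_rise))

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        v = self._norm * (np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise))
        return np.where(t >= 0, v, 0.0)

    def sample(self, frame_rate: float, tail: float = 1e-3) -> np.ndarray:
        """Kernel sampled at frame times until the decay falls below ``tail``."""
        t_max = self.tau_decay * np.log(self._norm / tail)
        n = int(np.ceil(t_max * frame_rate)) + 1
        return self(np.arange(n) / frame_rate)


def _default_session_sizes() -> dict:
    return {
        "sound_looming": 25,
        "sound_nonlooming": 25,
        "whisker": 50,
        "pairing": 20,
        "matched": 120,
        "mismatch": 30,
    }


def _default_fractions() -> dict:
    # Emulates the recorded population composition: 39.4% whisker-, 18.5%
    # pairing-, 33.2% matched- (of which a slice carries the expectation
    # ramp) and 8.4% mismatch-responsive neurons, remainder non-responders.
    return {
        "whisker": 0.394,
        "pairing": 0.185,
        "matched": 0.272,
        "ramp": 0.060,
        "mismatch": 0.084,
    }


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions.

    ``category_fractions`` partitions neurons into planted responder
    classes by largest-remainder rounding; the unassigned remainder are
    non-responders.  ``ramp`` neurons are matched responders that also
    carry the pre-stimulus expectation ramp.  ``n_matched_mismatch_overlap``
    neurons from the mismatch class additionally respond on matched trials,
    emulating the observed dual-category cells.
    """

    n_neurons: int = 834
    frame_rate: float = 30.0
    session_sizes: dict = field(default_factory=_default_session_sizes)
    mismatch_mode: str = "omission"
    delay: float = 0.0
    iti_range: tuple = (2.0, 5.0)
    trial_len_range: tuple = (8.0, 9.0)
    kernel_rise: float = 0.05
    kernel_decay: float = 1.0
    category_fractions: dict = field(default_factory=_default_fractions)
    n_matched_mismatch_overlap: int = 7
    amplitude_mu: float = float(np.log(0.3))
    amplitude_sigma: float = 0.5
    reliability: float = 0.35
    noise_sd: float = 0.05
    drift_amplitude: float = 0.02
    drift_period_s: float = 300.0
    baseline_f: float = 100.0
    prestim_ramp_amp: float = 0.2
    session_amp_scale: dict = field(default_factory=dict)
    lead_in_s: float = 10.0
    lead_out_s: float = 10.0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValidationError("n_neurons must be >= 1")
        if self.mismatch_mode not in ("omission", "decreased", "increased"):
            raise ValidationError(f"unknown mismatch_mode {self.mismatch_mode!r}")
        unknown = set(self.category_fractions) - set(CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown categories: {sorted(unknown)}")
        total = sum(self.category_fractions.values())
        if total > 1 + 1e-9:
            raise ValidationError(f"category fractions sum to {total:.3f} > 1")
        if any(f < 0 for f in self.category_fractions.values()):
            raise ValidationError("category fractions must be >= 0")
        if not 0 <= self.reliability <= 1:
            raise ValidationError("reliability must lie in [0, 1]")
        if not self.kernel_decay > self.kernel_rise > 0:
            raise ValidationError("kernel_decay > kernel_rise > 0 required")
        if not self.baseline_f > 0:
            raise ValidationError("baseline_f must be > 0")
        if self.session_sizes.get("mismatch", 0) > 0 and (
            self.session_sizes.get("matched", 0) == 0
        ):
            raise ValidationError(
                "mismatch trials require a nonzero matched count in the "
                "interleaved session"
            )

    @property
    def kernel(self) -> CalciumKernel:
        return CalciumKernel(self.kernel_rise, self.kernel_decay)

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

#: whisker-stimulus intensity (% of maximum) per trial type and mismatch mode
_INTENSITY = {
    "omission": {"matched": 80.0, "mismatch": 0.0},
    "decreased": {"matched": 60.0, "mismatch": 40.0},
    "increased": {"matched": 60.0, "mismatch": 80.0},
}


def make_trial_schedule(config: SimConfig, rng: np.random.Generator) -> TrialTable:
    """Build the per-trial event table for one simulated imaging block.

    Sessions follow the canonical order; sound trial types and the
    matched/mismatch composition of the interleaved session are randomly
    permuted.  Timing within each trial: cue at 2 s after trial start,
    sound onset 1 s after the cue, 1 s sound duration, whisker stimulus at
    sound offset plus ``config.delay``.  Whisker-only trials place the
    stimulus where the paired stimulus would fall (2 s after the cue).
    """
    sz = config.session_sizes
    mm_type = f"mismatch_{config.mismatch_mode}"
    seq: list[str] = []

    sound = ["sound_looming"] * sz.get("sound_looming", 0) + [
        "sound_nonlooming"
    ] * sz.get("sound_nonlooming", 0)
    seq.extend(np.array(sound)[rng.permutation(len(sound))] if sound else [])
    seq.extend(["whisker_only"] * sz.get("whisker", 0))
    seq.extend(["paired"] * sz.get("pairing", 0))
    inter = ["matched"] * sz.get("matched", 0) + [mm_type] * sz.get("mismatch", 0)
    seq.extend(np.array(inter)[rng.permutation(len(inter))] if inter else [])

    inten = _INTENSITY[config.mismatch_mode]
    rows = []
    t = config.lead_in_s
    for i, ttype in enumerate(seq):
        cue = t + 2.0
        sound_on = sound_off = stim = np.nan
        delay = 0.0
        intensity = 0.0
        if ttype in ("sound_looming", "sound_nonlooming"):
            sound_on, sound_off = cue + 1.0, cue + 2.0
        elif ttype == "whisker_only":
            stim = cue + 2.0
            intensity = 80.0
        else:
            sound_on, sound_off = cue + 1.0, cue + 2.0
            delay = config.delay
            stim = sound_off + delay
            if ttype == "paired":
                intensity = 80.0
            elif ttype == "matched":
                intensity = inten["matched"]
            else:
                intensity = inten["mismatch"]
        rows.append(
            {
                "trial_id": i,
                "session": _TYPE_SESSION[ttype],
                "trial_type": ttype,
                "cue_onset_s": cue,
                "sound_onset_s": sound_on,
                "sound_offset_s": sound_off,
                "stim_onset_s": stim,
                "intensity_pct": intensity,
                "delay_s": delay,
            }
        )
        trial_len = rng.uniform(*config.trial_len_range)
        iti = rng.uniform(*config.iti_range)
        t += trial_len + iti
    return TrialTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def largest_remainder_counts(fractions: dict, n: int) -> dict:
    """Integer counts per key summing to round(sum(fractions) * n).

    Each key receives floor(f * n); remaining units go to the largest
    fractional remainders, ties broken by insertion order.
    """
    keys = list(fractions)
    exact = np.array([fractions[k] * n for k in keys])
    base = np.floor(exact).astype(int)
    target = int(np.floor(exact.sum() + 0.5))
    remainder = exact - base
    short = target - base.sum()
    # stable sort: equal remainders keep key order
    order = np.argsort(-remainder, kind="stable")
    for j in order[:short]:
        base[j] += 1
    return dict(zip(keys, base.tolist()))


def assign_ground_truth(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    """Partition neurons into planted categories and draw their amplitudes."""
    n = config.n_neurons
    counts = largest_remainder_counts(config.category_fractions, n)
    perm = rng.permutation(n)
    categories: list[set] = [set() for _ in range(n)]
    pos = 0
    members: dict[str, list[int]] = {}
    for cat, cnt in counts.items():
        idx = perm[pos : pos + cnt]
        members[cat] = sorted(int(i) for i in idx)
        pos += cnt
        for i in idx:
            if cat == "ramp":
                # expectation ramp rides on matched responders
                categories[i].update({"matched", "ramp"})
            else:
                categories[i].add(cat)

    k = min(config.n_matched_mismatch_overlap, len(members.get("mismatch", [])))
    for i in members.get("mismatch", [])[:k]:
        categories[i].add("matched")

    amplitude = np.zeros(n)
    reliability = np.zeros(n)
    responders = [i for i in range(n) if categories[i]]
    amps = np.exp(
        config.amplitude_mu + config.amplitude_sigma * rng.standard_normal(len(responders))
    )
    for i, a in zip(responders, amps):
        amplitude[i] = a
        reliability[i] = config.reliability
    return GroundTruth(
        neuron_ids=np.arange(n),
        categories=categories,
        amplitude=amplitude,
        reliability=reliability,
    )


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

#: planted category -> (trial types, anchor column)
_CATEGORY_ANCHORS = {
    "sound": (("sound_looming", "sound_nonlooming"), "sound_onset_s"),
    "sound_offset": (("sound_looming", "sound_nonlooming"), "sound_offset_s"),
    "whisker": (("whisker_only",), "stim_onset_s"),
    "pairing": (("paired",), "stim_onset_s"),
    "matched": (("matched",), "stim_onset_s"),
    "mismatch": (MISMATCH_TYPES, "stim_onset_s"),
}


def synthesize_traces(
    schedule: TrialTable,
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> Recording:
    """Render the continuous fluorescence matrix for one imaging block."""
    if truth.n_neurons != config.n_neurons:
        raise ValidationError(
            f"ground truth has {truth.n_neurons} neurons, config expects "
            f"{config.n_neurons}"
        )
    rate = config.frame_rate
    df = schedule.df
    end = df[["cue_onset_s", "stim_onset_s", "sound_offset_s"]].max().max()
    n_frames = int(np.ceil((end + config.lead_out_s) * rate))
    tt = np.arange(n_frames) / rate
    if config.drift_amplitude != 0:
        drift = config.drift_amplitude * np.sin(2 * np.pi * tt / config.drift_period_s)
    else:
        drift = np.zeros(n_frames)
    carrier = config.baseline_f * (1.0 + drift)
    kern = config.kernel.sample(rate)

    # per-category anchor frames and session scale, shared by all neurons
    anchors: dict[str, np.ndarray] = {}
    for cat, (types, col) in _CATEGORY_ANCHORS.items():
        sub = df[df["trial_type"].isin(types)]
        times = sub[col].to_numpy(dtype=float)
        frames = np.round(times[~np.isnan(times)] * rate).astype(int)
        anchors[cat] = frames

    matched = df[df["trial_type"] == "matched"]
    ramp_spans = [
        (
            int(np.round(r["sound_onset_s"] * rate)),
            int(np.round(r["stim_onset_s"] * rate)),
        )
        for _, r in matched.iterrows()
    ]

    F = np.empty((config.n_neurons, n_frames))
    for i in range(config.n_neurons):
        resp = np.zeros(n_frames)
        cats = truth.categories[i]
        amp = truth.amplitude[i]
        rel = truth.reliability[i]
        for cat in sorted(cats):
            if cat == "ramp":
                continue
            fr = anchors[cat]
            if len(fr) == 0:
                continue
            hits = rng.random(len(fr)) < rel
            scale = config.session_amp_scale.get(cat, 1.0)
            for f0 in fr[hits]:
                hi = min(n_frames, f0 + len(kern))
                resp[f0:hi] += amp * scale * kern[: hi - f0]
        if "ramp" in cats:
            for f0, f1 in ramp_spans:
                span = f1 - f0
                resp[f0:f1] += config.prestim_ramp_amp * np.arange(span) / span
                # decay back with the indicator kinetics after the peak
                hi = min(n_frames, f1 + len(kern))
                tail = np.exp(-np.arange(hi - f1) / (config.kernel_decay * rate))
                resp[f1:hi] += config.prestim_ramp_amp * tail
        noise = (
            rng.normal(0.0, config.noise_sd * config.baseline_f, n_frames)
            if config.noise_sd > 0
            else 0.0
        )
        F[i] = carrier * (1.0 + resp) + noise
    return Recording(F, rate, np.arange(config.n_neurons), "synthetic")


def simulate_experiment(
    config: SimConfig, seed: int
) -> tuple[Recording, TrialTable, GroundTruth]:
    """Generate one full synthetic imaging block.

    The seed is expanded into independent substreams for the schedule, the
    ground-truth assignment, and the trace rendering, so each stage is
    individually reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_sched, s_truth, s_trace = ss.spawn(3)
    schedule = make_trial_schedule(config, np.random.default_rng(s_sched))
    truth = assign_ground_truth(config, np.random.default_rng(s_truth))
    rec = synthesize_traces(schedule, truth, config, np.random.default_rng(s_trace))
    return rec, schedule, truth
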