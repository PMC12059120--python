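# Methods

## Data model

A *recording* is one continuous fluorescence matrix F (neurons × frames,
arbitrary units) for one imaging block, with a frame rate (default
30 Hz). A *trial table* annotates each trial with its session (`sound`,
`whisker`, `pairing`, `interleaved`), trial type, event times in seconds
(trial-start cue, sound onset/offset, whisker-stimulus onset), stimulus
intensity, and the sound-to-stimulus delay. Omission trials carry the
*scheduled* stimulus onset with intensity 0 — the analysis treats the
omission window exactly like a stimulus window. Sessions are contiguous
trial ranges of a single recording, in the order sound → whisker →
pairing → interleaved.

Times are converted to 0-based frame indices once; windows are half-open
frame intervals, and a window of length L seconds spans round(L·r)
frames at rate r (1 s at 30 Hz = 30 frames).

## ΔF/F

ΔF/F = (F − F₀)/F₀ per trial, with F₀ the mean fluorescence in the 1 s
window before the trial-start cue. The per-trial baseline makes the
measure exactly invariant to per-neuron multiplicative rescaling (a
tested identity) and robust to slow drift. F₀ at or below 10⁻⁶ × median
F raises a degenerate-baseline error naming neuron and trial.

## Shuffle-null responsiveness

The single-trial response for a stimulus window is the mean ΔF/F over
[t, t+1 s) minus the mean over the 1 s baseline window before it, where
t is the anchor event (sound onset, sound offset, or actual/scheduled
whisker-stimulus onset). In sessions with a nonzero sound-to-stimulus
delay the baseline window is the sound-presentation window, i.e. shifted
back by the delay; this keeps the expectation-related activity of the
delay period out of the baseline and is applied identically to the null
events. Without this shift, planted ramp-carrying responders lose their
own stimulus response into the baseline (in development, ramp-neuron
recovery in 1 s-delay sessions fell from 24/24 to 9/24).

The null distribution per neuron and session is 1000 single-trial
responses computed at uniformly random (trial, anchor-frame) pairs
within the session's aligned snippets, drawn with replacement,
independently per neuron, with stimulus windows *included* (the literal
"random events from the same session"; inclusion inflates the null of a
truly responsive neuron and is therefore conservative). A flag excludes
stimulus-overlapping anchors for sensitivity analyses. One null is
shared across a session's stimulus windows.

A neuron is *responsive* in a window when the two-sided
Wilcoxon–Mann–Whitney test of its single-trial responses against the
null gives p < 0.05 (no multiple-testing correction, matching the
original procedure). Windows with fewer than 5 trials are flagged
insufficient instead of tested. Rank-sum p-values use exact enumeration
when the smaller sample has ≤ 8 tie-free values and the tie-corrected
normal approximation otherwise; signed-rank p-values use exact sign-flip
permutation up to n = 13 (valid under tied magnitudes) and the normal
approximation beyond.

### Calibration and its limits

On pure-noise cohorts the shuffle test is calibrated: the responsive
fraction lands in the binomial 99% band around α = 0.05 (measured 0.054
on 1000 neurons × 50 trials). The flip side of the uncorrected α is that
every neuron has ≈ α/2 probability per window of being spuriously
*selected* (significant and positive on odd trials). This bounds
category-recovery scores: for a category with T planted members out of N
neurons, the expected Jaccard against truth cannot exceed roughly
T/(T + 0.025·(N−T)) even at perfect sensitivity. At the recorded-like
composition (834 neurons, 8.4% mismatch) this cap is ≈ 0.79 for
mismatch, and the 20-trial pairing session at reliability 0.35 is
additionally power-limited (P(Binom(20, 0.35) ≥ 6) ≈ 0.75): measured
per-category Jaccards are whisker 0.92, matched 0.93, pairing 0.73,
mismatch 0.74, while the per-neuron category-set Jaccard averages 0.86.
These are properties of the α = 0.05 design itself, not of the
implementation, and are reported as measured.

## Cross-validated selection

Selection for downstream analysis requires responsiveness and a positive
mean response on odd trials (1st, 3rd, … in presentation order); all
reported statistics then use even trials. The bias-removal this buys is
specific to the odd-positivity step: on pure noise, neurons chosen by
odd positivity alone have even-trial means exactly centred on zero
(measured z = 1.2) while their odd means are strongly positive
(z ≈ 28). The *full* selection rule retains a small positive even-trial
bias on noise (≈ +0.003 ΔF/F at these noise levels, z ≈ 4) because the
responsiveness test itself uses all trials — a subtle property of the
published procedure worth knowing when interpreting near-zero population
responses.

## Response probability

Per trial, the single-trial trace is smoothed with a 1st-order
Savitzky–Golay filter over a 150 ms window (4.5 frames at 30 Hz, rounded
up to the odd 5; edges handled by polynomial fitting, which keeps the
order-1 filter exact on linear inputs). A trial counts as responsive
when the rank-sum comparison of the 30 post-stimulus frames against the
30 pre-stimulus frames gives p < 0.05 *and* the post-window median
exceeds the pre-window median (the directional reading of
"significantly larger" with a two-sided test). The probability is the
responsive fraction over all trials, odd and even.

Known limitation: smoothing correlates adjacent frames, and the
frame-level rank-sum test ignores that autocorrelation. On pure Gaussian
noise the one-directional false-positive rate is ≈ 0.19 per trial
(≈ 0.023 without smoothing), so on noisy data the probability estimate
is biased upward by roughly 0.19·(1 − true rate). The reliability-grid
validation therefore uses noise-free planted transients, which isolate
the Bernoulli counting (recovered within the binomial 99% CI at
reliabilities 0.1/0.35/0.8), and the anti-conservatism itself is pinned
by a separate calibration test. Smoothing is applied only inside this
per-trial test and display paths, never before the shuffle-null
classification.

## Population statistics

Population averages are means across the selected cohort of per-neuron
even-trial mean traces, each baseline-corrected by subtracting its mean
over the 1 s window before stimulus onset (the sound-presentation window
in delay sessions); the corrected population baseline mean is exactly
zero. SEM is across neurons. Mean stimulus responses raise each
per-neuron average trace above zero by its minimum (shift policy;
exclusion of negative-minimum traces is available behind a flag) before
taking the post-minus-pre window difference — the difference itself is
invariant to the shift. The pre-stimulus expectation correlate is the
mean ΔF/F in the 0.5 s before (scheduled) stimulus onset, corrected by
the sound-window baseline, compared across sessions per neuron with the
two-sided Wilcoxon signed-rank test (neurons missing from a session are
dropped from the pair, logged). Category labels may overlap; overlap
counts report per-category, pairwise and triple intersections.

## Synthetic data

The generator renders F(t) = baseline·(1 + drift)·(1 + Σ responses) +
noise. The multiplicative response model makes ΔF/F recover the planted
response exactly in the noise-free limit, which is what turns the exact
identities above into testable properties. Components:

* **Transients** — difference-of-exponentials kernel k(t) ∝
  e^(−t/τ_decay) − e^(−t/τ_rise), unit peak, τ_rise = 50 ms,
  τ_decay = 1 s (generic red-indicator kinetics; configurable).
* **Categories** — neurons are partitioned by largest-remainder rounding
  of configurable fractions; defaults emulate the recorded composition
  (39.4% whisker, 18.5% pairing, 33.2% matched of which 6% carry the
  expectation ramp, 8.4% mismatch; remainder non-responders), with 7
  dual matched∩mismatch neurons. Mismatch responders fire only at the
  scheduled onset on mismatch trials; whisker/pairing/matched responders
  fire only in their own session's trials.
* **Reliability and amplitude** — each responder fires on a trial with
  Bernoulli probability 0.35 (emulating reported ~32–37% response
  probabilities) at its per-neuron amplitude, drawn lognormal(log 0.3,
  0.5) across neurons.
* **Expectation ramp** — ramp carriers add, on every matched trial, a
  linear ΔF/F ramp from sound onset to the scheduled stimulus onset
  peaking at 0.2, decaying with the kernel after the peak. With a 1 s
  delay the ramp spans the delay period, so the 0.5 s pre-stimulus mean
  grows from 0.05 to 0.125 (both exact, noise-free) — the
  prolonged-and-enhanced expectation signature.
* **Noise and drift** — white Gaussian noise (sd 5% of baseline) and a
  2% sinusoidal drift with a 300 s period.
* **Timing** — 2 s pre-cue baseline, sound 1 s after the cue, 1 s sound,
  stimulus at sound offset plus the configured delay (whisker-only
  trials place the stimulus 2 s after the cue, where the paired stimulus
  would fall), trials 8–9 s, inter-trial intervals uniform 2–5 s.

What the generator does **not** emulate: spiking or calcium biophysics
beyond the kernel, motion artifacts, neuropil contamination, whisker
movement, or cross-session suppression of responders (a per-session
amplitude-scale map exists but is unset by default). Passing recovery
tests therefore demonstrates the statistics under the stated forward
model, not robustness to those real-data confounds.

## Determinism and problem sizes

Every stochastic step takes an explicit seed or generator; the pipeline
expands one global seed into independent substreams per condition and
stage, so reruns are byte-identical (asserted). Validation experiments
use 1000 neurons × 50 trials (calibration), 834 neurons × 270 trials
(recovery, the recorded-population scale), 40 neurons × 150 trials per
reliability grid point, and 250 neurons with 50 ramp carriers
(expectation); the full validation battery completes in about a minute
on one core.
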