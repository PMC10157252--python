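# Methods

`tuspac` analyses single-channel hippocampal CA1 local field potentials
(LFPs, 1 kHz sampling) recorded around low-intensity transcranial
ultrasound stimulation (TUS) under three behavioral states — anesthesia,
awake (head-fixed), and running — and ships a calibrated synthetic-LFP
generator so the whole chain can be exercised and validated without
in-vivo recordings.

## Stimulation model and dosimetry

The stimulus is a pulsed burst: 2.25 MHz carrier, 1 kHz pulse repetition
frequency (PRF), 50% duty cycle, 400 ms per trial, 16 trials per session.
Because the analysis operates on 1 kHz LFP data, the MHz carrier is never
synthesized at sample level; the stimulus is represented by its pulse
envelope plus timing and dose metadata — only timing and dose enter the
analysis. Dose is the plane-wave spatial-peak pulse-average intensity
Isppa = p² / (2Z). The characteristic impedance defaults to
Z = 1.5 × 10⁶ Pa·s/m (water/soft tissue), which maps the five stimulation
pressures 0.15–0.75 MPa exactly onto 0.75–18.75 W/cm²; Z is overridable in
the medium object. The inter-trial interval defaults to 15 s with a hard
floor of 10 s so the ±5 s peristimulus analysis windows of consecutive
trials can never overlap.

## Band-power analysis

Each trial is split into ten contiguous 1-s segments spanning [−5, 5) s
around onset (half-open intervals, onset rounded to the nearest sample).
Per segment a Welch PSD is estimated — Hann window, 500 samples, 50%
overlap, i.e. three averaged half-overlapping windows and 2 Hz resolution
inside a 1-s segment; all three parameters are configurable. Per-segment
PSDs are averaged across the 16 trials *before* band-power extraction
(trial-averaged spectrum); a per-trial-then-average mode is available as a
flag.

Absolute band power (AP) is the **mean** spectral density over the in-band
bins (units mV²/Hz), with band edges inclusive: theta 4–12 Hz, gamma
30–45 Hz, total 4–100 Hz. Relative power is RP = AP_band / AP_total; with
the mean-density convention, RP values of disjoint sub-bands do not sum
to 1. Stimulus effects are baseline-normalised: the baseline is the
arithmetic mean over the five pre-stimulus segments, and
ΔAP/AP = (AP_t − AP_baseline)/AP_baseline per post segment (ΔRP/RP
analogously). Per-animal values are trial-averaged; group summaries are
mean ± SEM (SEM = sd/√N, undefined below N = 2).

The time-frequency picture uses generalized Morse wavelets with symmetry
γ = 3 and time-bandwidth P² = 60 (decay exponent β = P²/γ = 20), realised
in the frequency domain as Ψ(ω) ∝ ω^β e^(−ω^γ) for ω > 0, normalised to
peak value 2 and evaluated on a log-spaced 2–100 Hz grid of 60 voices.
Morse voices are constant-Q, so the raw time-averaged magnitude-squared of
a broadband process rises ∝ f relative to its density;
`morse_density_profile` divides each voice by its equivalent noise
bandwidth to make the profile comparable to a Welch PSD.

## Phase–amplitude coupling

The coupling chain: band-pass the LFP in theta and take the Hilbert phase
φ_l; band-pass in gamma, take the Hilbert amplitude envelope, band-pass the
envelope in the *same* theta band, and take its phase φ_h. The index is
the phase-locking value PACI = |K⁻¹ Σ_k exp(i(φ_l[k] − φ_h[k]))| ∈ [0, 1],
computed as the mean over all K available samples. It is invariant to
overall amplitude scaling.

Filters are windowed-sinc FIRs (Hamming window, odd tap count
⌈3.3·fs/Δf⌉, transition width Δf = 2 Hz for theta, 5 Hz for gamma),
applied forward–backward so the net response has zero phase lag and
squared magnitude. The low-frequency extraction is a 4–12 Hz *band-pass*
rather than a plain low-pass: the phase of a signal containing DC is
ill-defined.

Filtering and phase extraction run once over the continuous recording —
not per segment — to avoid filter edge artifacts; phases are then sampled
inside per-trial windows, with 0.5 s trimmed from each window edge to keep
the stimulus-onset amplitude transient of the envelope filter out of the
estimate.

**Estimator floor and window design.** For uncoupled streams the expected
PACI is not zero but ≈ √(π/(4·K_eff)), where K_eff ≈ T·B is the number of
effectively independent phase samples in a window of length T for a band
of width B (~8 Hz for theta). Two design choices follow:

* Pre- and post-stimulus windows default to the *same* length
  (pre [−2, 0) s, post [0, 2) s), so the floor cancels in the relative
  change ΔPAC/PAC = (PACI_post − PACI_pre)/PACI_pre; unequal windows would
  masquerade as a stimulus effect under the null.
* The per-animal statistic pools trials at the resultant level: the complex
  resultants of all 16 trials' window samples are summed before taking the
  modulus. This lowers the floor by √16 relative to averaging per-trial
  indices (with 16 × 1 s effective windows the floor is ≈ 0.08) and is the
  only way weak coupling (modulation depth ~0.02, the anesthesia regime)
  is detectable above it. Per-trial indices are also returned. The same
  reasoning sets the 120-s window length of the Monte-Carlo null check in
  the acceptance suite: at 10 s the floor itself is ≈ 0.10, so a <0.1
  bound is uninformative there; 120 s puts the floor at ≈ 0.04, safely
  under the bound.

A circular-shift surrogate null (envelope-phase stream shifted by random
offsets ≥ 1 s, ≥ 19 surrogates) is provided for per-recording significance;
the state comparisons themselves contrast conditions, not surrogates.

## Group statistics

The statistical unit is the per-animal, trial-aggregated value (N = 7 per
state by design). States are compared with the tie-corrected
Kruskal–Wallis H (chi-square approximation, df = k−1); all-identical
pooled values return H = 0, p = 1 flagged rather than an error. Post-hoc
localisation defaults to Dunn's z-test on the joint ranks with Holm
adjustment (MATLAB's default after `kruskalwallis` is Tukey–Kramer on mean
ranks; Dunn + Holm is chosen for transparency, with Dunn–Bonferroni and
rank-sum–Bonferroni selectable). No correction is applied across time
bins, matching the per-bin presentation of the results. Significance is
p < 0.05 with star codes * / ** / *** at 0.05 / 0.01 / 0.001 (strict).

Note a rank-test floor: with n = 3 per group no pairwise rank procedure
can reach p < 0.05 for the middle-vs-adjacent pairs (the most extreme rank
configuration gives Dunn z ≈ 1.41); fully separated groups need n ≈ 10
before every Holm-adjusted pair clears α = 0.05.

## Synthetic LFP generator

The generator produces what the analysis assumes, not a biophysical CA1
model:

* **Background**: 1/f^α Gaussian noise (α = 1 by default, flat below
  1 Hz), shaped in the frequency domain and rescaled so the realised
  variance equals `noise_scale` (mV²) exactly.
* **Rhythms**: a theta tone at 8 Hz and a gamma carrier at 40 Hz whose
  envelope is amplitude-modulated by the theta phase (Tort-style
  construction), x = A_θcos(φ_θ) + A_γ[1 + m·cos(φ_θ − φ₀)]cos(2πf_γt+ψ).
  Amplitudes are set analytically so the Welch band powers of the
  rhythm-only signal match the per-state baselines: theta
  0.7 / 10.5 / 19.9 mV²/Hz for anesthesia / awake / running, gamma 0.3 ×
  theta by default. Modulation depths m = 0.02 / 0.15 / 0.35 reproduce the
  weak-to-strong baseline coupling ordering of the three states. Optional
  Ornstein–Uhlenbeck frequency jitter is off by default so oracles stay
  analytic.
* **Stimulus effects**: inside [onset, onset + 2 s) — matching the
  observation that effects are confined to ~2 s — theta and gamma
  amplitudes are scaled by √gain with per-1-s-bin constant power gains, and
  m is scaled by a state-specific depth gain. Gains are calibrated so the
  measured ΔAP/AP lands on the in-vivo group means (gain g reads out as
  g − 1 up to a few percent background dilution): theta 0–1 s gains
  5.6 / 3.7 / 1.07, 1–2 s 3.1 / 4.0 / 1.3; gamma 0–1 s 4.1 / 2.7 / 1.3
  (the 1–2 s gamma gains 2.4 / 2.2 / 1.2 are the package's own choice —
  no printed value exists for that bin — decaying like the theta effect).
  Depth gains 1.45 / 1.3 / 0.6 strengthen coupling under anesthesia and
  awake and weaken it under running.
* **Dose response**: each excess gain is tilted linearly in the normalised
  pressure offset x = (p − 0.45)/0.45 with a signed per-state sensitivity
  κ, g(p) = 1 + (g_ref − 1)(1 + κx). The sign pattern encodes the
  dose-response directions: under anesthesia theta relative power falls
  and gamma relative power and coupling rise with intensity; awake is the
  mirror image; running rises in theta, with coupling falling.
* **Seeds**: one master seed per session, split deterministically
  (`numpy.random.SeedSequence`) into background and rhythm-phase streams;
  identical seeds give bit-identical sessions.

`noise_scale` defaults to 4 × the state's theta baseline power
(numerically, in mV²). This keeps in-band dilution of the rhythms at the
few-percent level (so power gains still read out as g − 1) while providing
enough envelope noise that the coupling estimator operates in its
sensitive, unsaturated range in every state — with much weaker noise the
running state's strong coupling saturates PACI near 1 and the stimulus
effect on coupling becomes invisible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: broadband (non-sinusoidal) rhythms with drifting
frequency and waveform asymmetry, non-stationary state changes within a
session, movement and line-noise artifacts, electrode drift, the auditory
confound of ultrasound stimulation, and any biophysics linking dose to
effect. Recovery of the signed effect pattern demonstrates that the
analysis chain is correct and sensitive at realistic SNR, not that the
in-vivo findings are reproduced.

## Numerical choices and degenerate inputs

* Sample indexing is 0-based; onsets round to the nearest sample; all
  intervals are half-open [a, b).
* Zero-phase filtering extends the signal by odd reflection (3 × taps) and
  requires signals longer than 3 × taps (≈ 5 s for the theta filter at
  1 kHz).
* The analytic signal is computed with an FFT length padded to the next
  fast size and truncated back.
* A near-constant gamma envelope (no in-band amplitude variation, ripple
  below 10⁻³ of the envelope mean on the central 80% of samples) flags the
  PAC estimate as degenerate rather than erroring: its phase is then
  noise, and the index is a null reading.
* Zero total power, zero baselines, and empty bands raise errors naming
  the offending quantity; identical groups in the rank tests degrade to
  H = 0, p = 1 with a flag.
* EDF files are written as 16-bit with the physical range set per channel
  from the data extrema; round trips are exact to one quantum
  (range/65535). The final data record is zero-padded to a whole second.

## Problem sizes in the validation suite

The acceptance checks run the full in-vivo design — 3 states × 7 animals ×
16 trials (≈ 250 s of signal per animal) — across 10 master seeds for the
effect-pattern recovery, and a 5-pressure dose sweep at 3 animals per
state across 10 seeds (trend directions are group-mean properties and are
already stable at that size). Monte-Carlo calibrations of the rank tests
use 5000 direct null replicates; pipeline-level type-I/power checks
resample group assignments from a pool of per-animal statistics generated
once (the per-animal statistic is iid under identical profiles), rather
than simulating thousands of cohorts.
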