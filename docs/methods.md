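# Methods

This note documents the models, conventions and numerical choices behind
`oblfp`, in the order data flows through the package.

## Task and data model

A *session* is one go/no-go run: a mouse enters an odor port, the odorant
(S+ rewarded or S− unrewarded) arrives at a uniformly random delay of
1–1.5 s after port entry and lasts 2.5 s. The mouse reports by licking: a
trial counts as a *response* iff each of the four consecutive 0.5 s
intervals from odorant onset contains at least one lick. Outcomes partition
trials into Hit/Miss (S+) and FA/CR (S−). Sessions are scored in 20-trial
blocks of 10 S+ and 10 S− in random order; a mouse is *proficient* once at
least two sessions end at ≥ 80% correct over their final 40 trials.

All event times live on the continuous LFP clock; the on-disk format
(JSON + CSV + little-endian float32 binary with a self-describing sidecar)
round-trips bit-exactly. Percent-correct curves use a trailing 20-trial
window (a per-trial analog of the block score; a disjoint block summary is
also exposed). The window orientation is a convention — a centered window
would shift curves by half a window.

## Spectral analysis and Δ power

Power is estimated with a sliding 1 s Hann-tapered short-time PSD (1 Hz
resolution), converted to dB with a −120 dB floor so silent channels stay
finite. The window step defaults to 0.1 s in the single-trial operation;
the batched session tables use 0.25 s, which changes band Δ power by
~0.01 dB while cutting compute 6-fold (any step ≤ 0.25 s is equivalent at
the tolerances used anywhere in the package). Inputs sampled above
~1.2 kHz are decimated (anti-aliased) to 1 kHz first; every analysis band
lies below 100 Hz.

Δ power per (trial, electrode, band) is the dB-scale mean over time-bins
whose window *centers* fall in [onset, onset + 2 s) and frequency bins
inside the band, minus the same mean over [onset − 2.1, onset − 0.6 s).
Averaging on the dB scale is the default (linear averaging is a flag).
Two consequences worth knowing:

* windows centered near the onset straddle the power step, so a true
  +6.02 dB amplitude doubling is recovered as ≈ +5.7–5.8 dB — the smearing
  is a property of the center-inclusion rule, identical for all conditions,
  and irrelevant to rank-based statistics downstream;
* the baseline window ends 0.6 s before onset precisely so that no
  baseline window overlaps odorant-evoked signal.

Band-pass filtering anywhere in the package (including the theta filter
used for lick phases) is zero-phase (forward–backward Butterworth, order
4), because filter group delay would corrupt event–phase relationships.

## ROC classification

The centered auROC is computed from midranks, `([rank-sum U] − n₊n₋/2) /
(n₊n₋)`, which makes label-swap antisymmetry exact in floating point —
the mechanism behind the reward-reversal polarity result. Significance
against zero uses a two-sided z-test with the Hanley–McNeil variance of
the uncentered area evaluated at the observed area; at the null this
matches the exact U-statistic variance and away from it it is mildly
conservative. Calibration is tied to a label-permutation reference in the
tests rather than to any particular closed form. FDR correction is the
Benjamini–Hochberg step-up, reported with pFDR (the largest p declared
significant); families default to all electrodes of one band within one
condition, and family composition is always visible in the outputs because
the per-figure pFDR depends on it. d′ normalization divides Δ power by the
unweighted mean of the per-class standard deviations (scale-invariant by
construction).

## Resampling statistics

The permutation ANOVA shuffles raw values across groups (10⁴ shuffles by
default, seeded, vectorized) and applies the add-one rule, so p ∈
[1/(B+1), 1] and the test is valid under exchangeability; exhaustive
enumeration is available for small two-group designs and is exact. A
residual-shuffle mode exists for the two-way interaction. The genotype ×
laser interaction is the type-II two-way fixed-effects ANOVA term
(statsmodels); observations are per-electrode values pooled across mice,
following field practice for chronic multi-electrode recordings — this
pseudoreplicates when electrode values share within-session noise, which
is why the synthetic generator draws trial noise independently per
electrode (below) and why a real-data user should prefer the per-mouse
aggregation the API allows.

## Lick-aligned LFP

Lick-onset detection takes a continuous contact signal (half-range
threshold, rising edge, 70 ms debounce) or an event list. The lick-related
LFP (LR-LFP) is the mean LFP in ±0.5 s around lick onsets with a
percentile bootstrap CI over licks (1000 replicates, seeded). The theta
phase of an event is the analytic-signal angle of the zero-phase 6–12 Hz
filtered LFP at the event sample, with phase 0 at the oscillation peak and
increasing in time — phase histograms are only comparable under a stated
convention.

LR-LFP Δ power is the largest interpretive construction in the package:
per trial, the event-locked average over licks in the 2 s odorant window
is built over ±1 s, its sliding 1 s spectrogram evaluated at a requested
lag from lick onset (0.3 s is the anchored value), and the same quantity
computed from *surrogate* alignment events in the pre-odorant baseline is
subtracted. Surrogates are placed at theta phases drawn from the trial's
own lick-phase distribution (theta peaks when the trial has no licks), so
the subtraction compares lick-phase-locked power with like-aligned
baseline power. Trials without usable licks in the odorant window —
correct rejections withhold licking by task design — are aligned on
theta-peak surrogates; this is a documented convention, isolated in
`surrogate_events`, not a claim about how any particular recording was
analyzed. The genotype contrast ΔauROC = (laser − pre)ₒₚₛᵢₙ −
(laser − pre)ᶜᵒⁿᵗʳᵒˡ is reported per band × lag with a bootstrap CI over
electrode units and the interaction p, FDR-corrected over the grid.

## Synthetic sessions

The generator's job is to emulate the *statistical* structure the analyses
assume, with every effect size programmable, so that parameter recovery
and null calibration are testable. Defaults and what they model:

* **Sampling rate 1 kHz** (config field): all analysis bands are ≤ 95 Hz,
  so acquisition-grade rates add nothing to these analyses.
* **Trial period 7 s**: long enough that no trial's baseline window can
  see the previous trial's odorant response (which ends ≥ 1.4 s earlier).
* **LFP** = 1/f background (exponent 1, SD 10 µV) plus four band-limited
  oscillators (θ/β/low-γ/high-γ at 15/10/8/6 µV SD), synthesized
  spectrally with half-cosine skirts. Oscillator in-band PSD dominates the
  background by ~6–20×, so programmed dB steps are recovered with < 0.5 dB
  compression.
* **Programmed effects**: during each odorant the band amplitude scales by
  10^(ΔdB/20) with 100 ms cosine ramps (no spectral splatter). The mean
  ΔdB follows the *effect carrier* — odorant value (default; flips with
  reward reversal), odorant identity (the control construction for the
  reversal analysis), or the animal's response (false alarms then carry
  hit-like power, the premise of the FA/CR analysis). Trial-to-trial
  variability (SD 2 dB by default) is drawn **independently per
  electrode**: electrodes are then exchangeable analysis units, which is
  what keeps the electrode-pooled interaction ANOVA calibrated under a
  null. (Real electrodes share within-session state; see the caveat
  above.)
* **Theta and licks, one mechanism**: a single narrowband theta process
  per session provides the phase that every electrode's theta component
  carries (each electrode gets an independent stochastic amplitude
  envelope, preserving unit independence of theta *power*) and that licks
  lock to. Lick placement is once-per-theta-cycle at a von Mises phase
  (κ = 2 by default; rate 7 Hz; 70 ms refractory); κ = 0 switches to a
  phase-independent renewal process, because a per-cycle construction
  pruned by the refractory period would leave residual phase structure.
  Lick rates and inter-lick statistics are conventions — the task
  literature reports them only qualitatively.
* **Behavior**: correct-decision probability ramps linearly across a
  session; respond decisions produce criterion-satisfying lick trains
  (an extra theta-locked lick is inserted into any empty 0.5 s interval),
  withhold decisions produce no response-window licks. Misses produce no
  licks; FAs produce S+-like lick trains.
* **Laser**: on laser-enabled sessions the laser runs 3.5 s from port
  entry on every trial and multiplies the programmed S+/S− contrast by a
  per-genotype factor (control ≡ 1; opsin configurable, 0 = contrast
  silenced).
* **Determinism**: all randomness fans out from one seed through
  `numpy.random.SeedSequence`; identical configs give byte-identical
  sessions.

What the generator does **not** model: respiration as a signal distinct
from theta, biophysical olfactory-bulb circuitry, inter-mouse variance
beyond electrode gains, electrode drift, artifacts, or volume-conduction
correlations between electrodes. Passing tests therefore demonstrate that
the *analyses* are correct and calibrated on data satisfying their own
assumptions — not that real recordings satisfy those assumptions.

## Study-design scenario builders and problem sizes

The figure-level analyses ship with scenario builders that encode the
study designs at desk scale: a two-session learning pair (60 trials,
16 electrodes; contrast ramping 0→6 dB in session one, sustained in
session two; naive = first 30 trials of the first session, proficient =
last 30 of the last), a forward/reversed reward pair (60 trials; +4/−1 dB
value- or identity-locked effects), and a genotype × laser 2×2 (2 mice per
genotype × 16 electrodes, 30-trial sessions, 20-trial pre/laser epochs).
These sizes are deliberate scientific scale-downs of the original designs
(5–8 mice × 16 electrodes, sessions of several hundred trials); effect
sizes are chosen so that recovery is comfortable but not trivial.

## Validation suite

`oblfp.validation` (asserted by `tests/test_acceptance.py`, reported by
`scripts/acceptance.py`) checks, on synthetic data only: Δ power step
recovery (+6.02 dB programmed, ~5.75 recovered, tolerance ±0.5);
exact agreement of the rank-based auROC with exhaustive pair counting;
end-to-end auROC at a 6 dB / 3 dB-SD contrast against Φ(6/(3√2)) − 0.5 ≈
0.421 (±0.05 — the measured value runs ~0.02 low because spectral
estimation noise adds to the programmed trial SD); FDR null calibration at
96 electrodes (≤ 10% significant); permutation-ANOVA exactness (2/252)
and type-I error (0.05 ± 0.02); the learning, reversal and optogenetic
analyses at their scenario designs; lick-phase concentration recovery
(I₁(2)/I₀(2) ≈ 0.698 ± 0.05 at ~10³ licks); and byte-level determinism of
every CLI verb.

## Known limitations

* Electrode pooling in the interaction and permutation tests
  pseudoreplicates on real data (shared within-session noise); use the
  per-mouse aggregation for inference about animals.
* The Hanley–McNeil z-test is asymptotic; at 10 + 10 trials per class
  (20-trial laser epochs) its p-values are coarse. The permutation path
  is the refuge for small n.
* LR-LFP Δ power for lick-free trials depends on the surrogate-alignment
  convention; alternative baselines (e.g., random alignment) would shift
  absolute values, though contrasts between conditions are robust in the
  synthetic checks.
* The spectral smearing of the 1 s window biases absolute Δ power toward
  zero by ~0.3 dB for 2.5 s effects; comparisons across conditions are
  unaffected.
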