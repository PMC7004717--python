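# Methods

This note documents the models, algorithms and numerical choices in
the `cai` package: what is computed, under which assumptions, and
which design decisions were genuinely open.

## 1. The cortical activity index

### Signal picture

Scalp EEG is the summated postsynaptic activity of cortical pyramidal
cells. Awake, these cells fire tonically and asynchronously: the EEG
is low-amplitude, broadband, rich in brief "peak" deflections. Under
general anesthesia the population alternates between an active
up-state and a silent down-state; with deepening anesthesia the
up-states shorten into bursts, the down-states lengthen, the EEG
becomes dominated by high-amplitude delta-band slow waves, and at deep
levels shows burst suppression (bursts separated by near-isoelectric
gaps). CAI operationalizes this: the fraction of samples per epoch
that ride above an amplitude threshold is high exactly when cortex is
active.

### Definition

For an epoch `x[0..N-1]` (microvolts):

* adaptive threshold `T = K · (1/M) · Σ_{k=1..M} |DFT(x)[k]| / N`.
  The DC bin is excluded (electrode offset is not brain activity), so
  T is invariant to constant offsets and positively homogeneous:
  `T(c·x) = c·T(x)`. Division by N converts DFT magnitude back to
  amplitude scale — an on-bin cosine of amplitude A at bin 1 with
  `K=2, M=1` gives exactly `T = A`.
* peak density `ρ = #{n : |x[n]| > T} / N ∈ [0, 1]`, strict
  comparison on the rectified signal (EEG polarity is
  montage-dependent), non-increasing in T.
* the density stream is smoothed with a centered moving average
  (window shrinks symmetrically at the record edges) and mapped to
  display units as `100·ρ`, clipped to [0, 100].

### Parameters, defaults, calibration

| parameter | default | meaning |
|---|---|---|
| `epoch_len` | 512 samples (4 s at 128 Hz) | analysis window |
| `step` | 256 samples (2 s) | index cadence |
| `M` | 16 | DFT bins averaged: 0.25–4 Hz, the delta band |
| `K` | 6.0 | threshold gain |
| `smooth_epochs` | 15 (~30 s) | moving-average width |

`K` and `M` are calibration constants with no universal value; the
defaults were calibrated **on the simulator** (section 3) so that
awake recordings score ≈ 70+ and deep burst-suppression recordings
≈ 30 or below, with mean CAI strictly decreasing in simulated depth.
A 4 s window was chosen over 2 s because it resolves 0.25 Hz and,
at deep levels, usually spans at least one burst–suppression cycle,
which keeps the threshold anchored to burst amplitude during
suppression gaps. All of these are plain config values (`cai compute
--config`), because a different front end, montage or population may
need a different calibration.

A structural caveat: an epoch that falls entirely inside a long
suppression period contains only instrument noise, and the adaptive
threshold — derived from that same epoch — collapses with it, so such
epochs score *high*. The 4 s window and ~30 s smoothing dilute this,
and clinical maintenance anesthesia rarely produces such long gaps,
but fully isoelectric recordings are outside the index's valid range.
No artifact rejection is performed (a real deployment would gate
epochs first; the pipeline is a pure function of the input trace).

## 2. Reference spectral entropy

SpEn is the normalized Shannon entropy of the band-restricted power
spectrum: `H = −Σ p_i log p_i / log(nbins)`, `p_i = P_i/ΣP_i`, so a
flat (broadband, awake) spectrum scores 1 and a single spectral line
scores 0. Choices:

* band 0.8–32 Hz, state-entropy style; no electromyogram band
  (response entropy is out of scope).
* 8 s epochs (1024 samples) advancing 2 s: the 0.8 Hz band floor is
  unresolvable at 2 s windows (Δf = 0.5 Hz), and longer windows
  stabilize broadband entropy (with ~250 bins, white-noise epochs
  score ≈ 0.92 rather than ≈ 0.90 at 63 bins — the small-sample bias
  of plug-in entropy).
* rectangular window, one-sided periodogram with interior-bin
  doubling so the full-band powers satisfy Parseval exactly.
  Consequence: a tone *off* the DFT grid leaks across neighboring
  bins and scores a small nonzero entropy (≥ log 2/log nbins when it
  straddles two bins); the "pure sinusoid ⇒ entropy ≈ 0" limit holds
  for tones on the analysis grid.
* epochs with zero in-band power are missing values: excluded from
  smoothing, absent from the output stream; an all-zero record yields
  an empty stream with a warning.
* natural log; normalization makes the result base-independent.

On the simulator, SpEn decreases with depth through the clinical
range (d ≲ 0.7) but *rebounds* in deep burst suppression, where
epochs are noise-dominated and hence broadband — the known
suppression artifact of spectral entropy (commercial monitors patch
it with a burst-suppression-ratio term, deliberately not replicated
here). CAI, whose threshold is anchored by burst amplitude, does not
rebound until recordings become fully isoelectric.

## 3. Synthetic anesthesia EEG

Purpose: every downstream module must be testable without clinical
data, against a *known* depth. Depth is the scalar `d ∈ [0, 1]`,
defined as one minus the expected up-state fraction of the source
population — an abstract operationalization of "percentage of
pyramidal cells in the active state". No pharmacokinetics: d is an
input trajectory, not a drug model.

Generative model, per record:

1. **Population state.** One alternating-renewal up/down sequence
   with exponential dwells, means
   `mean_up(d) = 6·(1−d) + 0.05 s`, `mean_down(d) = 2·d + 0.01 s`,
   refreshed from the local d(t) at each dwell start. The up/down
   alternation is *shared* across sources: the slow oscillation of
   anesthesia is cortex-wide synchronized, and independent per-source
   switching would average out under the central limit, never
   producing near-isoelectric suppression gaps. The small down-floor
   (0.01 s vs 0.05 s for up) keeps the rare awake down-dips short
   enough not to dominate awake delta power.
2. **Sources.** 50 sources fire independent Poisson spikes at 20 Hz
   during up-states, modulated by a shared delta rhythm
   `1 + d·sin(2π·2·t)` — burst firing under anesthesia is rhythmic,
   and this is what gives deep epochs genuine slow-wave content
   rather than amplitude-modulated broadband noise. Spikes are
   convolved with an alpha PSP kernel
   `(t/τ)·exp(1−t/τ)·amp`, τ = 5 ms, amp = 3 µV (peak exactly `amp`
   at `t = τ`).
3. **Mixing.** Sources are summed, demeaned, embedded in 1/f pink
   noise (1 µV RMS, spectral shaping of seeded white noise) plus
   white instrument noise (1 µV RMS), and AC-coupled with a
   zero-phase order-2 high-pass at 0.3 Hz — the monitor front end.
   Without the high-pass, the standing depolarization pedestal of the
   up-state (≈ 40 µV for these defaults) turns state switching into a
   square wave that swamps the morphology.

Surgery profiles are piecewise linear: awake (d = 0.05, 2 min) →
induction ramp (1 min) → maintenance plateau (d ≈ 0.7 ± 0.1 with slow
wander, 5 min) → emergence (1 min) → recovery (1 min). Cohorts draw
sex ~ Bernoulli(½), age ~ N(45, 12²) truncated at 18, BMI ~ N(24, 3²)
truncated above 15 — invented distributions that exist to exercise the
regression, not to match any clinic. All randomness flows from
explicit seeds (`numpy.random.SeedSequence` spawning per subject);
identical seeds give bit-identical cohorts. A `synthetic_bis` helper
produces a BIS-like stream as `5 + 90·(1−d) + N(0, 3²)` clipped to
[0, 100] — a labelled synthetic stand-in for a monitor export, with
none of the real algorithm's internals.

What the simulator does **not** emulate: eye/movement/electrocautery
artifacts, electrode impedance drift, spindles and alpha
anteriorization, agent-specific signatures, EMG contamination.
Passing tests on simulated cohorts therefore demonstrate internal
consistency and qualitative behaviour (index orderings, monotonicity
with depth, correlation structure), not clinical performance.

## 4. Comparison statistics

* **Standardization** `z = (x − mean)/sd` per subject, per method,
  sample sd (n−1). Whether to standardize per subject or pooled was
  genuinely open; per subject matches per-recording display traces
  and removes between-subject scale, and is idempotent. Consequence
  worth knowing: with per-subject standardization every
  (subject, method) stream has mean zero, so subject-constant
  covariates (sex, age, BMI) carry almost no information in the
  pooled regression on *pipeline* output — their estimates shrink to
  ~0 by construction. The regression machinery itself is validated on
  synthetic long tables where the covariate effects are real.
* **Alignment**: linear interpolation of two streams onto a common
  1 s grid over their time overlap, no extrapolation; correlations
  are computed on standardized aligned pairs pooled across subjects.
* **Descriptives**: exact order statistics (midpoint median) and
  |max − min| per method.
* **Semiparametric regression** (`SemiparametricIndexModel`):
  `z ~ method + sex + age + bmi + time + s(time)`, methods coded
  against BIS, sex against Female. `s(time)` is a cubic B-spline with
  20 interior knots on time quantiles and a second-difference
  penalty. The penalty's null space (constant + linear) duplicates
  the explicit intercept and linear-time terms, so the basis is
  reparameterized onto the penalized eigenspace and orthogonalized
  against `[1, time]`; every remaining smooth direction is strictly
  penalized and the model collapses onto the parametric OLS fit as
  λ → ∞. λ is selected by GCV, `n·RSS/(n − edf)²`, over a log-spaced
  grid 1e-4…1e10 (57 points); an explicit λ can be passed instead.
  Reported smooth edf counts the whole time trend — the explicit
  linear term plus the spline block — hence → 1 in the no-smooth
  limit. Standard errors are frequentist
  (`σ²·A⁻¹C'C·A⁻¹`, `A = C'C + λP`), p-values use a t reference with
  `n − edf` df, and the smooth's significance is an approximate
  F-test against the parametric-only fit. These approximations
  ignore smoothing-parameter uncertainty and within-subject
  autocorrelation: the model pools all rows with no subject random
  effect (a deliberate simplification, flagged as a statistical
  limitation), so p-values are descriptive. Rank-deficient parametric
  designs (e.g. one subject, so age/BMI are constant) are rejected
  with the collinear terms named, via pivoted QR with an
  `eps`-scaled tolerance. An optional time-truncation flag drops rows
  beyond a cutoff before fitting (ragged emergence tails).

## 5. Problem sizes and determinism

The test and acceptance workloads use 60 s constant-depth records
(5 depths × 20 seeds) for the monotonicity study, 32-subject cohorts
of 10-minute surgery recordings for the end-to-end study, and
~5,000-row tables × 100 replicates for the regression recovery study
— sizes at which every studied quantity is stable yet the whole suite
runs in well under a minute per study on one CPU. The recovery
study's sinusoidal smooth uses whole cosine cycles over the time
span, so it is orthogonal to the intercept and linear-time columns
and the parametric truth stays identifiable — with a non-integer
number of periods, part of the "smooth" truth *is* a linear trend and
no estimator could attribute it correctly. Every stochastic step
consumes an explicit seed; reports regenerate byte-identically, and
provenance sidecars record seed, config hash and version (and no
timestamps, precisely so reruns are comparable).

## 6. Known limitations

* K, M and the epoch geometry are calibrated on the simulator, not on
  clinical data; the calibration transfers only to signals with
  comparable spectral contrast between awake and deep states.
* Isoelectric and artifact-laden epochs are outside CAI's valid range
  (no artifact gate, threshold collapse on pure noise).
* SpEn here is a reference implementation, not the commercial
  E-Entropy algorithm (different windowing, no EMG band, no
  burst-suppression correction).
* The regression pools subjects without random effects and its
  p-values are approximate (section 4).
* The EDF writer is deliberately minimal: single channel, integer
  sampling rates, 1 s records, 16-bit quantization over the record's
  own amplitude range.
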