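# Methods

`remidet` implements an automated seizure-event detector for reduced-channel
wearable EEG, together with the synthetic cohorts and the evaluation
machinery needed to exercise it end to end.  This note records the model,
its parameters, and the design and numerical choices that were genuinely
open.

## Signal model and montage

Each subject wears four single-channel scalp sensors below the hairline —
left/right forehead (LF, RF; near 10–20 positions F7/F8) and behind the
left/right ear (LE, RE; near T5/T6).  Sensors record at 512 Hz through a
0.8–92 Hz analog passband with a ±175 μV full scale digitized at 10 bits.
The four referential signals and their six pairwise differences
(LF−RF, LF−LE, LF−RE, RF−LE, RF−RE, LE−RE) form a fixed 10-channel montage,
the input to all downstream analysis.  The differential pair order is not
dictated by anything physical; it is fixed lexicographically so that file
outputs and feature schemas are deterministic.  Sensors are aligned by
their recording start times and trimmed to the common temporal overlap
(hardware tap-synchronization to a wired reference is out of scope).  All
times are seconds from a per-cohort epoch; intervals are half-open
`[start, stop)`.

EDF/EDF+ container: the physical range is the sensor full scale (±175 μV)
over a symmetric 16-bit digital range, so a round trip is exact to half an
EDF quantization step (~0.003 μV) and 0 μV is exactly representable.  The
10-bit sensor grid is applied in the simulator, not the container.

## Segmentation, scoring, and features

The montage is cut into non-overlapping, contiguous 2-s windows (trailing
partial window dropped).  Against a ground-truth seizure list, a window is
scored **ictal** if it overlaps any seizure by any positive amount (the
segment-level analogue of any-overlap event scoring), **near-ictal** if it
lies within 15 min (900 s) of a seizure boundary, and **non-ictal**
otherwise.  Near-ictal windows model pre-ictal evolution and post-ictal
slowing that would otherwise contaminate the negative class.

Per channel and window the feature vector covers four domains:

* **time** — variance, line length (Σ|xᵢ−xᵢ₋₁|), RMS;
* **frequency** — absolute and relative band power in delta (0.8–4 Hz),
  theta (4–8), alpha (8–13), beta (13–30) and gamma (30–70 Hz) from a
  Hann-windowed periodogram, the relative powers normalized by total
  passband power;
* **time–frequency** — mean-square energies of a 5-level db4 discrete
  wavelet decomposition (5 detail levels + final approximation).  The
  pyramid is a causal filter + dyadic decimation; boundary handling is
  immaterial for energy features;
* **complexity** — spectral entropy (normalized Shannon entropy of the
  passband periodogram) and sample entropy SampEn(m=2, r=0.2·SD).

Seizures evolve over tens of seconds, so each per-channel feature is
augmented with an exponentially weighted history
`h_t = α_h·h_{t−1} + (1−α_h)·f_t`, `h_0 = f_0`, with `α_h = 0.8`
(≈10-window memory).  Cross-channel structure is captured by the
across-channel mean, SD, max and min of each base feature over the 10
channels, plus the six zero-lag Pearson correlations of the broadband
sensor-pair signals per window.  A zero-variance channel yields correlation
0 by convention.  The full schema is 10×21 per-channel features, doubled by
history, plus 4×21 summaries and 6 correlations: 510 named features per
window, identical across subjects.

Numerical choices: sample entropy is computed on mean-pooled samples
(512 → 64 Hz, 128 points per window) so the O(n²) template match stays
tractable at cohort scale; degenerate windows (zero SD, or no length-m
template matches) return 0 by convention, and zero length-(m+1) matches are
capped at one match so the statistic stays finite.  Zero-power windows have
spectral entropy 0 and relative band powers 0.

## Detector

Training follows leave-one-subject-out (LOSO).  For each held-out subject,
ictal and non-ictal windows from all other subjects are pooled; all ictal
rows are kept and non-ictal rows are subsampled without replacement
(seeded) to a 3:1 non-ictal:ictal ratio.  Near-ictal rows never enter
training.  A random forest with 500 trees, bootstrap resampling, and
unlimited depth supplies a per-window ictal likelihood, which is smoothed
by a first-order leaky integrator `y_t = α·y_{t−1} + (1−α)·p_t` with
`y₋₁ = 0` and default leak `α = 0.8`.

Events are formed from the integrated trace with a fixed threshold θ: five
continuous supra-threshold windows (10 s) set a start marker at the first
supra-threshold window minus the integrator group delay
`L = round(α/(1−α))` windows (8 s at the default leak, floored at the
record start); five continuous sub-threshold windows set a stop marker at
the end of the last supra-threshold window; an event still open at the
record end is closed there.  Post-processing first merges events separated
by less than 2 min (iterated to a fixed point) and then discards any event
longer than 15 min — merge strictly precedes discard, so a chain of nearby
detections can grow past the cap and be removed as a whole.

**Threshold calibration.**  θ is chosen per LOSO fold as the largest value
on the grid 0.05–0.95 (step 0.01) whose post-processed detections reach
≥90% any-overlap event sensitivity on the training subjects; if no value
qualifies, the grid minimum is used with a warning.  A subtlety: a
fully-grown forest scores its own training rows at ≈1.0, so a sensitivity
check against in-sample traces is vacuous — every threshold up to the grid
maximum passes, which contradicts the intent of a threshold "set low" for
high sensitivity.  Calibration traces therefore use **out-of-bag**
likelihoods for windows that entered the training matrix (each row averaged
over only the trees that did not bootstrap it); all other windows —
near-ictal and unsampled non-ictal — are ordinary out-of-sample
predictions.  Rows never out of bag (vanishingly rare at 500 trees) fall
back to the in-sample value.  Calibrating per fold rather than once
globally keeps each fold blind to its held-out subject.

## Synthetic cohorts

No clinical recordings are deposited, so cohorts are generated.  The
defaults restate the study's cohort structure: 20 subjects, half with
focal-onset seizures, 1–6 seizures each with mean ≈ 2.4 (distribution
{1: .30, 2: .35, 3: .15, 4: .10, 6: .10}), at scaled-down default stays of
2–6 h (multi-day stays available by configuration).  Seizure durations
default to 30–300 s, a realistic focal-seizure band inside the admissible
10 s–15 min envelope.  Consecutive onsets are kept >30 min apart and
≥16 min from record edges so near-ictal windows never leave the record or
bridge adjacent seizures; a drawn seizure count is truncated to what the
stay can host under these rules (a 2-h stay holds at most 2).

Background EEG is 1/f-weighted noise plus a waxing-and-waning ~10 Hz
rhythm, band-passed to 0.8–92 Hz, scaled to 15 μV RMS, clipped to ±175 μV
and snapped to the 10-bit ADC grid.  A shared common-source component
(gain 0.45 against 0.9 own noise) stands in for volume conduction.  The
ictal waveform is an evolving oscillation — an 8 → 3 Hz frequency glide
with a ramp-up/ramp-down envelope, weak second harmonic and slow amplitude
waxing — applied at unit gain on one onset sensor and mixed onto the others
at fixed sub-unity gains (same side 0.55, contralateral homolog 0.40,
diagonal 0.25).  `ictal_snr` (default 4.0) is the ratio of onset-sensor
ictal RMS to nominal background RMS; waveform amplitude is linear in it.

This generator emulates amplitude statistics, spectral slope, band-limited
rhythms, ADC quantization, and a separable, spatially-lateralized ictal
signature.  It does **not** emulate artifacts (EMG bursts, electrode pops,
movement), true volume-conduction physics, state-dependent background
(sleep/wake), or the morphological diversity of real seizures — so a green
detection test establishes that the pipeline recovers the stated ictal
model from the stated background, not clinical performance.  Published clinical
figures for systems of this kind were measured on inpatient recordings this
package cannot access and are not reproduction targets here.

Reviewer marks for the agreement machinery are simulated per truth event
(independent reproduction with probability `hit_rate`, boundary jitter
±`boundary_jitter_s`) plus Poisson false marks placed ≥60 s clear of truth
events.

## Evaluation

Event scoring uses the any-overlap rule: a known seizure is a true positive
if ≥1 detection overlaps it by any positive amount; a detection overlapping
no seizure is a false positive; one detection may validate several seizures
and vice versa, and a detection is never both matched and false.  Percent
overlap of a true positive is the fraction of the seizure's duration
covered by the union of its matched detections.  Per subject: sensitivity
= TP/(TP+FN)·100, precision = TP/(TP+FP)·100, FDR = FP per recorded hour
(record hours = montage duration).  Conventions for degenerate subjects
are declared rather than inferred: subjects without seizures contribute no
sensitivity; a subject with no detections and no seizures has precision
100; a subject with seizures and no detections has undefined precision
(excluded from the precision mean).  Cohort summaries are unweighted
across-subject mean ± SD (ddof = 1) with range.  Patient-level rule-in
sensitivity is the fraction of seizure subjects with ≥1 true positive;
specificity the fraction of seizure-free subjects with no detections.

Consensus over three reviewers is built by 1-s pointwise majority (≥2 of
3) with runs shorter than 2 s discarded.  Cohen's κ (pairwise) and
Fleiss' κ (group) are computed over the known-seizure × rater binary
table; degenerate unanimity (chance agreement 1) is defined as κ = 1.
Both statistics are cross-checked in the test suite against brute-force
formula evaluation on exhaustively enumerated small tables and against
independent library implementations.

## Determinism

A single top-level seed is fanned out to named-purpose streams (per
subject, per stage) via hashed spawn keys, so adding a consumer never
perturbs existing streams; the forest seed is derived the same way.  The
full simulate → detect → evaluate pipeline is byte-identical across
repeats under one seed.

## Known limitations

* The feature list instantiates one reasonable choice per named domain;
  the original feature set is not published.
* The history operator, integrator form, latency correction, and consensus
  construction are declared operationalizations of loosely specified
  mechanisms (all recorded above).
* Scoring all 10 montage channels (not only the 4 sensors) is an assumption;
  the montage is treated as the declared algorithm input.
* At very small scales (1–2 training subjects, reduced sampling rates) the
  calibrated threshold can exceed what a held-out subject's trace reaches;
  small fixture worlds in the test suite therefore assert plumbing
  contracts, while detection-performance claims are made at the stated
  6-subject, 2-h, 512-Hz scale.
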