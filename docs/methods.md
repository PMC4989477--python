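# Methods

## The problem

Intermittent photic stimulation (IPS) at frequencies near the individual
alpha frequency α drives the posterior alpha rhythm: the free-running
oscillation locks to the stimulus (*frequency entrainment*) and its
amplitude grows (*resonance*), strongest at 1.00·α and at the first
subharmonic 0.50·α. Under scotopic (rod-dominated) viewing the flicker
fusion threshold sits near 15 Hz, so stimulation at ≥1.30·α is perceived
as steady light: the oscillatory driving disappears and is replaced by
transient evoked fields after stimulus onset (*on-response*, ~200 ms) and
offset (*off-response*, ~150 ms), together with a partial suppression of
the background alpha rhythm.

This package implements the full analysis chain for such experiments —
preprocessing, spectral entrainment classification, Topographic Matching
Pursuit (TMP), correlation-sequence phase segmentation, and on/off
transient detection — and a synthetic-session generator that reproduces
the phenomenology with known ground truth, so every classifier can be
validated end to end.

## Protocol and generator

A session consists of a 60 s eyes-closed resting segment followed by 20
frequency blocks, one per multiplier of α
{0.40, 0.45, 0.50, 0.55, 0.60, 0.70, 0.80, 0.90, 0.95, 1.00, 1.05, 1.10,
1.30, 1.70, 1.90, 1.95, 2.00, 2.05, 2.10, 2.30}, presented in a
seed-determined random order. Each block holds 30 trains of 40 flashes
with 4 s inter-train rest, sampled at 1000 Hz. Train onsets sit on integer
samples and every flash onset is rounded individually from its exact
continuous time, so fractional-sample drift of non-divisor frequencies
(e.g. 10.58 Hz) never accumulates.

The source model is a hard-locking phase oscillator:

* **Entrained blocks** (multiplier in [0.40, 1.10]): the oscillator runs at
  the stimulation frequency f with an engagement ramp 1 − exp(−t/τ),
  τ = 10 stimulation periods, matching the observation that engagement
  completes by stimulus 5–10. The resonance amplitude gain follows a
  double-Gaussian profile over the multiplier m,
  g(m) = 1.2 + 1.8·exp(−((m−1)/0.12)²) + 0.8·exp(−((m−0.5)/0.08)²),
  so g(1.00) = 3.0, g(0.50) = 2.0, and the weakest in-band response
  (~0.46 of the peak) still clears the 20% entrainment amplitude rule.
  Near 0.50·α the locked response carries a second-harmonic component
  (amplitude 1.5·exp(−((m−0.5)/0.05)²)), the subharmonic resonance that
  elevates alpha-band activity when driving at half alpha. After the last
  flash the driven rhythm persists for 2 periods (configurable 1–3) and
  then decays with a one-period time constant. Background alpha is
  suppressed by 90% while locked and recovers with a 1 s time constant
  (event-related desynchronization outlasts the stimulus).
* **Fused blocks** (multiplier ≥ 1.30): no oscillation at the stimulation
  frequency. Gaussian transients (50 ms FWHM, amplitude 2× the resting
  alpha) are planted at train onset + ~200 ms and train end + ~150 ms (the
  off bump scaled by 0.6); both latencies are jittered per subject with
  SD 18 ms. Background alpha is suppressed by 50% during the train.
* **Background alpha** is phase-diffusing (random-walk phase, 5 rad²/s,
  linewidth just under 1 Hz) and starts each train at an arbitrary phase.
  This is what makes engagement *visible in the train average*: the
  unlocked rhythm carries a random phase per train and largely cancels
  under 30-train averaging, while the stimulus-locked response survives.
  85% of the background energy comes from six generators with their own
  dipolar topographies and small frequency detunes (SD 0.3 Hz), so the
  sensor topography genuinely destabilizes when the drive ends.

Sources project to an idealized 306-channel layout (102 sites on a
sunflower disk lattice, each with one magnetometer and two orthogonal
planar gradiometers; the 12 most posterior sites are tagged occipital,
giving exactly 24 occipital gradiometers). Magnetometers carry a two-pole
field pattern (peak 200 fT per unit source), gradiometers its x/y
derivatives (peak 100 fT/cm). Sensor noise is iid Gaussian with SD =
(per-type peak alpha amplitude)/snr; snr defaults to 2. Sessions are
bit-identical for identical seeds; blocks are materialized on demand
(float32) so a full 306-channel session never needs to reside in memory.

### What the generator does not emulate

No realistic lead fields or head geometry, no eye blinks, cardiac or
muscle artifacts, no 1/f background spectrum (noise is white), no
inter-subject variability of resonance gains or entrainment bandwidth,
no slow drifts of the alpha frequency within a session. Passing the
recovery experiments therefore shows that the analysis chain is correct
and calibrated under the modeled phenomenology — not that it is robust to
every artifact of real MEG.

## Analysis chain

1. **Preprocessing** — zero-phase Butterworth bandpass 2–30 Hz of order 4
   (forward–backward `sosfiltfilt`, odd edge padding), applied to the
   continuous block before epoching. Epochs run from 500 ms before the
   first flash to 3 s after the end of the last period, anchored at the
   flash event markers, and are averaged across the 30 trains. The
   averaged block is linearly detrended and baseline-corrected to the
   500 ms pre-onset window. Note the digital filter follows the analog
   Butterworth magnitude on the bilinear (prewarped) frequency axis; at
   50 Hz the analog-axis formula deviates by ~4% (frequency warping),
   which is a property of any bilinear-designed IIR filter at this
   sampling rate.
2. **Spectra** — rectangular-window FFT over stimulus 1 to the end of
   period 40, zero-padded to the next power of two, amplitude convention
   2|X|/N, averaged over the 24 occipital gradiometers. The individual
   alpha frequency is the maximal local peak of the resting spectrum in
   7–13 Hz; a peak must exceed 2× the in-band median or the estimate is
   flagged rather than silently returned. Alpha peak ratios divide the
   stimulation alpha peak by the resting peak computed over a window of
   equal length (resolution-matched per block). Entrainment requires both
   (i) the maximal peak within ±2 Hz of the stimulation frequency to lie
   within one non-padded frequency bin of the stimulation frequency or a
   harmonic (k ≤ 3), and (ii) its amplitude to exceed 20% of the maximal
   peak found across the whole cohort. Ratio statistics: one-sample
   t-tests against μ = 1 (both one-sided alternatives) per multiplier and
   Holm-corrected pairwise paired t-tests.
3. **TMP** — one Gabor atom per stimulation period (40) plus ten
   post-stimulation periods. The dictionary holds unit-norm scaled,
   translated, modulated Gaussians; translations on a quarter-scale
   lattice, modulations 2–30 Hz in 0.5 Hz steps. For the one-period
   windows the scale ladder is {window/2, window}: envelopes narrower than
   half a single-cycle window act as bump-matchers and bias the
   modulation estimate low (a 10 Hz cycle fits a 2 Hz bump). The shared
   (s, u, ξ) maximizes the summed per-channel energy captured by the
   phase-optimal real atom (exact projection onto the atom's cosine/sine
   span); per-channel amplitude is the l2 norm of that projection —
   hence Σ amp² ≤ Σ ‖x‖² — and phase is measured at the envelope center.
   Ties resolve to the lowest modulation, then smallest scale, then
   earliest translation. The reference atom averages the forty 1.00·α
   stimulus atoms (parameters and amplitudes arithmetically, phases
   circularly). Correlation sequences take, per channel, the maximum over
   lag of the absolute normalized cross-correlation between the atom's
   and the reference's reconstructed waveforms, with the lag search
   bounded to ±window/24: an unbounded search rates any two
   same-frequency atoms as identical regardless of phase, which erases
   the engagement/disengagement structure the sequences exist to express.
4. **Phase segmentation** — a three-segment least-squares model (linear
   rise to a plateau, constant plateau, linear fall) with exhaustive
   breakpoint search (rise end in 2–15, fall start in 41–50). Phases
   count as detected when the fit explains the sequence (R² ≥ 0.5) and
   the fitted rise and fall amplitudes each exceed 0.10 of the plateau
   level. The amplitude fraction is 0.10 rather than a larger value
   because the lag-bounded correlation floor sits near 0.6–0.7, so real
   sequences occupy roughly the upper 40% of [0, 1]. Classes: *good* =
   phases detected and plateau sample variance < 0.004, *moderate* =
   detected with variance ≥ 0.004, *weak* = no phases. Per-phase
   variances of the atoms' modulation frequency are compared (I vs II,
   III vs II) with one-sided paired t-tests.
5. **Time domain** — MGFP (spatial RMS per channel type) and the
   channel-mean Hilbert envelope from 500 ms before onset to 3 s after
   the end; mixed channel types are combined after dividing each type by
   its median envelope (fT and fT/cm cannot be averaged raw). The
   on-response is the first envelope peak after onset exceeding the
   pre-onset baseline mean + 3 SD with a prominence of at least 3
   baseline SD (the "outstanding peak" rule — without the prominence
   requirement, ripple on the decaying post-stimulation plateau of driven
   blocks fires the detector); the off-response is the first such peak
   after the end of the last period. The first and last 100 ms of the
   envelope are excluded (analytic-signal edge effects). Group test:
   per-subject off-response occurrence proportions, low group (multiplier
   ≤ 1.10) vs high group (≥ 1.30), one-sided paired t-test, plus one-way
   ANOVAs of on-latency and on-amplitude across multipliers.

## Calibration and recovery (what the suite establishes)

* Entrainment classifier vs generator labels: 100% agreement on a
  noiseless 12-subject cohort (240 cells) and 100% over ten snr = 2
  single-subject sessions (200 cells; the criterion asks ≥ 90%).
* Response-class recovery: at snr = 2, all driven blocks (0.90–1.10)
  classify good/moderate and all fused blocks (1.70–2.30) weak over ten
  seeds (120/120). Noiseless recovery is 96%, not 100%: without sensor
  noise the incoherently averaged background residue occasionally aligns
  with the reference at a band-edge multiplier and the fitted rise or
  fall amplitude misses the 0.10·plateau rule by < 0.02. This is a known
  limitation of the compressed dynamic range of normalized atom
  correlations under this generator, not of the segmentation itself
  (planted sequences classify at 100%).
* Transients: planted on-latencies (150–250 ms) recovered within ±5 ms in
  ≥ 95% of 200 trials at snr = 2; with fusion disabled the off-occurrence
  test rejects at the 5% level in ~5% of 200 simulated cohorts (type-I
  control), with approximately uniform p-values.
* Matching pursuit: `fit_atom` agrees with an independent exhaustive
  least-squares search on 100 random 8-channel windows, and recovers the
  planted modulation within one grid step in ≥ 95% of 200 trials at
  SNR 3 (atoms restricted to ≥ 1 carrier cycle under the envelope; below
  that the modulation is not identifiable from the waveform).

### Problem sizes

Cohort experiments use the full default protocol. The snr = 2 agreement
study uses ten single-subject sessions; the type-I study uses 200 cohorts
of 6 subjects with a reduced protocol (3 trains × 10 flashes, two
occipital triplets); latency recovery uses single fused blocks of 8
trains × 15 flashes over the occipital patch. These sizes are the
package's defaults for its validation studies and are exposed as function
arguments.

## Degenerate inputs and numerical choices

All-zero TMP windows yield a zero-amplitude atom flagged degenerate;
zero-energy channels get correlation 0; zero-variance statistics are
flagged rather than producing NaN t-values; a missing alpha peak raises
instead of extrapolating; sequences of unexpected length, windows outside
the data extent, mixed channel types in unit-sensitive reductions, and
cutoffs at or above Nyquist are rejected with errors. Near-degenerate
Gabor cosine/sine pairs (vanishing sine part at the lowest modulations)
fall back to the cosine-only projection. Every tunable constant named
above is reachable from the pipeline YAML configuration and echoed into
the report for provenance.
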