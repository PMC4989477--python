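# photodrive

Analysis of **photic driving** in MEG: the rhythmic cortical response to
intermittent photic stimulation (IPS) at frequencies tied to the
individual alpha frequency α. The package implements the complete
analysis chain for experiments in which 20 stimulation frequencies
(0.40–2.30 × α, 30 trains of 40 flashes each) are presented under
scotopic, rod-dominated viewing, together with a synthetic 306-channel
MEG session generator that reproduces the phenomenology with known
ground truth.

It is written for researchers who analyze steady-state visual responses
and want a validated, reproducible reference implementation of:

* **Preprocessing** — zero-phase Butterworth bandpass (2–30 Hz, order 4),
  event-anchored epoching, 30-train averaging, detrending and baseline
  correction.
* **Frequency domain** — FFT amplitude spectra over 24 occipital
  gradiometers, resting-alpha estimation, *alpha peak ratios*
  (stimulation ÷ rest alpha peak) with paired t-statistics, and a
  two-rule **frequency-entrainment classifier**: the response frequency
  (maximal peak within ±2 Hz of the stimulation frequency f) must lie at
  f or a harmonic within one frequency bin, and its amplitude must exceed
  20% of the maximal peak in the whole cohort.
* **Spatiotemporal domain** — **Topographic Matching Pursuit (TMP)**: one
  Gabor atom g(t) ∝ exp(−π((t−u)/s)²)·exp(iξt) per stimulation period,
  with the scale s, translation u and modulation ξ shared over all
  channels (chosen to maximize the summed captured energy) and amplitude
  and phase fitted per channel. Atoms are compared with a per-subject
  reference atom (the average of the forty 1.00·α atoms), giving 40+10
  **correlation coefficient sequences** whose rise / plateau / fall
  encode topographic engagement and disengagement; responses classify as
  good / moderate / weak via a plateau-variance threshold of 0.004.
* **Time domain** — MGFP and the channel-mean Hilbert envelope from
  500 ms before onset to 3 s after the end, with **on-/off-response**
  detection (first outstanding envelope peak after onset / offset) and a
  paired group test of off-response occurrence at high (≥1.30·α) vs low
  (≤1.10·α) stimulation frequencies.
* **Synthetic sessions** — a hard-locking phase-oscillator source with
  resonance gains peaking at 1.00·α and 0.50·α, flicker fusion at
  ≥1.30·α with ~200 ms on- and ~150 ms off-transients, phase-diffusing
  background alpha from several dipolar generators, and Gaussian sensor
  noise — every block labeled with ground truth.

See `docs/methods.md` for the model, all tunable constants and the
validation studies.

## Worked example

```python
from photodrive import (
    generate_protocol, default_layout, simulate_session, ResponseModelParams,
)
from photodrive.preproc import bandpass, preprocess_block
from photodrive import spectra, tmp, spatiotemporal, timedomain

protocol = generate_protocol(alpha_hz=10.58, seed=7)
layout = default_layout().subset(default_layout().mask(region="occipital"))
session = simulate_session(protocol, layout, ResponseModelParams(snr=2.0, seed=7))

alpha_est = spectra.estimate_resting_alpha(bandpass(session.rest()))

blocks = {m: preprocess_block(session.block(session.block_index(m)), protocol, m)
          for m in (1.00, 2.00)}
occ = layout.occipital_gradiometers()
specs = {m: spectra.compute_spectrum(b, occ) for m, b in blocks.items()}
cohort_max = spectra.cohort_max_amplitude(specs.values())
for m, spec in specs.items():
    res = spectra.classify_entrainment(spec, protocol.stim_freq(m), cohort_max, m)
    print(f"multiplier {m:.2f}: response {res.response_freq_hz:.2f} Hz, "
          f"amplitude {res.response_amp:.1f} fT/cm, entrained={res.entrained}")

reference = tmp.reference_atom(tmp.atom_sequence(blocks[1.00])[:40])
for m in (1.00, 2.00):
    seq = tmp.correlation_sequence(reference, tmp.atom_sequence(blocks[m]))
    print(f"multiplier {m:.2f}: response class =",
          spatiotemporal.classify_response(seq).label)

env = timedomain.envelope(blocks[2.00])
on, off = timedomain.detect_on_off(env, 1000.0, blocks[2.00].onset_sample,
                                   blocks[2.00].stim_end_sample)
print(f"fused block transients: on at {on.latency_ms:.0f} ms, "
      f"off at {off.latency_ms:.0f} ms")
```

Output:

```
multiplier 1.00: response 10.50 Hz, amplitude 66.8 fT/cm, entrained=True
multiplier 2.00: response 22.46 Hz, amplitude 0.4 fT/cm, entrained=False
multiplier 1.00: response class = good
multiplier 2.00: response class = weak
fused block transients: on at 188 ms, off at 173 ms
```

Stimulation at the alpha frequency locks and amplifies the rhythm
(entrained, a *good* three-phase correlation sequence), while stimulation
at twice alpha — above the rod flicker-fusion threshold — shows no
driving, an unstable topography (*weak*), and on/off transients instead
(this subject's jittered on-latency is 188 ms; the resting alpha estimate
for the same session was 10.51 Hz against a true 10.58 Hz).

The cohort pipeline runs all stages over simulated subjects and writes
CSV tables plus a JSON summary:

```bash
photodrive simulate --alpha 10.6 --seed 7 --snr 2.0 --out session.h5
photodrive analyze --seed 7 --out report/
```

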