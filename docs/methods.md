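# Methods

This note documents the model and procedure the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the procedure left
room.

## Signal model and assumptions

A leg-worn tri-axial accelerometer (tibialis-anterior site) records walking at
$F_s = 148.15$ Hz. Each gait cycle produces two short, high-jerk transients:
the heel-strike impact and the smaller toe-off push-off. The method assumes

1. events appear as isolated peaks of the smoothed jerk magnitude $J(n)$;
2. heel-strike peaks are systematically larger than toe-off peaks, so two
   amplitude thresholds are meaningful;
3. gait is roughly periodic over a trial (cadence drifts slowly), so swing and
   stance durations estimated once generalise to the rest of the trial;
4. HS and TO strictly alternate.

No orientation calibration is assumed: the jerk magnitude is invariant to
sensor rotation, and a constant gravity offset vanishes under differentiation
(and under the 0.5 Hz high-pass).

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| `fs` | 148.15 | Hz | sampling rate; the scale grid assumes it |
| `hp_cutoff`, `hp_order` | 0.5, 2 | Hz, – | zero-phase Butterworth high-pass per axis |
| `th1` | 1.0 | g | composite-acceleration walking-onset threshold |
| `smooth_m` | 30 | samples | trailing-mean jerk smoothing (~200 ms); sets most of the detection latency |
| `window_len` | 300 | samples | observation window (~2 s, > 1 gait cycle at 0.5 Hz) |
| `fc` | 0.8125 | Hz | Morlet centre frequency; $\omega_0 = 2\pi f_c \approx 5.105$ |
| `s_max` | 241 | – | scale grid 1..241 = scale of the 0.5 Hz minimum gait frequency |
| prior modes / widths | 75, 150 / 15, 25 | scales | two-Gaussian prior at the assumed 1.6 / 0.8 Hz event and cycle frequencies |
| `band_filter_cutoff` | 10 | Hz | zero-phase low-pass of the band signals $x_e, x_c$ |
| `wait_len` | 15 | samples | streaming confirmation wait (~100 ms) |
| `r_b`, `r1`, `r2` | 0.8, 0.5, 0.5 | – | baseline, amplitude and duration memberships |
| `match_tolerance` | 0.4 | s | evaluation matching window; accepts the observed 70–230 ms detection delays while rejecting cross-cycle mismatches at normal cadence |

The membership defaults sit on a performance plateau: the `sweep` command
reproduces the F1-vs-$(r_1, r_2)$ grid over $\{0.1, 0.3, 0.5, 0.7, 0.9\}$.

## Wavelet stage: numerical choices

* The CWT is evaluated directly as a cross-correlation with the sampled
  complex Morlet $\pi^{-1/4} e^{i\omega_0\eta} e^{-\eta^2/2}$, with $1/\sqrt s$
  amplitude normalisation and zero-padded boundaries (FFT convolution; kernel
  truncated at $|\eta| \le 8$, where the envelope is below $2\times10^{-14}$).
  Tying $\omega_0 = 2\pi f_c$ makes the map $f = f_c F_s / s$ exact, which is
  what reproduces the integer scales 75/150/241. An independent CWT
  (PyWavelets' `cmor`) serves as a cross-check oracle in the tests, never as
  the implementation.
* Printed scales use round-half-up; all argmin/argmax tie-breaks go to the
  smallest scale or sample index, for determinism.
* The energy-peak scale of a pure tone sits ~2% above $f_c F_s / f$ (the
  $\sqrt s$ energy weighting shifts the argmax by a factor $1 + \omega_0^{-2}$);
  this bias is far smaller than the inter-mode separation the calibration
  relies on and is shared by the cross-check implementation.
* Spectra are max-normalised before the delay cross-correlation, making
  $\tau$ amplitude-invariant and shift-equivariant over the full symmetric
  lag range.
* The band signals use the **real part** of the CWT rows (not the modulus):
  the segmentation needs negative peaks, so an oscillatory band signal is the
  only consistent reading. The 10 Hz band filter is a low-pass — its stated
  purpose is removing high-frequency noise — with a config switch
  (`band_filter_kind = "highpass"`) for the literal alternative.

## Window calibration: robustness rules

The region rule (one event per inter-negative-peak region of $x_e$, including
the two boundary regions) assumes every region contains a genuine event. The
boundary regions need not: the window can start or end mid-gap, and an ungated
argmax then promotes a noise bump to an event, which corrupts the mean peak
amplitudes and — worse — the alternation anchor, flipping the kind of every
subsequently streamed event. Two rules, both reusing the method's own gates,
handle this:

* a region's jerk peak must exceed the baseline gate $r_b \cdot \mathrm{median}(J)$
  (the same Step-1 gate the streaming stage applies);
* the first and last window events must pass the amplitude membership
  $r_1 \times$ (mean same-kind peak of the other window events) — the same
  membership the streaming stage applies to its candidates. Only boundary
  events are eligible, so alternation cannot be broken by the drop.

Non-alternating window sequences are repaired by dropping the lower-amplitude
offender of a same-kind adjacent pair. Degenerate windows (missing a kind or
an adjacent pair) raise a calibration error naming what is missing.

## Streaming detector

Confirmation is a single restartable timer: any sample exceeding the current
starting-point peak restarts the 15-sample wait with that larger value (ties
keep the first occurrence). An expired wait promotes the peak to a candidate,
gated by amplitude and elapsed-time memberships for the expected kind (the
opposite of the previous event). Events are timestamped at the peak index;
the reported latency is the wait (16 samples to decision) plus the smoothing
group delay $(m-1)/2$ samples — about 200 ms at the defaults, which is also
the observed mean offset between detected peaks and ground-truth event onsets.

The pipeline starts the stream at the sample after the last calibrated window
event rather than at the window end: the detector is causal, so re-processing
the window tail is sound, and this closes a dead zone in which an event whose
peak falls between the last calibrated event and the window end would be seen
by neither stage (one missed event there phase-flips all later labels).
After a rejected candidate the machine returns to search at the next sample;
no timeout relaxes the duration gate (a configurable relaxation was considered
and left out — miscalibrated-threshold deadlock has not been observed on the
synthetic corpus, and silent gate relaxation would mask calibration failures).

## FSR reference

Heel strike = heel channel rising through 5% of its observation-window
maximum; toe off = toe channel falling below 95% of its window maximum (a "5%
decrease from maximum"; `toe_fraction` switches to the literal "below 5% of
maximum" reading). Crossings are linearly interpolated, the event index is
the first sample at/after the crossing, and crossings closer than a quarter of
the median inter-event interval are debounced. Thresholds are relative, so
channel gain is irrelevant.

## Synthetic generator

`generate_trial` emulates the study protocol: a 2 s quiet lead-in
(gravity + noise), then strides at a jittered cadence (2% SD per cycle), each
placing an HS and a TO burst — damped sinusoids (8 Hz, 80 ms decay) with fixed
oblique direction cosines — at times set by the swing fraction (0.38). FSR
channels are trapezoidal contact pulses keyed to the same times (heel loading
starts at HS; toe unloading completes at TO), with the programmed threshold
crossings stored for testing. Terrain presets vary cadence and burst
amplitude: level 0.9 strides/s with 3.0 g impacts, stair ascent slower and
softer (0.75, 2.2 g), stair descent slow with the hardest impacts
(0.78, 3.6 g); toe-off bursts are 1.5× smaller than heel-strike bursts
throughout, which is what makes separate HS/TO amplitude thresholds
meaningful.

Additive noise (default σ = 0.05 g per axis) is Gaussian, zero-phase
low-passed at 15 Hz and rescaled to σ. This models what dominates leg-worn
accelerometry at that magnitude — soft-tissue and motion artefact, which is
band-limited — rather than full-band white sensor noise: differentiation at
$F_s$ would amplify white noise of the same σ into a jerk floor comparable to
the toe-off bursts themselves, an SNR regime in which no jerk-peak heuristic
(this one included) can operate and which real recordings of this kind do not
exhibit. `noise_band = None` restores white noise for stress testing.

**What passing tests do and do not show.** The generator reproduces the
timing/amplitude structure the detector keys on (two bursts per cycle,
terrain-dependent amplitudes, stance/swing asymmetry, contact-keyed FSR
pulses), so perfect scores on it validate the detection logic, the
calibration, and their integration. It does not model measured waveform
shapes, inter-stride waveform variability, soft-tissue resonance,
orientation drift, speed changes, turns, or pathological gait — robustness to
those is untested by construction.

## Problem sizes

The test suite and the acceptance script use 8–12 s trials (7–16 gait
cycles), 10 seeds per condition and 3 terrains — enough cycles that one
spurious or missed event visibly moves the per-trial F1, and enough seeds
that a systematic failure mode cannot hide, while keeping the whole suite in
tens of seconds.

## Known limitations

* Single-window calibration: no re-calibration during long walks, so cadence
  or amplitude drift beyond the membership margins (±50%) degrades detection.
* Parity fragility: event kinds are assigned by alternation from the
  calibration anchor; a single false or missed event mislabels everything
  until the end of the trial. The window robustness rules above remove the
  observed triggers, but the mechanism is inherent to the streaming design.
* Fixed 15-sample wait and 30-sample smoothing put a ~200 ms floor on
  detection latency at 148.15 Hz.
* The frequency–scale constants assume the default sampling rate; other rates
  rescale the grid via the same map but were not the design point.
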