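# gaitevents

Self-calibrating, real-time detection of **heel-strike (HS)** and **toe-off
(TO)** gait events from a single leg-worn tri-axial accelerometer, with an FSR
(foot-switch) reference method, an evaluation suite, and a synthetic gait
simulator for three walking terrains (level ground, up stairs, down stairs).

The package is aimed at wearable-sensor gait analysis: triggering functional
electrical stimulation for drop-foot correction, controlling leg prostheses,
and scoring gait-event detectors against reference instrumentation.

## Method

All detection operates on the smoothed jerk magnitude of the acceleration
signal. With per-axis acceleration $a_x, a_y, a_z$ (in g, high-passed at
0.5 Hz, zero phase), the chain is

$$\mathrm{Jerk}(n) = \sqrt{\dot a_x^2 + \dot a_y^2 + \dot a_z^2}, \qquad
  J(n) = \tfrac{1}{m}\textstyle\sum_{k=n-m+1}^{n} \mathrm{Jerk}(k), \quad m = 30,$$

so each gait event contributes one dominant peak of $J$: a large one at heel
strike (impact) and a smaller one at toe off (push-off).

**Self-calibration (per trial).** Walking onset is the first sample where the
composite acceleration $\sqrt{a_x^2+a_y^2+a_z^2}$ exceeds 1 g. A 300-sample
(~2 s) observation window starting there is analysed with the complex Morlet
continuous wavelet transform ($\omega_0 = 2\pi f_c$, $f_c = 0.8125$ Hz) on the
integer scale grid $s = 1..241$, using the frequency–scale map $f = f_c F_s/s$
(at $F_s = 148.15$ Hz: 1.6 Hz ↦ scale 75, 0.8 Hz ↦ 150, 0.5 Hz ↦ 241). The
scale-energy spectrum $E_s = \sum_n |W_n(s)|^2$ is cross-correlated with a
two-Gaussian prior (modes 75 and 150, widths 15 and 25) to estimate the scale
delay $\tau$ of the subject's cadence from the assumed one; the spectrum is
split at its energy minimum between the shifted modes, and the posterior event
and cycle scales $\hat\mu_e, \hat\mu_c$ re-estimated by argmax on either side.
The real parts of the CWT rows at those scales (low-passed at 10 Hz) segment
the window at the event band's negative peaks; each region's $J$ peak is one
gait event, labelled HS or TO by the sign of the cycle band's dominant
extremum. The window yields the detector's thresholds: baseline
$TH_2 = \mathrm{median}(J)$, mean HS and TO peak amplitudes $TH_3, TH_4$, and
mean swing/stance durations $T_{swin}, T_{std}$.

**Streaming detection.** A constant-memory state machine processes each new
sample: a local $J$ peak above $r_b TH_2$ opens a 15-sample confirmation wait
(any larger sample restarts it); a confirmed candidate is accepted as the next
event — kinds strictly alternate — iff its amplitude exceeds
$r_1 TH_{3|4}$ and the elapsed time since the previous event exceeds
$r_2 T_{swin|std}$ (defaults $r_b = 0.8$, $r_1 = r_2 = 0.5$). Events are
timestamped at their peak; the decision latency (wait + smoothing group delay,
~200 ms at the defaults) is reported per event.

**Evaluation.** Detected events are matched one-to-one to a reference stream
(nearest in time within 400 ms, same kind); precision, recall and
$F_1 = 2PR/(P+R)$ are reported per kind, and timing agreement Bland-Altman
style (mean difference ± SD, absolute mean difference, limits of agreement
MD ± 1.96 SD, 95% CI).

## Worked example

Generate a noisy 12-s stair-ascent trial with ground truth, run the full
pipeline, and score it against the built-in FSR reference:

```bash
gaitevents simulate --terrain up --duration 12 --noise 0.05 --seed 7 --out trial.csv
gaitevents run --input trial.csv --events-out events.csv --report report.json
```

The run logs the calibration summary —

```
INFO gaitevents.calibration: calibrated window: tau=10 mu_e=84 mu_c=162, 3 events, TH2=6.34 TH3=27.1 TH4=19.9
INFO gaitevents: report written to report.json (pooled F1 = 1.000)
```

— meaning the subject walked slower than the prior assumed (scale delay
τ = 10, event/cycle scales 84/162 instead of 75/150), three events were found
in the observation window, and the thresholds were set from them. The first
rows of `events.csv`:

```
kind,n,t_s,amplitude,latency_ms
HS,325,2.1937175,27.39162967,0
TO,447,3.0172053,19.86668012,0
HS,523,3.5301977,26.74391018,0
TO,647,4.3671853,18.15262849,199.12205
```

Calibration-window events carry zero latency (they are found retrospectively);
streamed events carry the real-time decision latency (~199 ms: 16-sample
confirmation plus 14.5-sample smoothing delay). In `report.json`, both event
kinds score P = R = F1 = 1.00 against the FSR reference, with a mean timing
difference of +226 ms (the jerk peak lags the FSR contact transition by the
burst rise plus the smoothing delay) and limits of agreement [149, 304] ms.

The same pipeline is available as a scikit-learn style estimator:

```python
from gaitevents import GaitEventDetector
det = GaitEventDetector()            # fs=148.15, r1=r2=0.5, ...
events = det.fit(X).predict(X)       # X: (n_samples, 3) acceleration in g
```

`fit` self-calibrates on the observation window (fitted attributes
`onset_`, `thresholds_`, `scale_estimate_`, `calibration_events_`);
`predict` streams the detector over the trace and returns the event table.

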