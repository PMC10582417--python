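# Methods

This note records the models, parameter choices, numerical decisions and
limitations behind `thermogait`, in the spirit of a package methods
appendix. Units throughout: mV, °C, km h⁻¹, Hz, µW, W kg⁻¹.

## Sensing model and its assumptions

Each TEG channel is quasi-steady within a 2 s analysis window and obeys
the gait-extended King's law `(V/ΔT)² fⁿ = I + J vᵐ`. Assumptions baked
into this form:

- The channel output is proportional to the skin–air temperature
  difference ΔT (linearized Seebeck response); ΔT must be positive, or
  the model is not invertible.
- The convective "wind speed" over the element equals the locomotion
  speed — the wearer generates their own relative air flow.
- The exponents m and n are small positive integers (capped at 3 in the
  fitting grid; the largest exponent the model family uses is the thigh
  AC channel's f³). Integer exponents keep the on-device arithmetic
  cheap.
- No transient thermal dynamics: warm-up appears only as the slow skin
  temperature drift of the generator, and each window is treated as an
  equilibrium point.

The default channel coefficients (shank DC I=9, J=6, m=1, n=1; shank AC
6, 2.2, 2, 1; thigh DC 12, 8, 1, 1; thigh AC 8, 3, 2, 3) were chosen so
that (a) every channel output stays inside the 20–90 mV span the
conditioning electronics accept, over the treadmill envelope of skin–air
ΔT (≈6–9 °C) and speeds 3–8 km/h, and (b) each leg's DC/AC ratio is
strongly speed-sensitive, which the inversion needs. An identifiability
analysis during design showed two hazards that shaped these defaults and
the generator: with cadence a deterministic function of speed, f is
collinear with v and the cubic frequency exponent cannot be told apart
from speed-exponent alternatives; and small intercepts I are
leverage-amplified by extrapolation to v=0. Hence the cadence jitter
below and intercepts of comparable magnitude to the slope terms.

## Synthetic sessions: what they emulate, what they do not

The generator reproduces the treadmill protocol the system targets:
speeds 3–8 km/h in 1 km/h steps, 30 s dwell, six sessions, 50 Hz raw
rate (9000 samples per session; the raw rate is an assumption consistent
with the published sample counts, not a stated value).

Per-channel construction:

- **TEG voltages** — DC-channel response plus a gait-locked sinusoid
  whose amplitude is the AC-channel response, sharing one phase track
  with the knee and accelerometer waveforms. Additive Gaussian noise
  with SD = 2% of the instantaneous clean level (default).
- **Gait frequency** — cadence map f = 0.5 + 0.15·v Hz shared by both
  legs, plus seeded N(0, 0.08 Hz) jitter per 2 s window (≈6%
  stride-to-stride variability, in the range reported for human gait).
  The jitter is what makes the frequency exponent identifiable from a
  protocol in which cadence otherwise tracks speed exactly.
- **Knee angle** — a two-hump flexion template per gait cycle (small
  stance bump, large swing peak, wrapped Gaussians), amplitude
  min(65, 30+4v) degrees over a 5° baseline; constant at rest. The hump
  weights/widths keep the fundamental dominant in the periodogram.
- **Strain channel** — angle mapped linearly to gauge strain
  (175° full scale → 0.40 strain), transduced with a lens-shaped
  loading/unloading hysteresis that vanishes at the travel endpoints and
  peaks at `hysteresis_width` × full scale mid-travel (default width
  0.028 → 2.8% hysteresis error by construction). Strain above the 40%
  range is clipped with a logged warning.
- **Acceleration** — per-axis gait-locked fundamentals plus second
  harmonics and impact-transient pulses, amplitude growing with speed;
  deliberately distorted relative to the knee angle so the fidelity
  contrast between strain gauge and accelerometer is realistic.
- **Metabolic rate** — base 2.0 + 0.9v + 0.05v² W/kg (monotone in speed,
  spanning ≈5–12 W/kg over the protocol), plus AR(1) noise at 1 Hz
  (ρ=0.9, innovation SD 0.15 W/kg), all smoothed by a first-order 20 s
  lag to mimic oxygen-uptake kinetics at speed transitions.

Not emulated: validated biomechanics (waveforms are statistical
stand-ins), sensor drift/aging, motion artifacts, subject-to-subject
variability (all six sessions share one "subject"), ambient temperature
changes, or radio behavior. Passing tests therefore demonstrate that the
algorithms are correct and well-conditioned under the stated noise model
— not that the accuracy figures transfer to real subjects.

## Window decomposition

Windows are non-overlapping and half-open, [t, t+2). Per window and leg:

1. **Activity** — summed per-axis acceleration variance over a threshold
   (default 0.1 (m/s²)²; generated rest ≈ 0.0075, slowest walking ≈ 1.5).
2. **f** — dominant periodogram frequency (hann window, zero-padded FFT)
   in the 0.5–4 Hz human-cadence band, then refined by minimizing the
   residual of a harmonic regression over f. The refinement is needed
   because a 2 s window holds barely two gait cycles at 3 km/h, where
   the raw periodogram peak is pulled several percent low by its
   negative-frequency image — and f enters the thigh equation cubed.
3. **V1, V2** — intercept (at the window centre) and quadrature
   amplitude of the regression x ~ b₀ + b₁t + bₛsin(2πft) + b_c cos(2πft).
   The plain window mean is biased by the non-integer cycle count; a
   robust percentile-span amplitude estimator is kept as a swappable
   alternative (`ac_amplitude`) for non-sinusoidal waveforms, but it
   carries a few-percent bias at two cycles per window.

Inactive windows report the plain mean, a percentile amplitude and f=0.
Windows containing NaNs are flagged invalid and excluded downstream with
a logged count; a channel that is NaN over an entire recording is treated
as absent rather than invalidating every window.

## Calibration

For each exponent pair (m, n) in {1,2,3}², y = (V/ΔT)²fⁿ is regressed on
vᵐ by closed-form OLS; the pair with the smallest residual sum of squares
wins, ties toward smaller m+n, candidates with non-positive intercepts
rejected with a warning. Fitting pools all sessions (per-window rows:
measured V and f, ground-truth window means of v and ΔT; only valid,
active, constant-speed windows). Requirements: ≥2 distinct speeds (else
J is unidentifiable) and positive ΔT throughout.

The shipped default calibration (`data/default_calibration.json`) is the
output of this procedure on the default six-session fixture with seed 0;
it recovers the generating exponent pattern (n = 1, 1, 1, 3) exactly and
the coefficients within ~0.5%.

A note on misuse detection: swapping the shank and thigh channels is
*not* reliably visible as an R² drop — the wrong leg's ΔT is nearly
proportional to the right one, so OLS absorbs it into I and J. It *is*
visible as the recovered exponent pattern flipping (the f³ signature
follows the physical thigh AC channel), which is what the test suite
checks.

## Inversion

The per-leg channel ratio `(V1/V2)² f^(n1−n2) = (I1+J1vᵐ¹)/(I2+J2vᵐ²)`
eliminates ΔT exactly (and f entirely on the shank, where n1=n2).
Because the exponents are integers, clearing the denominator yields a
polynomial of degree ≤3 whose real roots in [0, 12] km/h are extracted
exactly via the companion matrix. A bracketing scan was rejected: the
DC/AC ratio is non-monotone at very low speed (extremum near 0.7 km/h
for the defaults) and twin roots between scan points get missed. With
multiple roots, the one nearest the previous window's estimate wins
(temporal continuity), else the smallest. Leg-wise speeds are fused by
unweighted mean (configurable); ΔT follows by back-substitution into the
DC equation, and skin temperature as T_air + ΔT. Inactive windows report
v=0 and temperatures from the static inversion ΔT = V1/√I. Any failed
sub-solver flags the window invalid — estimates are never interpolated.

## Metabolic estimator

Single-layer LSTM, 5 cells, linear read-out of the last hidden state;
inputs are strain + 3 acceleration axes, mean-binned from 50 Hz to 5 Hz
and windowed into 10 steps; the target is the window-mean metabolic
rate. Channel-wise standardization statistics come from the training
folds only and are stored in the model artifact. Training: full-batch
Adam on MSE, learning rate 0.02, 400 epochs, uniform ±1/√H weight
initialization with forget-gate bias +1, all seeded; gradients are
handwritten BPTT, verified against finite differences in the tests.
Non-finite loss aborts with the epoch number. Evaluation is
leave-one-session-out with pooled and per-fold MAPE/RMSE. On the default
fixture the pooled MAPE is ≈4%, comfortably below the ≈10% plateau that
motivates this design point; the variant (10 Hz, 20 steps) is available
through the config.

## Power budget

The ledger stores (component, mode, strategy, average power, duty)
entries; totals are duty-weighted sums. The default ledger reproduces
the measured mode totals of the hardware this models — 8.1/13.9 µW
static and 92.1/168.7 µW dynamic for ECM/RTM — with the three known
per-function averages (strain sensor 0.048 µW, analytic estimation
1.5 µW, LSTM estimation 25.6 µW) entered as such and the remainder
distributed over MCU, accelerometer, signal conditioning and Bluetooth;
that split is a documented assumption. ECM savings are
100·(P_RTM−P_ECM)/P_RTM: 45.4% dynamic, 41.7% static.

Sustainability uses mode-constant harvested floors (60 µW static, 300 µW
dynamic) times the 35% DC-DC efficiency → 21/105 µW effective supply;
the speed-resolved harvest curve (monotone PCHIP through (0, 60),
(3, 300), (9, 1600) µW) lives in `teg.py` for finer analyses. Supply ≥
demand counts as sustainable (boundary inclusive).

The state machine is discretized at 0.25 s ticks; polls run at 0.25 Hz,
mode changes at the first poll observing a changed activity state, and
in dynamic mode an estimate+broadcast event fires at 0.25 Hz once the
2 s buffer has filled after the switch (a 60 s active bout yields 15
broadcasts).

## Numerical choices and degenerate inputs

- Root extraction tolerance 1e-6 km/h; roots clipped into [0, 12].
- Both channel slopes J=0 → speed unidentifiable, explicit error.
- MAPE requires strictly positive truth (zero entries are reported by
  index); fidelity is undefined for constant series.
- Hysteresis full scale = output span of the loading branch; branches
  interpolated onto their common strain range (512 points).
- Session CSVs are written with 17 significant digits and parsed with
  correctly-rounded floats, so write→read is bit-lossless.
- All randomness flows through `numpy.random.default_rng` seeded from
  the protocol/config seeds; per-session streams derive from
  SeedSequence(seed, session_index).

## Problem sizes

Defaults used by the tests and the acceptance script: six sessions of
9000 samples (54 000 raw samples), 540 analysis windows, 540 LSTM
windows across six leave-one-out folds; the calibration-recovery study
repeats the six-session fit over 20 seeds. These sizes keep the entire
suite in the tens of seconds while leaving every estimate comfortably
determined.

## Known limitations

- One synthetic "subject"; no inter-individual transfer is tested.
- The thigh inversion consumes the measured ft raised to the second
  power in the ratio; its accuracy rests on the refined frequency
  estimator (relative error SD ≈0.3% on 2 s windows).
- The ratio inversion is ambiguous below the channel-ratio extremum
  (<≈0.7 km/h for the defaults) — slower than any protocol speed, but a
  caveat for shuffling-gait applications.
- The metabolic network sees only motion channels; metabolic changes at
  constant motion (slope, load carriage, fatigue) are invisible to it.
- The component split of the default power ledger beyond the three known
  per-function averages is an assumption; only the mode totals are
  anchored.
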