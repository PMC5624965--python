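# Methods

## Vibro-impact oscillator

Between impacts the bill displacement follows x'' + p x' + q x = R(t) with
positive x pointing toward the wood. The wall at x = x₀ is one-sided: an
impact occurs when x crosses x₀ moving toward the wood (v > 0), whereupon
x is kept continuous and v is replaced by −α v. Everything is
dimensionless; the model illustrates regimes (sustained drumming versus a
short decaying transient), it is not a dimensional model of bill/neck
mechanics, and no parameters are estimated from recordings.

Parameters and defaults:

| parameter | meaning | default |
|---|---|---|
| p | damping rate | 0.2 |
| q | stiffness; √q is the natural angular frequency | 0.3 |
| α | coefficient of restitution ∈ (0, 1] | 0.8 |
| x₀ | wall displacement | 0.2 |

The two shipped presets pair these with the canonical forcings: a unit sine
burst on the open window 2π < t < 20π (`fig2-periodic`) and a unit-width,
unit-amplitude Gaussian thrust centred at 20π (`fig2-impulsive`). The
source material does not state the initial state, integration span or
solver for these illustrations; we start from rest at the equilibrium
(x = v = 0 at t = 0) — the only parameter-free choice, since the forcing is
zero before the window opens — and integrate to t = 30π, long enough for
the post-forcing transient to die out. Reproduction of the illustrated
solutions is therefore qualitative (regime structure) plus pinned to an
independent reference integrator, not to digitized curve values.

### Numerics

The smooth flow is integrated with adaptive RK45 (`scipy.solve_ivp`),
rtol 1e-9, atol 1e-12, max step 0.1; the impact surface is a terminal
integration event (upward crossing of x₀) localized by root-finding on the
solver's dense output, which is far tighter than the 1e-9 `event_tol`
contract. Integration restarts at each impact from (x₀, −α·v_in).
Segments are split at forcing breakpoints (window edges of the burst; the
approach of the Gaussian) so the adaptive solver cannot step across a
discontinuity or over the pulse while the state is at rest. The dense
trajectory is sampled every 0.01 time units.

Restitution sequences with α < 1 can in principle chatter (a Zeno
accumulation of ever-smaller impacts). Impacts slower than
`chatter_speed_eps` (1e-6) set the rebound velocity to zero — the bill
rests on the wood — and more than 100 consecutive such micro-impacts
terminate the run with a logged warning rather than looping. With the
default presets chatter never occurs (the restoring force pulls the bill
away from the wall); the guard is exercised in tests with a constant thrust
whose equilibrium lies beyond the wall.

Cross-validation: an independent fixed-step RK4 integrator with bisection
event location (tests/oracle.py, no shared code, no scipy) reproduces every
impact of both presets; adaptive and reference impact times agree to better
than 1e-5 (measured ~1e-7). Impact times from both integrators are also
frozen in the test suite as regression anchors. Measured dense-output
overshoot above the wall is below 1e-14, so trajectory samples are reported
as integrated, without projection.

## Cadence statistics and regime classification

An impact train reduces to counts, inter-impact intervals (population CV —
a descriptive statistic on the complete train, not a sample estimate),
speed-decay ratios, and counts during/after the forcing window. For a
periodic burst the window is the open interval (t_on, t_off); for an
impulsive thrust the pulse centre divides "driven" from "transient"
impacts. With no forcing all impacts count as "after".

Classification is deliberately operational, since the regimes are
qualitative: **periodic** (drumming) requires a run of at least 5
consecutive during-forcing impacts whose intervals have CV ≤ 0.1. A run is
used rather than the CV of all during-forcing intervals because lock-on to
the drive begins with a few irregular impacts (on the periodic preset the
first three intervals are 0.84, 0.82 and 6.34 against a steady ~6.2), which
would otherwise mask an arbitrarily long steady drum. **Transient** (double
knock) requires at most 4 impacts, each slower than its predecessor;
**mixed** is everything else. All three thresholds are exposed and should
be re-tuned for oscillator parameters far from the defaults.

Far-field detectability of knocks is modelled purely as a threshold on
impact speed (count of impacts with speed_in ≥ threshold); no acoustic
propagation is attempted. The number of detected knocks is then monotone
in the thrust intensity, matching the intuition that harder thrusts carry
farther.

## Flap-rate model

f = St·U / (b·sin(33.5·b^−0.24)), with the stroke angle in **degrees**:
direct evaluation with the published inputs (St = 0.25, U = 15.2 m/s,
b = 0.78 m → 8.38 Hz; U = 9.55 m/s, b = 0.705 m → 5.70 Hz) confirms the
degree convention; radians produce values inconsistent with every quoted
rate. The predictor validates that the angle lies in (0°, 180°), which
holds for wingspans of roughly 0.1–3 m.

Rate arithmetic keeps unrounded intermediates: 15/2.27 = 6.6079… Hz is
divided by the 0.714 duty fraction before any display rounding, giving
9.2548… → 9.25 Hz. Percent differences use the observed rate as the
denominator — the convention consistent with both quoted comparisons (9.4%
and 9.6%). The video frame rate is not stated anywhere; 60 fps is the
unique rate consistent with all four quoted frames-per-flap ↔ rate pairs
(6 → 10 Hz, 7 → ~8.5 Hz, 8 → 7.5 Hz, 12 → 5 Hz) and ships as an
overridable default. The Ivory-billed wingspan default is 0.78 m, the mean
of the reported 0.76–0.80 m range. The "ten standard deviations" flap-rate
claim cannot be recomputed because the underlying standard deviation is not
published; only a generic z-score utility with a user-supplied sd is
provided.

## Synthetic data

The generators emulate what field media would provide, with known ground
truth.

*Knock trains*: nominal grids (a two-knock pair 0.1 s apart at amplitude
ratio 0.8, or an n-knock roll at 0.06 s period with 0.95 amplitude decay
per knock — plausible large-woodpecker values, not species measurements)
perturbed by Gaussian timing jitter and re-sorted. *Audio*: each knock is
an exponentially decaying sinusoid (default 1200 Hz ring, 20 ms decay — a
minimal resonant-impact model; the decay is short enough that a knock's
tail falls well below the detector's release level before the next knock
at drum-roll spacing) plus Gaussian white noise, peak-normalized, written
as 16-bit mono WAV. *Onset detection*: a moving-RMS envelope (5 ms window)
with threshold at 0.25 of the envelope peak and hysteresis (re-arm below
half the threshold) so noise riding on a decaying tail cannot retrigger;
onsets closer than 20 ms are merged. The generate → render → detect round
trip recovers knock counts exactly and intervals within 5 ms for noise RMS
up to 0.05 and spacing of 50 ms or more.

*Flap sequences*: each cycle is a flap of duration 1/f (the flap period
proper: wings open to wings folded) followed by a folded-wing pause, so a
cycle lasts 1/(duty·f) and n flaps span n/(duty·f) seconds; event frames
are rounded after per-event Gaussian frame jitter. Counting flaps back off
the sequence recovers the raw rate f̃ = duty·f, and dividing by the duty
fraction recovers the intrinsic rate within 2% (mean over 100 seeded
sequences at 1-frame jitter). Note the geometry: pause = (1−duty)/(duty·f),
not (1−duty)/f — only the former makes 15 flaps at f = 9.25 Hz and duty
0.714 span 2.27 s with f̃ = 6.61 Hz, the internally consistent set of
values.

What the generators do **not** emulate: reverberation, propagation loss,
wind/handling noise, species-specific double-knock timing (no such timings
are published for the five *Campephilus* species of interest), camera
motion or rolling-shutter effects. Passing round-trip tests therefore
demonstrates internal consistency of the pipeline, not performance on field
recordings.

## Problem sizes

The shipped configurations are desk-scale by design: oscillator runs span
t ∈ [0, 30π] (~94 time units, ≤14 impacts), synthetic audio is under a
second at 16 kHz, and recovery studies use 100 seeded sequences of 15–200
flaps. The full test suite runs in a few seconds.

## Known limitations

- The oscillator is dimensionless; mapping p, q, α, x₀ to a real bird
  would require measurements that do not exist.
- Regime thresholds are tuned to the default presets; they are exposed
  precisely because other parameter regions (weak damping, near-elastic
  restitution) blur the periodic/transient boundary.
- The raw-rate estimator for flap sequences uses flap-start spacings, so
  it needs at least two flaps and degrades for very short sequences with
  heavy jitter.
- The flap-rate model is a scaling law; the ±10% differences from observed
  rates in the worked example are typical of its accuracy, not defects of
  the implementation.
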