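# Methods

## The representation models

All four models map an imagined-cursor trajectory x_c(t) to the hand
trajectory a participant holding that representation would produce.
Trajectories are uniformly sampled planar position series (cm, s,
default 200 Hz — the rate of the recording setup being emulated), with
+y the sagittal (forward) direction.

- **Time**: hand(t) = cursor(t + τ̂). Implemented as an integer sample
  shift (τ̂ rounded to the nearest sample); the final τ̂ seconds hold
  the cursor's terminal sample, which is exact because the cursor is
  stationary at trial end in every simulated task.
- **Spatial shift**: hand = cursor + Δx̂·û. The shift direction û is
  not defined by the mapping itself in 2D; we use the start→target
  unit vector for reaching and +y for tracking (pong hits occur only on
  upward paddle motion, so the learned offset is sagittal).
- **Gain**: hand = o + ĝ·(cursor − o). The anchor o is the movement
  start for reaching and the cursor path centre (its mean) for
  tracking; this reproduces pure amplitude scaling without introducing
  offsets. With a data-dependent anchor the gain commutes with the
  spatial shift; with a fixed anchor it would not.
- **Mechanical**: hand = cursor + (B̂/K̂)·cursor′ + (M̂/K̂)·cursor″ —
  the paddle as a damped mass on a spring, kept in its second-order
  Taylor form rather than integrated as an ODE. Derivatives are
  2nd-order central differences with 2nd-order one-sided stencils at
  the ends, so the model is deterministic and testable against
  analytic sines. The two ratios are exposed independently: the
  single-τ̂ expansion fixes (τ̂, τ̂²/2) via `taylor_params`, but the
  standard figure-eight illustration pairs B̂/K̂ = 0.5 s with
  M̂/K̂ = 0.005 s², which no single τ̂ produces, so the constraint is a
  convenience, not an invariant. For a sinusoid at angular frequency ω
  the amplitude gain is |1 − (τ̂²/2)ω² + jτ̂ω| = √(1 + τ̂⁴ω⁴/4):
  unity at DC, growing with frequency — the signature that separates
  it from a frequency-flat gain.

## Blind-task simulation

**Reaching.** The imagined cursor performs a minimum-jerk reach
(quintic 10s³ − 15s⁴ + 6s⁵, tf = 0.3 s, 10 cm targets separated by
45°); the hand is the active model applied to it. The reported
endpoint is the hand position at its maximal along-reach excursion —
this reduces to the terminal point for monotone trajectories and
captures the overshoot of the non-monotone time/mechanical
trajectories — plus per-axis Gaussian noise (SD 1 cm), the composite
read-out noise of sensorimotor control. Whether that noise is per-axis
or radial is not specified by the paradigm; per-axis is implemented.

**Tracking.** The target runs either a figure-eight Lissajous
(x = A sin(2πt/T), y = A sin(4πt/T), A = 8 cm, T = 5 s; one frontal
cycle per two sagittal cycles) or a five-sine sagittal mixture
(A = 2 cm per component at 0.23–0.67 Hz). The mixture's printed form
sin(fr·π·t + φ) would halve the stated frequencies; we implement
sin(2π·fr·t + φ) so the listed values are true frequencies in Hz, as
the accompanying text treats them. Baseline (no-delay) tracking is
modelled as the target delayed by a 0.2 s reaction lag (initial sample
held during start-up). The state models are applied to that lagged
cursor — their diagnostics (slope, intercept, amplitude ratio) are
lag-invariant. The time model is the exception: it predicts a hand
that precedes the *target* by τ̂ outright, because pre-empting in time
is precisely what that representation compensates; its lead over the
baseline hand is therefore τ̂ + 0.2 s (0.7 s at τ̂ = 0.5 s). Applying
the advance to the lagged cursor instead would predict a 0.5 s
relative lead, which contradicts the stated 0.7 s.

## The pong game

Arena 24 × 16 cm, 1 kHz control loop. The paddle displays the hand
position τ seconds ago via a rounded-sample ring buffer (all standard
delays are integral at 1 ms). Side/bottom walls reflect elastically;
the upper wall adds horizontal jitter j = −ẏ·tan(α), α ~ N(0, 0.05π)
(or j ~ U(−13, 13) cm/s), so the rally never locks into a fixed
pattern. A hit registers only when the paddle moves upward against a
downward ball; contact is detected when the ball crosses the moving
paddle line from above within a step (linear interpolation in the
relative coordinate, so a fast paddle overtaking a slow ball also
makes contact — the paddle's frontal half-width, not specified by the
paradigm, is a config parameter, default 2 cm). Post-hit velocities
are ẋ → 0.7ẋ + 0.42ẋ_p and ẏ → −0.7ẏ + 0.42ẏ_p; the sign structure
guarantees an upward exit, and a paddle at (0.3/0.42) ≈ 0.71 of the
incoming speed is speed-neutral. Wall collisions resolve before paddle
collisions within a step; corner hits reflect both components. No
clipping is applied to the frontal coupling. The haptic pulse
magnitude is m_b·Δv/Δt in SI units (3 N for m_b = 0.15 kg,
Δv = 50 cm/s, Δt = 25 ms); its triangular time-profile is a rendering
detail and is not simulated. Delay schedules: abrupt (0.1 s from trial
1) and gradual (0.004 s/trial, reaching 0.1 s at trial 25). Built-in
policies (dead, scripted oscillator, ball-chasing proportional tracker
with optional reaction lag) make the game exercisable without human
input; they are reference controllers, not behavioural models.

## Metrics

- **Reach amplitude**: onset at the first sample exceeding 2% of peak
  speed; end 0.1 s after the speed first drops below 5% of peak after
  the peak (clipped to the last sample — simulated trials end exactly
  at tf); amplitude is the onset→end Euclidean distance.
- **Tracking R²** = 1 − [var(x_err) + var(y_err)] / [var(x_h) + var(y_h)];
  trials below 0.6 are excluded. Note the denominator is the *hand*
  variance: uncorrelated equal-variance tracking scores ≈ −1, not 0,
  and a constant offset scores 1 (the filter tests pattern fidelity).
- **Ellipse fit**: direct least-squares conic fit with the
  ellipse-specific constraint (Fitzgibbon/Halir–Flusser), solved on
  mean-centred data and shifted back. Centre, counterclockwise
  major-axis angle θ (four-case arc-cotangent rule on the cross term),
  slope = tan θ and intercept = o_h − slope·o_t. The angle rule
  assumes the Matlab acot convention (range (−π/2, π/2]); it is exact
  for θ ∈ [0, π/2] — the regime of positively coupled target–hand
  scatter — and folds axes in (π/2, π) back by π/2, which the tests
  document explicitly. Near-collinear scatter (minor/major axis ratio
  < 1e-3, e.g. lag-free tracking) falls back to the principal axis of
  the centred scatter with the intercept through the centroid; exactly
  collinear input raises an error. The figure-eight analysis fits one
  ellipse per dimension over all samples.
- **Target–hand delay**: argmax over integer-sample lags (bounded by
  max_lag, default 2 s, required below half the duration) of the
  Pearson correlation of the two overlapping segments, each centred on
  its own mean. Positive output = hand precedes target. The
  per-overlap normalization is deliberate: with unnormalized products
  the shrinking overlap biases the argmax toward zero on short
  signals (measured 0.66 s where the true shift is 0.70 s on a single
  5 s cycle), whereas the normalized form is exact for any
  sample-shifted copy. It agrees with a brute-force shift-and-correlate
  search by construction, which the tests assert.
- **Spectra**: the periodogram is Hann-windowed and zero-padded 25×
  (600,000 bins from a 120 s, 200 Hz trial), scaled so a sinusoid of
  amplitude A peaks at power A²/2, whence A = √(2·pow); probe
  frequencies take the local peak within ±0.05 Hz. The pong analysis
  uses the plain FFT amplitude A = 2|FFT|/L with L the unpadded
  length. Decibels are 10·log₁₀(A²/2) throughout (one printed variant
  omits the log; it is treated as a typo). Dominant frequency: centred
  101-sample moving average of the dB profile (windows shrink
  symmetrically at the edges), argmax restricted to [0.5, 1.5] Hz,
  ties broken toward the lowest frequency.

## Synthetic cohorts

Each participant contributes a pre session (identity mapping) and a
post session (the ground-truth model; identity for control cohorts),
with 45 reach trials (3 targets × 15) or 15/45 tracking trials per
session. Endpoint noise is Gaussian, SD 1 cm. Trajectory noise is an
artifact assumption — the paradigm specifies only endpoint noise — and
is modelled as per-sample Gaussian noise low-passed at 5 Hz
(zero-phase Butterworth, rescaled to the nominal SD) so synthetic
trajectories are kinematically plausible. Per-participant parameters
jitter multiplicatively (SD 10% of the effect) to produce
between-participant spread comparable to real cohorts without claiming
any specific variance. Everything is deterministic given the seed.

What a green test establishes: that the pipeline measures what the
generator put in, at the stated noise levels. The generator does not
emulate submovement corrections, reaction-time variability, fatigue,
or trial-to-trial learning, so green tests say nothing about effect
sizes in human cohorts (which require the unavailable recordings).

**Recovery** fits each candidate model's single parameter to a session
pair by bounded scalar least squares (endpoint space for reaching,
trajectory space for tracking, trials averaged first). The time
variant's tracking objective is piecewise constant in τ̂, so it is
searched exactly on the sample grid. Residuals for all candidates are
reported; model selection stays with the caller. The identifiability
study classifies a generator as mechanical when the slope of the
post-minus-pre dB difference across the five mixture frequencies
exceeds half the noiseless mechanical prediction (≈ 0.56 dB/Hz at
τ̂ = 0.2 s) — a threshold fixed by theory before any data are drawn.

## Numerical choices

Uniform sampling is enforced to 1 ns per step. τ values round to the
nearest sample everywhere (exactness over interpolation; all standard
values are integral at the relevant rates). The conic eigen-solution
takes the real part and requires the ellipse discriminant positive;
spectral tie-breaks and the moving-average edge policy are described
above. Degenerate inputs (constant signals, zero variance, empty
buffers, collinear scatter, too-short trajectories) raise typed errors
rather than returning NaN.
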