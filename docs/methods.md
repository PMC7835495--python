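# Methods

This note documents the models implemented in `beekin`, their assumptions,
the parameters that matter, and the design choices made where the design was
genuinely open. Units are stated everywhere because the package mixes three
natural scales: seconds and frames for time, radians internally and degrees
on disk for angles, deg/s for angular velocities.

## Coordinate systems and orientation

Each body part (head, thorax) carries three markers forming a rigid,
nominally equilateral triangle (5 mm side by default). The body frame is
defined as:

* origin: centroid of the three markers;
* **y**: unit vector from the *right* marker to the *left* marker (so +y is
  the animal's left, making x-forward/y-left/z-up right-handed with z up for
  a level animal — a convention this package fixes explicitly, since
  "aligned left to right" alone does not pin the sign of yaw);
* **x**: component of (front marker − origin) orthogonal to y, normalized;
* **z** = x × y.

The columns (x, y, z) form the body→world rotation R. Orientation angles use
the yaw-pitch-roll composition **R = Rz(ψ)·Ry(θ)·Rx(φ)** (roll applied
first, yaw last), with pitch confined to [−π/2, π/2]. At gimbal lock
(|pitch| = π/2) yaw and roll are degenerate; we set roll = 0, let yaw absorb
the in-plane rotation, and warn. The decomposition is cross-checked against
scipy's intrinsic-ZYX Euler implementation in the test suite.

Yaw is always **unwrapped** before smoothing, interpolation or integration;
±π wraps otherwise create spline artifacts that dwarf any real signal.

## Angular velocity

ω is computed from the full rotation sequence, Ω× = Rᵀ·dR/dt with dR/dt by
central differences (one-sided at the ends) and the skew part antisymmetrized
before reading off ω_z. This stays correct under nonzero pitch and roll and
reduces to d(yaw)/dt when both are zero. Central differencing attenuates a
component at frequency f by ~(2πf/fps)²/6 — about 2 % at 30 Hz and 500 fps —
which is far below the contrasts any of the analyses depend on.

## Smoothing splines with fixed effective degrees of freedom

Pose channels are filtered with a penalized cubic smoothing spline
(minimize Σ(y−g)² + λ∫g″²). Rather than exposing the raw penalty λ — whose
scale depends on sampling — the API takes the smoother's **effective degrees
of freedom** (trace of the hat matrix; n = interpolation, 2 = straight line;
default 150 for ~10 s at 500 fps). The penalty is solved by bisection on
log λ using the Reinsch banded form of the hat matrix, whose trace is
computed with chunked banded solves in O(n²); the fit itself is scipy's
`make_smoothing_spline`, and a unit test verifies the two agree on the hat
trace. Data-driven selection of the smoothing strength (e.g. GCV) is out of
scope; the degrees of freedom are a configuration input.

## Saccade segmentation

Two-threshold hysteresis on |ω_z|: frames above the **high** threshold
(372.42 deg/s) seed a saccade, which extends over the contiguous run of
frames above the **low** threshold (200.54 deg/s). These defaults are the
manually determined head-velocity values that define ground truth. Design
choices: thresholds apply to the *absolute* velocity because saccades turn
both ways (a signed mode exists behind a flag); no minimum duration or merge
gap is imposed. The implementation labels connected components above the low
threshold and keeps those containing a seed; the test suite checks it
against an independent flood-fill-to-fixpoint oracle on large random
ensembles.

The **benchmark** is the pair of thorax thresholds maximizing frame-wise
agreement with head-derived labels, found by exhaustive grid search
(defaults: high ∈ [200, 1000] step 5 deg/s, low ∈ [50, high] step 5). Ties
break deterministically toward the largest high, then the largest low. The
optimizer exploits that, for a fixed low threshold, the connected components
are fixed and a component is predicted saccade iff its peak exceeds high, so
cumulative sums over peak-sorted components evaluate all highs at once. A
caveat worth knowing: when the trace's component peaks are sparse (clean
pulses far above threshold), many threshold pairs are exactly optimal and
the tie-break — not the generating pair — decides; recovery of a specific
pair is only identifiable on traces that explore the threshold range
densely.

## Saccade classification

The learning task: given the thorax velocity window
Ω_z^thorax(t) = [ω_z(t−Δt/2), …, ω_z(t+Δt/2)], predict the head's binary
saccade state at the center frame. Windows with incomplete support are
dropped; the window sample count is the odd integer 2·⌊Δt·fps/2000⌋+1, so
Δt = 0 degenerates to the center sample and odd products are well defined.

Models are sklearn decision trees and random forests (100 trees by default,
seeded). The data split is time-respecting: the first 70 % of frames
(⌊0.7·n⌋) of each of the first K−1 flights train, the remaining 30 %
validate, and the last flight is held out entirely — shuffling frames would
leak heavily autocorrelated neighbors across the split. Hyperparameters
(depth ∈ [1, 20], Δt ∈ [0, 50] ms) are chosen by validation accuracy; ties
prefer the simpler model (smaller depth, then smaller window). Classes are
not reweighted; a warning fires if the imbalance exceeds 4:1 (the default
synthetic conditions sit near that line, at roughly one saccade frame in
five).

Robustness sweeps emulate two common degradations: (i) low frame rate —
poses are decimated by the integer stride nearest fps/target and
re-interpolated to the original grid with cubic splines before velocities
are recomputed (non-integer ratios are therefore approximate); (ii)
single top-view camera — marker z coordinates are replaced per frame by
their mean, which forces pitch = roll = 0 downstream and projects yaw. The
benchmark keeps its full-rate thresholds through the sweeps, matching how a
fixed threshold would actually be reused on degraded data.

## Velocity mapping and the anti-identity loss

The mapper is a three-layer feed-forward network: n_samples inputs plus a
bias, N relu hidden units plus a constant bias unit, and two tanh outputs
(O_c, O_s) encoding (cos θ, sin θ) of the predicted angular velocity. The
angle is θ = ω·s with the **velocity scale** s defaulting to radians of turn
per sample interval, i.e. (π/180)/fps per (deg/s): a data-free choice that
keeps even 5000 deg/s at 500 fps well inside (−π, π) and makes the encoding
exactly "rotation per frame". s is configurable.

Training minimizes

    L = Σ_t |target_enc(t) − O(t)|² / (λ·|source_enc(t) − O(t)|² + ϵ)

with λ = 0.5 and ϵ = 0.1. The numerator is an ordinary squared error to the
target (head) encoding; the denominator *shrinks* — inflating the loss —
when the output reproduces the source (thorax) encoding, so the network is
repelled from the trivial identity mapping. The penalty is maximal exactly
at the identity solution and the loss is zero exactly at a perfect
prediction.

Optimization choices the loss definition leaves open: Adam with step size
1e-2, minibatch 64, shuffled each epoch from the run seed, weights
initialized uniformly in ±1/√fan_in, 30 epochs. The step size matters: the
encoded targets live on a ~1e-2 scale under the default velocity scale, and
at step 1e-3 thirty epochs demonstrably underfit (training loss plateaus
high and decoded predictions can transiently anti-correlate with the
target); 1e-2 converges on both tiny-scale fixtures and flight-scale data.
Training is bit-reproducible given (seed, data, config); inputs are
pre-multiplied by the velocity scale so all layers operate on O(1e-2)
quantities.

### Temporal shifts

τ (ms, discretized to whole samples; the realized sample shift is reported
alongside the requested value) relates the observation window to the
predicted instant:

* τ = 0 — centered window (the plain mapping task);
* τ < 0 — *forecasting*: the window ends |τ| before the predicted instant,
  so the entire observation precedes what it predicts;
* τ > 0 — *backcasting*: the window starts τ after the predicted instant.

The scan retrains a fresh network per τ with the same seed (reusing weights
across shifts would entangle the curve with optimization history) and
reports the Pearson correlation r(τ) between decoded prediction and target
on the held-out flight, plus the median unsigned error angle
ΔΩ = arccos(ô·o) ∈ [0, π] between predicted and measured encodings. If one
body part leads the other by δ, the lead-to-lag prediction stays good on the
forecasting side up to |τ| ≈ δ and degrades for backcasting — the asymmetry
that indicates the direction of information flow. Note the τ = 0 convention
differs from the one-sided windows at τ ≠ 0, so r(τ) need not be continuous
through zero.

## Synthetic flights

The generator emulates the behavioral structure the analyses assume, not
bumblebee aerodynamics:

* **Events**: a renewal process with gaps = refractory + Exp(1/rate −
  refractory), so the mean gap is 1/rate (rate default 4 events/s,
  refractory 200 ms; configurations with rate·refractory ≥ 1 are rejected).
  Events keep a margin from the trace edges so pulse integrals are complete.
* **Head velocity**: per event, a Gaussian velocity pulse with integral
  equal to the signed saccade amplitude (uniform ±[20, 60]°) and SD 14 ms —
  saccades lasting several tens of ms with peaks of ~800–2400 deg/s, well
  above the seed threshold and well below fly-like 5000 deg/s.
* **Thorax velocity**: a pulse of equal integral, center led by
  `thorax_lead` (default 8 ms) and width × 1.5 — earlier, broader,
  lower-peaked. The lead is defined **center-to-center** (the broader pulse
  moves the onset earlier still): the center lag is what cross-correlation
  and the τ-scan measure, so the causality experiments have an exact ground
  truth. Negative values let the head lead.
* **Noise**: Ornstein–Uhlenbeck with 20 ms correlation time (SD 30 deg/s
  head, 80 deg/s thorax), mimicking the temporally correlated jitter that
  differentiating tracked poses produces — and making thorax traces
  genuinely harder to threshold than head traces. White noise would be too
  easy: hysteresis removes isolated single-frame excursions almost for free.
* **Pose**: yaw integrates the *noisy* velocity (trapezoid), so pose and
  velocity stay mutually consistent through the resampling sweeps; the
  "measured" velocity series are re-derived from the pose by the same
  body-frame differentiation the real pipeline uses. Ground-truth labels
  come from the noise-free head velocity at the default thresholds, keeping
  label noise out of classifier evaluations. Optional sinusoidal pitch/roll
  oscillation (default off) exercises the top-view degradation.

What passing on these flights does **not** show: real learning flights have
translation-coupled kinematics, variable pulse shapes, tracking dropouts and
marker occlusions, and an unknown joint distribution of head–thorax lags;
absolute accuracies and AUCs here say nothing about recorded data. What it
does show: the chain is internally correct (exact round trips, oracle
equivalence), the learned classifier genuinely extracts temporal context a
hard threshold cannot (it beats the benchmark under matched conditions), the
causality scan recovers a known lag with the right asymmetry, and every
negative control lands at chance.

## Numerical conventions and degenerate inputs

Frame indices are 0-based; intervals half-open. Collinear or coincident
markers raise a geometry error naming the frame. Series with fewer samples
than a window yield an empty dataset with a warning; shifts longer than the
series likewise. Undefined quantities (AUC against a single-class reference,
r under degenerate variance) are reported as missing with a warning, never
silently as numbers. Angles are stored in degrees in CSV files and radians
in memory; all randomness flows from explicit integer seeds.

## Problem sizes

The shipped experiments use 6 flights × 10 s at 500 fps for the
classifier-vs-benchmark comparison (10 seed replicates), 4 × 6 s for the
lag-recovery and null-control scans (5 seeds), 3 × 6 s over 8 seeds for the
frame-rate ensemble, 10⁵ random signals for the segmentation oracle check,
and a 10 °/s optimizer grid inside repeated ensembles (5 °/s elsewhere).
These sizes make the full suite and the reproduction script run in minutes
on a single CPU while keeping every comparison's margin far larger than its
seed-to-seed spread.
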