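# beekin — head–thorax flight choreography analysis

Flying insects steer with a saccadic gaze strategy: brief, fast yaw turns
(saccades) of the head and body alternate with near-rotation-free
intersaccades in which translational optic flow carries distance
information. Head orientation is hard to record — it needs multi-camera,
high-frame-rate tracking of tiny head markers — so experimenters usually
track only the thorax and infer the head's behavior from it. `beekin` is a
toolkit for doing that inference properly, built around bumblebee
(*Bombus terrestris*) learning flights:

* **Kinematics** — rigid-body orientation from three tracked markers per
  body part, the yaw-pitch-roll decomposition
  `R = Rz(ψ)·Ry(θ)·Rx(φ)`, penalized cubic smoothing splines
  parameterized by effective degrees of freedom, and the body-frame angular
  velocity `Ω = unskew(Rᵀ Ṙ)` (deg/s about the body z-axis).
* **Segmentation** — two-threshold (hysteresis) saccade extraction: frames
  with |ω_z| > 372.42 °/s seed a saccade, which extends over contiguous
  frames with |ω_z| > 200.54 °/s; plus the *benchmark*: the thorax threshold
  pair optimized to best reproduce head-derived labels.
* **Saccade classifier** — a decision tree / random forest predicting the
  head's saccade state at frame *t* from the thorax velocity window
  `Ω_z^thorax(t) = [ω_z(t−Δt/2), …, ω_z(t+Δt/2)]`, with hyperparameter
  search over depth D ∈ [1, 20] and Δt ∈ [0, 50] ms, and robustness sweeps
  over frame rate and the null-pitch/roll (single top camera) assumption.
* **Velocity mapper** — a three-layer MLP (relu hidden layer, two tanh
  outputs encoding (cos θ, sin θ) of the predicted velocity) mapping one
  body part's velocity window to the other's, trained with the
  anti-identity loss

  `L = Σ_t |head_enc(t) − O(t)|² / (λ·|thorax_enc(t) − O(t)|² + ϵ)`,

  λ = 0.5, ϵ = 0.1, which blows up exactly when the network copies its own
  input. Scanning a temporal shift τ (τ < 0: the observation window wholly
  precedes the predicted instant, *forecasting*; τ > 0: *backcasting*) and
  plotting the prediction–target correlation r(τ) probes the direction of
  information flow between head and thorax.
* **Synthetic flights** — a generator with known event times, amplitudes,
  head–thorax lag and marker geometry, so every stage is testable without
  recorded flights.

## Worked example

```python
import beekin as bk

flights = [bk.generate_flight(bk.FlightConfig(duration=10.0), seed=i)
           for i in range(6)]

res = bk.SaccadeClassifier.from_flights(flights, seed=0).fit()
print(res.summary())
```

```
Head-saccade classifier
=============================================
family        : random_forest
depth         : 10
window        : 20.0 ms (11 samples @ 500 fps)
trees         : 100
train rows    : 17450
---------------------------------------------
validation  accuracy 0.9734  error 2.66%  AUC 0.9959
test        accuracy 0.9685  error 3.15%  AUC 0.9948
```

The forest classifies ~96–97 % of validation frames correctly; the
optimally thresholded thorax benchmark on the same frames reaches ~93–94 %
(`bk.optimize_benchmark_thresholds`), so windowing the thorax velocity
recovers a large share of the frames that a hard threshold mislabels.

The causality scan, on flights generated with the head leading the thorax
by 10 ms:

```python
cfg = bk.MapperConfig(n_hidden=8, window_ms=5.0, seed=0)
vm = bk.VelocityMapper.from_flights(
    [bk.generate_flight(bk.FlightConfig(duration=6.0, thorax_lead=-10.0),
                        seed=50 + i) for i in range(4)],
    "head2thorax", cfg)
print(vm.shift_scan([-12.0, -10.0, -8.0, 0.0, 8.0]).to_string(index=False))
```

```
 tau_ms  tau_samples  median_error_angle        r    n
  -12.0           -6            0.002736 0.927618 2992
  -10.0           -5            0.002671 0.930588 2993
   -8.0           -4            0.002458 0.930934 2994
    0.0            0            0.002601 0.895718 2998
    8.0            4            0.005408 0.789327 2994
```

r(τ) peaks on the forecasting side at the generated ~10 ms lag and decays
for backcasting — the asymmetry that identifies which body part leads.

There is also a CLI (`beekin simulate|segment|benchmark|train-clf|sweep|
train-map|map-grid|shift-scan|run`); `beekin run --config pipeline.yaml`
executes multi-stage runs with a reproducibility manifest.

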