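# Methods

## Problem setting and representation

The forecaster consumes single-agent planar tracklets (track id, frame, x, y)
produced by any upstream detector–tracker, in a 0-based, y-down image
convention. Coordinates are generic planar units; a units-per-pixel scale can
be applied externally if metric output is needed, since monocular footage
carries no intrinsic calibration. A training/evaluation sample ("window") is
T_past = 8 observed positions followed by T_fut = 60 future positions
(defaults; roughly two seconds at 25–30 Hz). Eight positions yield seven
displacement tokens — no extra preceding position is assumed, which keeps
windows self-contained. Future positions are recovered by cumulatively
summing predicted displacements from the last observed point, so the model
is translation-invariant by construction.

Tracks with frame gaps are split at the gaps, never interpolated: a gap
means the tracker lost the bird, and fabricated positions would contaminate
the displacement statistics. Segments shorter than T_past + T_fut = 68
frames are dropped (the shortest usable window).

## Density head

The predictive distribution is a K = 5 component mixture of multivariate
Student-t distributions over the vectorized future displacement sequence
(dimension d = 2·T_fut). Scale matrices are diagonal: d positive entries per
component, obtained by exponentiating clamped raw outputs. A full 2×2-block
(per-timestep Cholesky) structure would capture within-step x–y correlation,
but the diagonal form keeps determinant and inverse trivial and was adopted
as the default; correlation across time and axes is instead expressed
through the mixture itself. One ν per component, shared across timesteps,
is learned as 2 + softplus(raw) so covariances stay finite; ν = ∞ is
accepted in the containers and evaluated with the Gaussian closed form,
which is how Gaussian-head baselines share every downstream code path.

All densities are computed in log space via log-gamma and log-sum-exp; the
log density is finite for every finite input, and raw log-scales are clamped
to [−10, 10] before exponentiation so extreme head outputs cannot overflow.
The identical code path (written against a dispatching numerical layer)
serves both plain arrays and autodiff tensors, so the training loss and the
reported NLL cannot drift apart.

## WTA training

For each sample the component with the highest individual log density wins
(weights are not consulted; ties break to the lowest index) and only the
winner's μ, Σ, ν receive gradient, together with all weight logits through
the softmax. The argmax is treated as a constant during differentiation —
no straight-through estimators. Batch loss is the mean over samples.

Two practical notes discovered during development:

* **Initialization.** The final head layer starts at zero weights, so the
  initial forecast is (nearly) a standstill and early training is stable.
  Exactly zero initialization, however, makes all K components identical,
  and with the deterministic tie-break every sample routes to component 0
  forever — guaranteed mode collapse. The location-block *biases* therefore
  receive tiny seeded noise (`ModelConfig.mu_init_std`, default 0.01;
  set 0 to restore the exact standstill). This is enough for the WTA
  partition to key on motion direction and for components to specialize.
* **Rich-get-richer collapse.** Plain WTA can still collapse on adversarial
  tasks where all histories are identical and the future is bimodal: one
  component reaches the data first, its scale shrinks, and its density then
  dominates everywhere, freezing the rest. `TrainConfig.soft_wta_epochs`
  optionally trains the first epochs on the full-mixture NLL before
  switching to WTA; on the bimodal toy this recovers both modes with weights
  0.50/0.50. The flag defaults to off — plain WTA from step 0 is the
  reference recipe, and on realistic flock data (diverse histories) the
  components specialize without help.

Optimization: AdamW, base lr 5e-4, decoupled weight decay 0.02, batch 64,
cosine annealing to zero with linear warmup over the first 10% of steps,
dropout 0.1 in attention and feed-forward layers (training mode only),
gradient clipping at global norm 5 (heavy-tailed targets occasionally spike
early gradients). Early stopping monitors the per-step full-mixture
validation NLL; the best checkpoint is restored after training. With a
fixed seed the loss history is bit-reproducible.

## Evaluation protocol

The K "modes" scored by minADE/minFDE are the component mean displacement
sequences reconstructed into position space — means, not samples, which is
the standard protocol when a mixture provides K hypotheses. minADE averages
the Euclidean error over the first h steps; minFDE takes step h alone, and
its minimizing mode may differ from minADE's. NLL is computed on the full
mixture (all K components) in displacement space and reported per future
timestep; the joint (2·T_fut-dimensional) value is available via
`nll(..., normalization="joint")` since reporting conventions differ across
the literature.

The noise-robustness protocol perturbs every observed past displacement with
i.i.d. N(0, α²) noise at inference time only, re-anchoring the rebuilt past
on the true last observed position so reconstruction remains comparable;
futures are untouched. Each noise level is averaged over seeded repeats
(fresh noise per repeat). The horizon sweep truncates the same fixed
T_fut-frame forecast at increasing horizons. Density-grouped evaluation is
label-driven: the caller supplies one group label per window (e.g. flock
density bins), since any binning definition is dataset-specific.

## Baselines

* **CV-Kalman** — linear Kalman filter, state (position, velocity),
  constant-velocity transition at unit timestep, position observations.
  Initialized from the first two points (velocity = p1 − p0), updated over
  the remaining observations, then rolled forward with no further updates.
  Defaults: process noise 1e-3, observation noise 1e-2 (exposed; on
  noise-free linear tracks the forecast is exact for any setting because
  innovations vanish).
* **Gaussian LSTM** — encoder LSTM over past displacements; autoregressive
  decoder emitting a diagonal Gaussian per future step; teacher forcing in
  training, free-running on its own mean at inference. The default hidden
  size (224) puts its parameter budget near the Transformer
  configuration's, mirroring the capacity-matched comparison.

## Simulator

`flocksim` generates regime-switching correlated random walks, not a full
boids model: the forecaster is single-agent, so the fixtures need heavy
tails and multimodality rather than faithful collective dynamics. Per frame
and agent: with probability `turn_switch_prob` (default 0.03) the heading
takes a sharp Student-t(ν = `innovation_nu`, default 3) increment of
standard deviation `turn_rate_std` = 0.5 rad; otherwise it drifts by
N(0, 0.05²) rad. Speed follows a mean-reverting walk around
`cruise_speed_mean` = 6 units/frame (reversion 0.05/frame) with Student-t
innovations of scale `cruise_speed_std` = 0.1. Innovations are standardized
to unit variance before scaling, so the Gaussian-innovation control
(`innovation_family="gaussian"`) is matched in variance and differs only in
tail weight. Optional linear cohesion pulls agents toward the flock
centroid; Gaussian jitter (default std 0.5 units) models tracking noise.
All randomness derives from one seed through named substreams; simulation,
jitter and splitting are independent streams.

Speed is not clipped: a rare large negative t-draw briefly reverses the
motion, which is acceptable as a burst maneuver and keeps the innovation
distribution exact (closed-form kurtosis 6/(ν−4) is verified against the
generated increments). Benchmarks split at the track level before
windowing, so no track leaks across train/validation/test.

What the simulator does *not* emulate: identity switches, occlusion-induced
gaps mid-benchmark, perspective foreshortening, inter-agent interaction
beyond centroid cohesion, and 3-D motion projected to 2-D. Passing tests
therefore demonstrate correctness of the method and its implementation on
data with the assumed statistical structure (smooth cruising + heavy-tailed
bursts + jitter), not performance on any particular field dataset.

## Desk-scale study conditions

Training-time experiments (test suite and acceptance script) run a reduced
configuration chosen once: d_model 48, FFN 96, head width 96, T_fut 10,
~2000 train / 800 validation / 500 test windows from 30 independent
6-bird flocks with innovation ν = 3. The paired Student-t vs Gaussian
comparison trains both heads identically for 12 epochs (the ordering is
already stable there, with a per-step NLL gap ≈ 0.35–0.39); the acceptance
script's headline run uses 25 epochs, after which the Student-t model
typically also beats the CV baseline on minADE. Run-to-run variance under
plain WTA is real: across seeds most runs plateau near a per-step validation
NLL of ~2.73–2.76, while an occasional seed settles in a worse optimum
(~3.1) with correspondingly higher minADE; the Student-t-over-Gaussian NLL
ordering is stable across all seeds observed. The reference configuration (d_model 96,
2 layers, FFN 192, K = 5, T_fut = 60) totals 439,258 trainable parameters
by the documented closed-form count
(`flockcast.backbone.parameter_count_formula`); published parameter totals
for architectures of this shape vary with unstated head layouts, which is
why the formula, not a single number, is the contract.

## Numerical choices and limitations

* float64 throughout; evaluation-mode forwards are deterministic and
  batch-size invariant (verified bitwise in tests).
* WTA ties break to the lowest component index; softmax and log-sum-exp are
  max-shifted; softplus uses the log1p(exp(−|x|)) form.
* The Gaussian-limit agreement |log T(ν = 1e6) − log N| ≤ 1e-3 holds for
  points typical under the distribution; far off-distribution the O((q−d)²/ν)
  correction grows, which is a property of the Student-t family, not of the
  implementation.
* The `StudentTParams` container enforces ν > 2 (finite covariance); the
  unconstrained core (`log_student_t_terms`) accepts any ν > 0 for
  diagnostics such as the Cauchy case.
* No inter-agent attention or social pooling: histories are encoded per
  agent. No full covariance across timesteps. Divergence (non-finite loss)
  aborts training with the offending batch and step named rather than
  continuing silently.
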