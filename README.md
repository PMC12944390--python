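# flockcast

Probabilistic trajectory forecasting for bird flocks observed by a fixed
monocular camera. Given a short history of a bird's image-plane positions, the
package predicts a full probability distribution over its next one to two
seconds of motion — not a single path — using a compact Transformer encoder
and a heavy-tailed Student-t mixture density head. It is aimed at movement
ecologists and airspace-monitoring engineers who work with tracker output
(CSV/MOT tracklets) and need calibrated uncertainty about sudden turns and
accelerations, on hardware too small for large forecasting models.

## Model

Motion is represented by frame-to-frame displacements Δp_τ = p_τ − p_{τ−1}.
Each of the T_past − 1 observed displacements is linearly embedded into a
d_model-dimensional token, sinusoidal positional encodings are added, and a
small pre-norm Transformer encoder (2 layers, 4 heads, FFN width 192)
contextualizes the tokens. Temporal average pooling gives a history vector
h_hist, from which a shallow GELU MLP emits the parameters of a K-component
multivariate Student-t mixture over the vectorized future displacement
sequence y ∈ R^{2·T_fut}:

    p(y | x) = Σ_k π_k · T(y; μ_k, Σ_k, ν_k)

with diagonal scale matrices Σ_k, softmax weights π_k, and degrees of freedom
ν_k = 2 + softplus(·) > 2 so every component has finite covariance. Smaller ν
means heavier tails: large deviations (sharp turns, tracking glitches) are
penalized polynomially instead of exponentially, which is what calibrates the
model on bursty flight.

Training uses a Winner-Takes-All objective: for each sample the component
with the highest individual log density, k* = argmax_k log T(y; μ_k, Σ_k, ν_k),
is selected (mixture weights play no role in selection) and the loss

    L = −log π_{k*} − log T(y; μ_{k*}, Σ_{k*}, ν_{k*})

updates only that component's density parameters, plus all weight logits
through the softmax. This drives the K components to specialize in distinct
motion modes. Optimization is AdamW (lr 5e-4, weight decay 0.02, batch 64)
under a cosine schedule with 10% linear warmup and dropout 0.1.

Evaluation follows the standard multimodal-forecasting protocol: minADE and
minFDE over the K component-mean trajectories at 30- and 60-frame horizons,
plus the negative log likelihood (NLL) of the true future under the full
mixture, reported per future timestep. Baselines with the same interface: a
constant-velocity Kalman filter and an LSTM encoder–decoder with a Gaussian
head. A regime-switching correlated-random-walk simulator generates
heavy-tailed flock tracklets (Student-t turn and speed innovations, optional
cohesion, Gaussian tracking jitter) for benchmarks and tests.

The network and its training loop run on a small numpy reverse-mode autodiff
core shipped with the package (`flockcast._autodiff`, `flockcast.nn`), so the
only runtime dependencies are numpy/scipy/pandas plus click and pyyaml for
the CLI.

## Worked example

```python
import numpy as np
from flockcast import (
    MiniFormer, ModelConfig, SimConfig, TrainConfig,
    evaluate, make_benchmark, train,
)
from flockcast.baselines import CVKalman

# heavy-tailed flock benchmark: 6-bird flocks, 30 Hz, Student-t(3) bursts
sim = SimConfig(n_tracks=6, track_length=90, innovation_nu=3.0, seed=1)
tr, va, te = make_benchmark(sim, T_past=8, T_fut=10, n_flocks=30)

model = MiniFormer(ModelConfig(d_model=48, ffn_dim=96, head_hidden=96,
                               T_fut=10, K=5), seed=1)
train(model, tr[:2000], va[:800], TrainConfig(epochs=25, seed=1))

rep = evaluate(model, te[:500], horizons=(5, 10))
cv = evaluate(CVKalman(T_fut=10), te[:500], horizons=(5, 10))
print(f"minADE@10 {rep.min_ade[10]:.2f}  minFDE@10 {rep.min_fde[10]:.2f}  "
      f"NLL/step {rep.nll:.2f}   (CV minADE@10 {cv.min_ade[10]:.2f})")
```

Output:

    minADE@10 3.85  minFDE@10 7.04  NLL/step 2.95   (CV minADE@10 4.58)

minADE/minFDE are in simulator distance units (the simulated cruise speed is
6 units per frame, so 3.85 is well under one frame of motion averaged over a
10-frame horizon, and ~16% better than the constant-velocity baseline). The
NLL is per future timestep; an identically trained Gaussian-head variant
reaches 3.34 on the same split, the 0.39 gap being the calibration benefit of
the heavy tails.

A command-line interface wraps the same pipeline:

    flockcast simulate --seed 1 --out data/flock.csv
    flockcast train    --tracklets data/flock.csv --out runs/a
    flockcast evaluate --checkpoint runs/a/checkpoint.zip --tracklets data/flock.csv --out runs/a/eval
    flockcast predict  --checkpoint runs/a/checkpoint.zip --tracklets data/flock.csv --out runs/a/pred

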