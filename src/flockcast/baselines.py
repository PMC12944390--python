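"""Reference forecasters: constant-velocity Kalman filter and Gaussian LSTM.

Both baselines satisfy the same forward/evaluate contract as the Transformer
forecaster (a window in, a :class:`~flockcast.studentt.MixtureParams` out),
so one evaluation harness produces comparable reports for all models.

* The CV baseline runs a linear Kalman filter with state (position,
  velocity) and a constant-velocity transition at unit timestep over the
  observed positions, then extrapolates with no further updates.  It is
  exact on noise-free linear motion.
* The LSTM baseline encodes past displacements with an LSTM, then decodes
  autoregressively, emitting a diagonal Gaussian over each future
  displacement.  Teacher forcing is used during training; at inference the
  decoder consumes its own predicted mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from ._autodiff import Tensor, concatenate, stack
from .studentt import LOG_SCALE_CLAMP, MixtureParams, RawHeadOutput, constrain_params
from .trackio import Window

__all__ = [
    "cv_kalman_forecast",
    "CVKalman",
    "LSTMConfig",
    "LSTMGaussian",
    "build_lstm_gaussian",
]


# ---------------------------------------------------------------------------
# Constant-velocity Kalman filter
# ---------------------------------------------------------------------------

def cv_kalman_forecast(past_positions: np.ndarray, T_fut: int,
                       process_noise: float = 1e-3, obs_noise: float = 1e-2) -> np.ndarray:
    """Kalman-filtered constant-velocity extrapolation, shape (T_fut, 2).

    State x = (px, py, vx, vy); transition F advances position by velocity;
    only positions are observed.  The filter is initialized from the first
    two observations (position = p1, velocity = p1 - p0), updated on the
    remaining observations, then rolled forward T_fut steps deterministically.
    """
    P_obs = np.asarray(past_positions, dtype=np.float64)
    if P_obs.ndim != 2 or P_obs.shape[0] < 2:
        raise ValueError("need at least 2 observed positions")
    F = np.eye(4)
    F[0, 2] = F[1, 3] = 1.0
    H = np.zeros((2, 4))
    H[0, 0] = H[1, 1] = 1.0
    Q = process_noise * np.eye(4)
    R = obs_noise * np.eye(2)

    x = np.concatenate([P_obs[1], P_obs[1] - P_obs[0]])
    P = np.eye(4)
    for z in P_obs[2:]:
        # predict
        x = F @ x
        P = F @ P @ F.T + Q
        # update
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (z - H @ x)
        P = (np.eye(4) - K @ H) @ P
    out = np.empty((T_fut, 2))
    for t in range(T_fut):
        x = F @ x
        out[t] = x[:2]
    return out


class CVKalman:
    """CV-Kalman wrapped in the shared forecaster contract (K=1, point mode).

    The predictive distribution is a single near-deterministic Gaussian
    centred on the extrapolated displacements, so the shared evaluation
    harness can treat it uniformly; its NLL is not meaningful and is not
    reported in comparisons.
    """

    def __init__(self, T_fut: int, process_noise: float = 1e-3, obs_noise: float = 1e-2,
                 predictive_var: float = 1.0):
        self.T_fut = T_fut
        self.process_noise = process_noise
        self.obs_noise = obs_noise
        self.predictive_var = predictive_var

    def forward(self, window: Window) -> MixtureParams:
        traj = cv_kalman_forecast(window.past_positions, self.T_fut,
                                  self.process_noise, self.obs_noise)
        prev = np.vstack([window.past_positions[-1:], traj[:-1]])
        disp = (traj - prev).ravel()
        raw = RawHeadOutput(
            weight_logits=np.zeros(1),
            raw_mu=disp[None],
            raw_log_scale=np.full((1, disp.size), math.log(self.predictive_var)),
            raw_nu=None,
        )
        return constrain_params(raw)


# ---------------------------------------------------------------------------
# LSTM encoder-decoder with a Gaussian density head
# ---------------------------------------------------------------------------

@dataclass
class LSTMConfig:
    hidden_size: int = 224  # chosen so the budget approximates the Transformer's
    T_past: int = 8
    T_fut: int = 60
    family: str = "gaussian"

    def __post_init__(self):
        if self.family != "gaussian":
            raise ValueError("the LSTM baseline uses a Gaussian head")

    @property
    def d(self) -> int:
        return 2 * self.T_fut

    @property
    def has_nu(self) -> bool:
        return False

    @property
    def K(self) -> int:
        return 1


class LSTMGaussian(nn.Module):
    """LSTM encoder-decoder emitting per-step diagonal Gaussian displacements."""

    uses_teacher_forcing = True

    def __init__(self, config: LSTMConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        h = config.hidden_size
        self.encoder = nn.LSTMCell(2, h, rng)
        self.decoder = nn.LSTMCell(2, h, rng)
        self.out = nn.Linear(h, 4, rng, zero_init=True)  # (mu_x, mu_y, ls_x, ls_y)

    def _run(self, X: np.ndarray, Y_teacher: np.ndarray | None,
             rng: np.random.Generator | None = None) -> dict[str, Tensor]:
        """Encode past displacements, decode T_fut Gaussian steps.

        X: (B, T_past-1, 2). Y_teacher: (B, d) vectorized future displacements
        for teacher forcing, or None for free-running decoding.
        """
        B = X.shape[0]
        hsz = self.config.hidden_size
        h = Tensor(np.zeros((B, hsz)))
        c = Tensor(np.zeros((B, hsz)))
        for t in range(X.shape[1]):
            h, c = self.encoder(Tensor(X[:, t]), h, c)
        T_fut = self.config.T_fut
        teacher = None
        if Y_teacher is not None:
            teacher = Y_teacher.reshape(B, T_fut, 2)
        inp = Tensor(X[:, -1])  # last observed displacement primes the decoder
        mus, log_scales = [], []
        for t in range(T_fut):
            h, c = self.decoder(inp, h, c)
            z = self.out(h)
            mu_t = z[:, 0:2]
            ls_t = z[:, 2:4]
            mus.append(mu_t)
            log_scales.append(ls_t)
            if teacher is not None and self.training:
                inp = Tensor(teacher[:, t])
            else:
                inp = mu_t.detach()
        mu = stack(mus, axis=1).reshape(B, 2 * T_fut)         # (B, d)
        log_scale = stack(log_scales, axis=1).reshape(B, 2 * T_fut)
        return {
            "weight_logits": Tensor(np.zeros((B, 1))),
            "raw_mu": mu.reshape(B, 1, 2 * T_fut),
            "raw_log_scale": log_scale.reshape(B, 1, 2 * T_fut),
        }

    def forward_raw(self, X: np.ndarray, rng: np.random.Generator | None = None,
                    Y_teacher: np.ndarray | None = None) -> dict[str, Tensor]:
        return self._run(np.asarray(X, dtype=np.float64), Y_teacher, rng)

    def forward(self, window: Window) -> MixtureParams:
        c = self.config
        if window.T_past != c.T_past or window.T_fut != c.T_fut:
            raise ValueError("window shape does not match the model configuration")
        raw = self._run(window.past_displacements[None], None)
        return constrain_params(
            RawHeadOutput(
                weight_logits=raw["weight_logits"].data[0],
                raw_mu=raw["raw_mu"].data[0],
                raw_log_scale=np.clip(raw["raw_log_scale"].data[0],
                                      -LOG_SCALE_CLAMP, LOG_SCALE_CLAMP),
                raw_nu=None,
            )
        )

    def predict_batch(self, windows) -> list[MixtureParams]:
        X = np.stack([w.past_displacements for w in windows])
        raw = self._run(X, None)
        out = []
        for b in range(len(windows)):
            out.append(
                constrain_params(
                    RawHeadOutput(
                        weight_logits=raw["weight_logits"].data[b],
                        raw_mu=raw["raw_mu"].data[b],
                        raw_log_scale=np.clip(raw["raw_log_scale"].data[b],
                                              -LOG_SCALE_CLAMP, LOG_SCALE_CLAMP),
                        raw_nu=None,
                    )
                )
            )
        return out


def build_lstm_gaussian(config: LSTMConfig | None = None, seed: int = 0) -> LSTMGaussian:
    """Construct the Gaussian-head LSTM baseline with the shared contracts."""
    return LSTMGaussian(config or LSTMConfig(), seed=seed)
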