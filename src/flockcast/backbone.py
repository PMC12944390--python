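"""The compact Transformer forecaster: embedding, encoder, density head.

Architecture (defaults in :class:`ModelConfig` follow the reference recipe):

1. each past displacement ``dp_t`` (2-vector) is linearly embedded into a
   ``d_model``-dimensional token and a sinusoidal positional encoding is added;
2. a stack of pre-norm Transformer encoder blocks (multi-head self-attention
   + GELU feed-forward, residual connections, layer norm) contextualizes the
   tokens; full bidirectional attention is used because the history is a
   completed observation, not an autoregressive prefix;
3. temporal average pooling yields a fixed history vector ``h_hist``;
4. a shallow MLP head (two GELU hidden layers) emits the unconstrained
   parameters of a K-component mixture over the vectorized future
   displacement sequence (dimension ``d = 2*T_fut``).

The ``family`` switch selects the density placed on each component:
``student_t`` (heavy-tailed, with learned degrees of freedom), ``gmm``
(Gaussian components, K > 1) or ``gaussian`` (single Gaussian, K forced
to 1).  The backbone is identical across families; only the head's output
partition and likelihood change.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass
from io import BytesIO
from pathlib import Path

import numpy as np

from . import nn
from ._autodiff import Tensor
from .studentt import MixtureParams, RawHeadOutput, constrain_params
from .trackio import Window

__all__ = [
    "ModelConfig",
    "positional_encoding",
    "MiniFormer",
    "count_parameters",
    "parameter_count_formula",
    "save_checkpoint",
    "load_checkpoint",
]

_FAMILIES = ("student_t", "gaussian", "gmm")


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults are the reference configuration."""

    d_model: int = 96
    n_layers: int = 2
    n_heads: int = 4
    ffn_dim: int = 192
    dropout: float = 0.1
    K: int = 5
    T_past: int = 8
    T_fut: int = 60
    head_hidden: int = 192
    head_depth: int = 2
    family: str = "student_t"
    scale_structure: str = "diagonal"
    # std of the tiny random location offsets in the otherwise zero-initialized
    # final head layer; breaks the exact component symmetry that would make the
    # WTA tie-break route every sample to component 0 (mode collapse). 0 gives
    # an exact standstill initial forecast.
    mu_init_std: float = 0.01

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.family == "gaussian":
            self.K = 1
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.K < 1 or self.T_past < 2 or self.T_fut < 1:
            raise ValueError("require K >= 1, T_past >= 2, T_fut >= 1")
        if self.scale_structure != "diagonal":
            raise ValueError("only the diagonal scale structure is implemented")

    @property
    def d(self) -> int:
        """Dimension of the vectorized future displacement target."""
        return 2 * self.T_fut

    @property
    def has_nu(self) -> bool:
        return self.family == "student_t"

    @property
    def raw_per_component(self) -> int:
        """Raw head outputs per component: logit + mu + log-scale (+ nu)."""
        return 1 + 2 * self.d + (1 if self.has_nu else 0)


def positional_encoding(L: int, d_model: int) -> np.ndarray:
    """Standard sinusoid: PE[t, 2i] = sin(t / 10000^(2i/d)), PE[t, 2i+1] = cos."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if d_model % 2 != 0:
        raise ValueError("d_model must be even")
    t = np.arange(L)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = t / np.power(10000.0, 2.0 * i / d_model)
    pe = np.empty((L, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


class MiniFormer(nn.Module):
    """Displacement-token Transformer encoder with a mixture density head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.embed = nn.Linear(2, c.d_model, rng)
        self.layers = [
            nn.TransformerEncoderLayer(c.d_model, c.n_heads, c.ffn_dim, c.dropout, rng)
            for _ in range(c.n_layers)
        ]
        for i, layer in enumerate(self.layers):
            setattr(self, f"layer{i}", layer)
        self.final_norm = nn.LayerNorm(c.d_model)
        head_dims = [c.d_model] + [c.head_hidden] * c.head_depth
        self.head_hidden_layers = []
        for i, (din, dout) in enumerate(zip(head_dims[:-1], head_dims[1:])):
            lin = nn.Linear(din, dout, rng)
            setattr(self, f"head{i}", lin)
            self.head_hidden_layers.append(lin)
        # zero-initialized final layer: the initial forecast is (near) a
        # standstill; tiny bias noise on the location block breaks the exact
        # component symmetry so WTA can specialize the K components
        self.head_out = nn.Linear(head_dims[-1], c.K * c.raw_per_component, rng, zero_init=True)
        if c.mu_init_std > 0:
            bias = self.head_out.bias.data.reshape(c.K, c.raw_per_component)
            bias[:, 1:1 + c.d] = c.mu_init_std * rng.standard_normal((c.K, c.d))

    # -- pieces -----------------------------------------------------------
    def embed_displacements(self, displacements, *, as_tensor: bool = False):
        """Token embedding + positional encoding for an L x 2 displacement matrix."""
        arr = displacements.data if isinstance(displacements, Tensor) else np.asarray(displacements, dtype=np.float64)
        if not np.all(np.isfinite(arr)):
            raise ValueError("displacements contain non-finite entries")
        if arr.ndim == 2:
            arr = arr[None]
        L = arr.shape[-2]
        x = Tensor(arr)
        tokens = self.embed(x) + Tensor(positional_encoding(L, self.config.d_model))
        return tokens if as_tensor else tokens.data[0]

    def encode_history(self, tokens, rng: np.random.Generator | None = None):
        """Run the encoder stack and mean-pool over time; (B, L, D) -> (B, D)."""
        if not isinstance(tokens, Tensor):
            tokens = Tensor(np.asarray(tokens, dtype=np.float64))
        if tokens.ndim == 2:
            tokens = tokens.reshape(1, *tokens.shape)
        if tokens.shape[-2] == 0:
            raise ValueError("cannot encode an empty token sequence")
        x = tokens
        for layer in self.layers:
            x = layer(x, rng)
        x = self.final_norm(x)
        return x.mean(axis=-2)

    def mdn_head(self, h) -> dict[str, Tensor]:
        """Map pooled history (B, D) to raw mixture parameters (Tensors)."""
        if not isinstance(h, Tensor):
            h = Tensor(np.asarray(h, dtype=np.float64))
        if h.ndim == 1:
            h = h.reshape(1, -1)
        for lin in self.head_hidden_layers:
            h = nn.gelu(lin(h))
        raw = self.head_out(h)  # (B, K * raw_per_component)
        c = self.config
        B = raw.shape[0]
        raw = raw.reshape(B, c.K, c.raw_per_component)
        out = {
            "weight_logits": raw[:, :, 0],
            "raw_mu": raw[:, :, 1:1 + c.d],
            "raw_log_scale": raw[:, :, 1 + c.d:1 + 2 * c.d],
        }
        if c.has_nu:
            out["raw_nu"] = raw[:, :, 1 + 2 * c.d]
        return out

    # -- full passes ------------------------------------------------------
    def forward_raw(self, past_displacements, rng: np.random.Generator | None = None) -> dict[str, Tensor]:
        """Batched differentiable pass: (B, T_past-1, 2) -> raw parameter Tensors."""
        tokens = self.embed_displacements(past_displacements, as_tensor=True)
        h = self.encode_history(tokens, rng)
        return self.mdn_head(h)

    def raw_head_output(self, past_displacements) -> RawHeadOutput:
        """Single-sample raw head output as plain arrays (evaluation mode)."""
        raw = self.forward_raw(np.asarray(past_displacements)[None] if np.asarray(past_displacements).ndim == 2 else past_displacements)
        return RawHeadOutput(
            weight_logits=raw["weight_logits"].data[0],
            raw_mu=raw["raw_mu"].data[0],
            raw_log_scale=raw["raw_log_scale"].data[0],
            raw_nu=raw["raw_nu"].data[0] if "raw_nu" in raw else None,
        )

    def forward(self, window: Window) -> MixtureParams:
        """Predict the mixture over the window's vectorized future displacements."""
        c = self.config
        if window.T_past != c.T_past or window.T_fut != c.T_fut:
            raise ValueError(
                f"window shape (T_past={window.T_past}, T_fut={window.T_fut}) does not "
                f"match model (T_past={c.T_past}, T_fut={c.T_fut})"
            )
        return constrain_params(self.raw_head_output(window.past_displacements))

    def predict_batch(self, windows) -> list[MixtureParams]:
        """Vectorized evaluation-mode prediction for a list of windows."""
        c = self.config
        X = np.stack([w.past_displacements for w in windows])
        raw = self.forward_raw(X)
        out = []
        for b in range(len(windows)):
            out.append(
                constrain_params(
                    RawHeadOutput(
                        weight_logits=raw["weight_logits"].data[b],
                        raw_mu=raw["raw_mu"].data[b],
                        raw_log_scale=raw["raw_log_scale"].data[b],
                        raw_nu=raw["raw_nu"].data[b] if "raw_nu" in raw else None,
                    )
                )
            )
        return out


def count_parameters(model: nn.Module) -> int:
    """Total trainable scalar count."""
    return model.count_parameters()


def parameter_count_formula(c: ModelConfig) -> int:
    """Closed-form trainable parameter count for a :class:`MiniFormer`.

    embedding: 2*D + D
    per encoder layer: 4*(D^2 + D) attention + (D*F + F) + (F*D + D) FFN + 2*2*D norms
    final norm: 2*D
    head: (D*H + H) + (depth-1)*(H^2 + H) + (H*K*R + K*R)
    with D=d_model, F=ffn_dim, H=head_hidden, R=raw outputs per component.
    """
    D, F, H = c.d_model, c.ffn_dim, c.head_hidden
    emb = 2 * D + D
    per_layer = 4 * (D * D + D) + (D * F + F) + (F * D + D) + 4 * D
    head = (D * H + H) + (c.head_depth - 1) * (H * H + H)
    head += H * c.K * c.raw_per_component + c.K * c.raw_per_component
    return emb + c.n_layers * per_layer + 2 * D + head


# ---------------------------------------------------------------------------
# Checkpointing: a zip archive with config JSON + named weight arrays (npz)
# ---------------------------------------------------------------------------

def save_checkpoint(model, path, extra: dict | None = None) -> None:
    path = Path(path)
    state = model.state_dict()
    buf = BytesIO()
    np.savez(buf, **state)
    meta = {"config": asdict(model.config), "kind": type(model).__name__}
    if extra:
        meta["extra"] = extra
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(meta, indent=2))
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path):
    """Load a checkpoint; returns (model, meta). Shapes are validated."""
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        with zf.open("weights.npz") as fh:
            state = dict(np.load(BytesIO(fh.read())))
    kind = meta.get("kind", "MiniFormer")
    if kind == "MiniFormer":
        model = MiniFormer(ModelConfig(**meta["config"]))
    elif kind == "LSTMGaussian":
        from .baselines import LSTMConfig, LSTMGaussian

        model = LSTMGaussian(LSTMConfig(**meta["config"]))
    else:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    model.load_state_dict(state)
    model.eval()
    return model, meta
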